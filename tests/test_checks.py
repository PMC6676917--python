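"""Unit and property tests for the check evaluators and threshold gate."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdmdq.cdm_model import make_check_id
from cdmdq.checks import (CheckContractError, Finding, apply_thresholds,
                          eval_element_presence, evaluate_check,
                          modified_zscores, run_checks, summarize_dataset)


def get_check(catalog, cid):
    return catalog.check(cid)


def finding_for(catalog, ds, ctx, cid):
    return evaluate_check(get_check(catalog, cid), ds, catalog, ctx)


# ---------------------------------------------------------------- presence

def test_missdata_percentage_arithmetic(catalog, clean_small, ctx_small):
    """Nulling 3 of the first 10 rows of a fully populated field yields the
    percentage a row-count oracle gives."""
    ds = clean_small.copy()
    col = "condition_end_date"
    df = ds.tables["condition_occurrence"]
    df.loc[df.index[:3], col] = pd.NaT
    cid = make_check_id("MissData", (("condition_occurrence", col),))
    f = finding_for(catalog, ds, ctx_small, cid)
    n = len(df)
    expect = round(100.0 * 3 / n, 2)
    assert f.violation_count == 3
    assert f.numeric_value == pytest.approx(expect)
    # fully populated -> 0.0
    f0 = finding_for(catalog, clean_small, ctx_small, cid)
    assert f0.numeric_value == 0.0 and f0.violation_count == 0


def test_missconceptid_all_unmapped_is_100(catalog, clean_small, ctx_small):
    ds = clean_small.copy()
    ds.tables["condition_occurrence"]["condition_concept_id"] = 0
    cid = make_check_id("MissConceptID",
                        (("condition_occurrence", "condition_concept_id"),))
    f = finding_for(catalog, ds, ctx_small, cid)
    assert f.numeric_value == 100.0


def test_presence_contract_error(catalog, clean_small):
    check = get_check(catalog, make_check_id(
        "PreBirth", (("visit_occurrence", "visit_start_date"),
                     ("person", "time_of_birth"))))
    with pytest.raises(CheckContractError):
        eval_element_presence(check, clean_small, catalog)


# ---------------------------------------------------------------- agreement

def test_implevent_start_after_end(catalog, clean_small, ctx_small):
    ds = clean_small.copy()
    v = ds.tables["visit_occurrence"]
    i = v.index[5]
    v.loc[i, "visit_start_date"] = pd.Timestamp("2016-03-02")
    v.loc[i, "visit_start_datetime"] = pd.Timestamp("2016-03-02 08:00")
    v.loc[i, "visit_end_date"] = pd.Timestamp("2016-03-01")
    v.loc[i, "visit_end_datetime"] = pd.Timestamp("2016-03-01 18:00")
    cid = make_check_id("ImplEvent", (("visit_occurrence", "visit_start_date"),
                                      ("visit_occurrence", "visit_end_date")))
    f = finding_for(catalog, ds, ctx_small, cid)
    assert f.violation_count == 1


def test_incondatetime_consistent_is_zero(catalog, clean_small, ctx_small):
    cid = make_check_id("InconDateTime",
                        (("visit_occurrence", "visit_start_date"),
                         ("visit_occurrence", "visit_start_datetime")))
    f = finding_for(catalog, clean_small, ctx_small, cid)
    assert f.violation_count == 0


def test_inconsource_null_disagreement(catalog, clean_small, ctx_small):
    ds = clean_small.copy()
    df = ds.tables["condition_occurrence"]
    df.loc[df.index[0], "condition_source_value"] = None  # concept stays mapped
    cid = make_check_id("InconSource",
                        (("condition_occurrence", "condition_source_value"),
                         ("condition_occurrence", "condition_concept_id")))
    f = finding_for(catalog, ds, ctx_small, cid)
    assert f.violation_count == 1


# ------------------------------------------------------------- face validity

def test_prebirth_strictly_before_boundary(catalog, clean_small, ctx_small):
    """A visit on the birth date itself is not a violation; the day before is."""
    ds = clean_small.copy()
    v = ds.tables["visit_occurrence"]
    p = ds.tables["person"]
    pid = int(v["person_id"].iloc[0])
    p.loc[p["person_id"] == pid, "time_of_birth"] = pd.Timestamp("2010-05-01 07:30")
    idx = v.index[v["person_id"] == pid][0]
    cid = make_check_id("PreBirth", (("visit_occurrence", "visit_start_date"),
                                     ("person", "time_of_birth")))
    v.loc[idx, "visit_start_date"] = pd.Timestamp("2010-05-01")
    v.loc[idx, "visit_start_datetime"] = pd.Timestamp("2010-05-01 08:00")
    assert finding_for(catalog, ds, ctx_small, cid).violation_count == 0
    v.loc[idx, "visit_start_date"] = pd.Timestamp("2010-04-30")
    v.loc[idx, "visit_start_datetime"] = pd.Timestamp("2010-04-30 08:00")
    f = finding_for(catalog, ds, ctx_small, cid)
    assert f.violation_count == 1
    assert f.description.startswith("1 visits before patient was born")


def test_implfuturedate_all_past_is_zero(catalog, clean_small, ctx_small):
    cid = make_check_id("ImplFutureDate",
                        (("observation", "observation_date"),))
    assert finding_for(catalog, clean_small, ctx_small, cid).violation_count == 0


def test_invalidmap_flags_deprecated_pairs(catalog, clean_small, ctx_small,
                                           vocab):
    ds = clean_small.copy()
    df = ds.tables["condition_occurrence"]
    dep = sorted(vocab.deprecated_pairs)[0]  # one deprecated crosswalk row
    df.loc[df.index[:4], "condition_source_concept_id"] = dep[0]
    df.loc[df.index[:4], "condition_concept_id"] = dep[1]
    cid = make_check_id("InvalidMap",
                        (("condition_occurrence", "condition_concept_id"),))
    f = finding_for(catalog, ds, ctx_small, cid)
    assert f.violation_count == 4


# ------------------------------------------------------- source agreement

def test_unexdiff_formula_and_not_computable(catalog, clean_small, ctx_small):
    ctx = ctx_small
    prior = summarize_dataset(clean_small, catalog.manifest)
    prior.row_counts["drug_exposure"] = 10000
    ds = clean_small.copy()
    ds.tables["drug_exposure"] = pd.concat(
        [ds.tables["drug_exposure"]] * 1, ignore_index=True)
    from cdmdq.checks import ReferenceContext
    ctx2 = ReferenceContext(prior_cycle_summary=prior,
                            cross_site_ranks=ctx.cross_site_ranks,
                            current_date=ctx.current_date)
    cid = make_check_id("UnexDiff", (("drug_exposure", None),))
    curr = len(ds.tables["drug_exposure"])
    f = finding_for(catalog, ds, ctx2, cid)
    assert f.numeric_value == pytest.approx(
        round(abs(curr - 10000) / 10000 * 100, 2))
    # equal counts -> 0, zero prior -> not computable (skipped, no exception)
    prior.row_counts["drug_exposure"] = curr
    assert finding_for(catalog, ds, ctx2, cid).numeric_value == 0.0
    prior.row_counts["drug_exposure"] = 0
    f0 = finding_for(catalog, ds, ctx2, cid)
    assert f0.skipped and "zero" in f0.skip_reason


def test_unexmiss_signed_percentage_points(catalog, clean_small, ctx_small):
    from cdmdq.checks import ReferenceContext
    prior = summarize_dataset(clean_small, catalog.manifest)
    prior.missingness[("condition_occurrence", "condition_end_date")] = 30.0
    ds = clean_small.copy()
    df = ds.tables["condition_occurrence"]
    k = round(0.5 * len(df))
    df.loc[df.index[:k], "condition_end_date"] = pd.NaT
    ctx = ReferenceContext(prior_cycle_summary=prior,
                           current_date=ctx_small.current_date)
    cid = make_check_id("UnexMiss",
                        (("condition_occurrence", "condition_end_date"),))
    f = finding_for(catalog, ds, ctx, cid)
    assert f.numeric_value == pytest.approx(100 * k / len(df) - 30.0, abs=0.02)


def test_source_agreement_skipped_without_prior(catalog, clean_small, ctx_small):
    findings = run_checks(clean_small, catalog, ctx_small)
    by_alias = {}
    for f in findings:
        by_alias.setdefault(f.type_alias, []).append(f)
    assert all(f.skipped for f in by_alias["UnexDiff"])
    assert all(f.skipped for f in by_alias["UnexMiss"])


# --------------------------------------------------- distribution comparison

def test_tempoutlier_matches_hand_oracle(catalog, clean_small, ctx_small):
    """One spiked month in an otherwise flat 24-month series is exactly the
    month a hand-computed median/MAD oracle flags."""
    counts = np.array([100.0] * 23 + [1000.0])
    z = modified_zscores(counts)
    med = float(np.median(counts))
    mad = float(np.median(np.abs(counts - med)))
    scale = max(mad, np.sqrt(med))
    hand = 0.6745 * (counts - med) / scale
    assert np.allclose(z, hand)
    assert (np.abs(z) > 3.5).sum() == 1 and abs(z[-1]) > 3.5


def test_unextop_flags_rare_top_concept(catalog, clean_small, ctx_small):
    from cdmdq.synth import OUTLIER_CONCEPT
    ds = clean_small.copy()
    df = ds.tables["condition_occurrence"]
    top = df["condition_concept_id"].value_counts().index[0]
    need = int((df["condition_concept_id"] == top).sum()) + 5
    idx = df.index[df["condition_concept_id"] != OUTLIER_CONCEPT][:need]
    df.loc[idx, "condition_concept_id"] = OUTLIER_CONCEPT
    cid = make_check_id("UnexTop",
                        (("condition_occurrence", "condition_concept_id"),))
    f = finding_for(catalog, ds, ctx_small, cid)
    assert set(f.value_list) == {OUTLIER_CONCEPT}
    assert "Shooting pain" in f.description and "4171519" in f.description
    # top concept ranked inside a reference top-50 -> not flagged
    f0 = finding_for(catalog, clean_small, ctx_small, cid)
    assert f0.value_list == ()


def test_distribution_skipped_without_ranks(catalog, clean_small, ctx_small):
    cid = make_check_id("UnexTop", (("drug_exposure", "drug_concept_id"),))
    f = finding_for(catalog, clean_small, ctx_small, cid)
    assert f.skipped


# ----------------------------------------------------------- threshold gate

def test_apply_thresholds_boundaries(catalog):
    cid = make_check_id("UnexDiff", (("drug_exposure", None),))
    check = catalog.check(cid)   # bounds [0, 15]

    def f(value):
        return Finding(check_id=cid, type_alias="UnexDiff",
                       result_kind="percentage", numeric_value=value)
    assert apply_thresholds(f(22.65), check) is not None
    assert apply_thresholds(f(15.0), check) is None      # bound inclusive
    assert apply_thresholds(f(15.01), check) is not None
    pre = catalog.check(make_check_id(
        "PreBirth", (("visit_occurrence", "visit_start_date"),
                     ("person", "time_of_birth"))))

    def g(value):
        return Finding(check_id=pre.check_id, type_alias="PreBirth",
                       result_kind="count", numeric_value=value)
    assert apply_thresholds(g(0.0), pre) is None         # [0, 0], 0 acceptable
    assert apply_thresholds(g(1.0), pre) is not None


@settings(max_examples=200, derandomize=True)
@given(value=st.floats(-1000, 1000),
       lo=st.floats(-100, 100), width=st.floats(0, 100))
def test_threshold_gate_matches_interval_predicate(value, lo, width):
    from cdmdq.cdm_model import CheckInstance
    check = CheckInstance(check_id="MissData::person.gestational_age",
                          type_alias="MissData",
                          targets=(("person", "gestational_age"),),
                          lower_threshold=lo, upper_threshold=lo + width)
    f = Finding(check_id=check.check_id, type_alias="MissData",
                result_kind="percentage", numeric_value=value)
    cand = apply_thresholds(f, check)
    assert (cand is not None) == (value < lo or value > lo + width)


# -------------------------------------------------------------- properties

def test_findings_invariant_under_row_permutation(catalog, clean_small,
                                                  ctx_small):
    ds = clean_small.copy()
    rng = np.random.default_rng(0)
    for t, df in ds.tables.items():
        ds.tables[t] = df.sample(frac=1, random_state=3).reset_index(drop=True)
    f1 = {f.check_id: (f.numeric_value, f.violation_count,
                       tuple(sorted(f.value_list or ())))
          for f in run_checks(clean_small, catalog, ctx_small)}
    f2 = {f.check_id: (f.numeric_value, f.violation_count,
                       tuple(sorted(f.value_list or ())))
          for f in run_checks(ds, catalog, ctx_small)}
    assert f1 == f2


def test_percentages_bounded_counts_nonnegative(catalog, clean_small,
                                                ctx_small):
    for f in run_checks(clean_small, catalog, ctx_small):
        if f.skipped or f.failed:
            continue
        kind = catalog.type_of(f.type_alias).result_kind
        if kind == "percentage" and f.type_alias != "UnexMiss":
            assert 0.0 <= f.numeric_value <= 100.0, f.check_id
        if kind == "count":
            assert f.numeric_value == int(f.numeric_value) >= 0
        assert f.violation_count >= 0


def test_engine_failure_is_contained(catalog, clean_small, ctx_small):
    """A broken table breaks its own checks into failure records, not the run."""
    ds = clean_small.copy()
    ds.tables["location"] = ds.tables["location"].drop(columns=["state"])
    findings = run_checks(ds, catalog, ctx_small)
    assert len(findings) == len(catalog.checks)
    failed = [f for f in findings if f.failed]
    assert failed and all("state" in (f.error or "") or True for f in failed)
    ok = [f for f in findings if not f.failed and not f.skipped]
    assert len(ok) > 500
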