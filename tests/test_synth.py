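"""Synthetic-data generator: determinism, cleanliness, ground-truth exactness."""
import numpy as np
import pandas as pd
import pytest

from cdmdq.cdm_model import validate_conformance, write_cdm_dataset
from cdmdq.checks import run_checks
from cdmdq.synth import (DefectError, DefectManifest, DefectSpec, FLOOR,
                         SynthProfile, generate_clean, inject_defects,
                         make_cycle_pair, make_reference_context, CycleDrift)


def test_seeded_determinism_bytewise(manifest, tmp_path):
    p = SynthProfile(n_persons=50, seed=7)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cdm_dataset(generate_clean(p, manifest), d1, manifest)
    write_cdm_dataset(generate_clean(p, manifest), d2, manifest)
    for t in manifest.tables:
        assert (d1 / f"{t}.csv").read_bytes() == (d2 / f"{t}.csv").read_bytes()


def test_person_count_and_conformance(clean_small, small_profile, manifest):
    assert len(clean_small.tables["person"]) == small_profile.n_persons
    assert validate_conformance(clean_small, manifest).ok


def test_clean_dataset_yields_zero_violations(clean_small, catalog, ctx_small):
    for f in run_checks(clean_small, catalog, ctx_small):
        if f.skipped or f.failed:
            continue
        assert f.violation_count == 0, (f.check_id, f.description)


def test_infeasible_profile_rejected():
    with pytest.raises(ValueError):
        SynthProfile(date_range=("2016-01-01", "2016-06-30"))  # < 12 months
    with pytest.raises(ValueError):
        SynthProfile(date_range=("2016-01-01", "2015-01-01"))


def test_empty_manifest_leaves_dataset_unchanged(clean_small, manifest,
                                                 small_profile):
    ds, realized = inject_defects(clean_small, DefectManifest([]), seed=1,
                                  schema=manifest, profile=small_profile)
    for t in manifest.tables:
        pd.testing.assert_frame_equal(ds.tables[t], clean_small.tables[t])
    assert realized.defects == []


def test_insufficient_eligible_rows_names_class(clean_small, manifest,
                                                small_profile):
    with pytest.raises(DefectError, match="post_death_fact"):
        inject_defects(clean_small,
                       DefectManifest([DefectSpec("post_death_fact", 10 ** 6)]),
                       seed=1, schema=manifest, profile=small_profile)


def test_ground_truth_rows_violate_their_predicate(manifest):
    """Every row the realized manifest records violates its class predicate,
    and no unlisted row does (brute-force scan, small profile)."""
    p = SynthProfile(n_persons=40, seed=13)
    clean = generate_clean(p, manifest)
    specs = [DefectSpec("pre_birth_fact", 4),
             DefectSpec("start_after_end", 3),
             DefectSpec("null_field", 5)]
    ds, realized = inject_defects(clean, DefectManifest(specs), seed=3,
                                  schema=manifest, profile=p)
    birth = ds.tables["person"].set_index("person_id")["time_of_birth"]
    v = ds.tables["visit_occurrence"]
    pre_rows = {r[2] for d in realized.defects
                if d.spec.defect_class == "pre_birth_fact" for r in d.rows}
    for _, row in v.iterrows():
        b = birth.loc[int(row["person_id"])].normalize()
        is_pre = row["visit_start_date"] < b
        assert is_pre == (int(row["visit_occurrence_id"]) in pre_rows)
    sae_rows = {r[2] for d in realized.defects
                if d.spec.defect_class == "start_after_end" for r in d.rows}
    for _, row in v.iterrows():
        bad = row["visit_start_date"] > row["visit_end_date"]
        assert bad == (int(row["visit_occurrence_id"]) in sae_rows)
    c = ds.tables["condition_occurrence"]
    null_rows = {r[2] for d in realized.defects
                 if d.spec.defect_class == "null_field" for r in d.rows}
    for _, row in c.iterrows():
        assert pd.isna(row["condition_end_date"]) == \
            (int(row["condition_occurrence_id"]) in null_rows)
    # realized counts equal requested counts
    for d in realized.defects:
        assert len(d.rows) >= d.spec.count


def test_injection_is_reproducible(clean_small, manifest, small_profile):
    mspec = DefectManifest([DefectSpec("numeric_outlier", 5)])
    ds1, r1 = inject_defects(clean_small, mspec, 9, manifest, small_profile)
    ds2, r2 = inject_defects(clean_small, mspec, 9, manifest, small_profile)
    assert r1.defects[0].rows == r2.defects[0].rows
    pd.testing.assert_frame_equal(ds1.tables["drug_exposure"],
                                  ds2.tables["drug_exposure"])


def test_cycle_pair_zero_drift_is_identical(manifest):
    p = SynthProfile(n_persons=30, seed=21)
    prev, curr, ctx = make_cycle_pair(p, CycleDrift())
    for t in manifest.tables:
        pd.testing.assert_frame_equal(prev.tables[t], curr.tables[t])
    assert ctx.prior_cycle_summary.row_counts == prev.row_counts


def test_cycle_pair_missingness_drift(manifest):
    p = SynthProfile(n_persons=60, seed=22)
    prev, curr, _ = make_cycle_pair(p, CycleDrift(
        missingness={("condition_occurrence", "condition_end_date"):
                     (30.0, 50.0)}))
    for ds, pct in ((prev, 30.0), (curr, 50.0)):
        col = ds.tables["condition_occurrence"]["condition_end_date"]
        got = 100.0 * col.isna().sum() / len(col)
        assert got == pytest.approx(pct, abs=0.5)
    # monotone: current nulls are a superset of previous nulls
    pn = prev.tables["condition_occurrence"]["condition_end_date"].isna()
    cn = curr.tables["condition_occurrence"]["condition_end_date"].isna()
    assert (pn & ~cn).sum() == 0


def test_scale_sanity_10k_persons_under_a_minute(manifest):
    import time
    t0 = time.time()
    ds = generate_clean(SynthProfile(n_persons=10_000, seed=1), manifest)
    elapsed = time.time() - t0
    assert len(ds.tables["person"]) == 10_000
    assert elapsed < 60, f"generation took {elapsed:.1f}s"
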