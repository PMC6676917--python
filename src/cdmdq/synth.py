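"""Synthetic pediatric CDM datasets with parameterized defect injection.

The generator emulates one site's submission: a cohort of children (ages 0-21
at the start of the observation window, births strictly before it), visits
with bounded-jitter monthly volumes, coded facts in five clinical domains
with standard/non-standard concept mappings drawn from the packaged
miniature vocabulary, ADT events for inpatient stays, payer rows per visit,
and a small death cohort whose facts all precede death.

A *clean* dataset passes pre-workflow conformance with zero violations and
yields zero violations on every check in the reference catalog (given
suitable reference context).  Structural guarantees, not luck, make this
hold for any seed: numeric values are clipped inside their robust fences,
monthly volumes have bounded jitter (so no month can exceed the modified-z
cutoff), every person has at least one fact per clinical domain, and every
inpatient visit has an ADT record.

:func:`inject_defects` then plants exactly the requested number of defects
of each class and returns a realized manifest recording every altered row,
the exact finding deltas each check should report, and the enumerated
cross-talk a defect class unavoidably produces (e.g. a fact dated before
the plausibility floor in a pediatric cohort is necessarily also pre-birth).
That manifest is the oracle for sensitivity/specificity testing.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cdm_model import Dataset, SchemaManifest, load_schema_manifest
from .checks import (FACT_TABLES, PriorCycleSummary, ReferenceContext,
                     Vocabulary, default_vocabulary, summarize_dataset)

DEFECT_CLASSES = (
    "pre_birth_fact", "post_death_fact", "future_date", "past_floor_date",
    "start_after_end", "date_datetime_mismatch", "null_field",
    "unmapped_concept", "invalid_vocabulary", "value_set_violation",
    "source_concept_null_disagreement", "monthly_spike", "top_rank_outlier",
    "cohort_violation", "numeric_outlier",
)

# Default target of each defect class: (table, field).
DEFAULT_TARGETS = {
    "pre_birth_fact": ("visit_occurrence", "visit_start_date"),
    "post_death_fact": ("measurement", "measurement_date"),
    "future_date": ("observation", "observation_date"),
    "past_floor_date": ("drug_exposure", "drug_exposure_start_date"),
    "start_after_end": ("visit_occurrence", "visit_end_date"),
    "date_datetime_mismatch": ("condition_occurrence", "condition_start_date"),
    "null_field": ("condition_occurrence", "condition_end_date"),
    "unmapped_concept": ("condition_occurrence", "condition_concept_id"),
    "invalid_vocabulary": ("drug_exposure", "drug_concept_id"),
    "value_set_violation": ("location", "state"),
    "source_concept_null_disagreement": ("condition_occurrence",
                                         "condition_source_value"),
    "monthly_spike": ("visit_occurrence", "visit_start_date"),
    "top_rank_outlier": ("condition_occurrence", "condition_concept_id"),
    "cohort_violation": ("person", None),
    "numeric_outlier": ("drug_exposure", "quantity"),
}

FLOOR = pd.Timestamp("2000-01-01")
OUTLIER_CONCEPT = 4171519  # "Shooting pain", rare at every reference site


class DefectError(ValueError):
    """Raised when a defect cannot be injected as requested."""


@dataclass
class SynthProfile:
    """Study conditions for one synthetic site."""

    n_persons: int = 1000
    visits_per_person_mean: float = 8.0
    facts_per_visit_mean: float = 2.0     # extra facts, spread over 5 domains
    date_range: tuple[str, str] = ("2014-01-01", "2016-12-31")
    current_date: str = "2017-01-15"
    birth_year_range: tuple[int, int] = (1996, 2013)
    death_rate: float = 0.02
    inpatient_rate: float = 0.2
    organism_rate: float = 0.1
    monthly_jitter: float = 0.1
    n_reference_sites: int = 3
    seed: int = 0

    def __post_init__(self):
        start, end = pd.Timestamp(self.date_range[0]), pd.Timestamp(self.date_range[1])
        if start >= end:
            raise ValueError("date_range start must precede end")
        if self.n_persons <= 0 or self.visits_per_person_mean < 1:
            raise ValueError("need at least one person and one visit per person")
        months = (end.year - start.year) * 12 + end.month - start.month + 1
        if months < 12:
            raise ValueError("date_range must span at least 12 months")
        self.months = months

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.date_range[0])

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.date_range[1])


def _rng(seed: int, label: str) -> np.random.Generator:
    """Per-component substream: adding a component never perturbs earlier
    draws."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Clean generation helpers


def _zipf_weights(n: int, a: float = 0.8) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** a
    return w / w.sum()


def _pool(vocab: Vocabulary, vocabulary: str = None, domain: str = None,
          standard: str = None) -> np.ndarray:
    df = vocab.concepts
    m = pd.Series(True, index=df.index)
    if vocabulary is not None:
        m &= df["vocabulary"] == vocabulary
    if domain is not None:
        m &= df["domain"] == domain
    if standard is not None:
        m &= df["standard"] == standard
    return df.loc[m, "concept_id"].to_numpy()


def _month_assignment(rng, n: int, profile: SynthProfile) -> pd.Series:
    """Assign n events to calendar months with bounded jitter around a flat
    quota.  Bounded deviations keep every clean month inside the modified-z
    cutoff of the monthly-volume outlier check."""
    months = pd.period_range(profile.start, profile.end, freq="M")
    w = 1.0 + rng.uniform(-profile.monthly_jitter, profile.monthly_jitter,
                          len(months))
    quota = np.floor(n * w / w.sum()).astype(int)
    short = n - quota.sum()
    quota[rng.choice(len(months), size=short, replace=False)] += 1
    idx = np.repeat(np.arange(len(months)), quota)
    rng.shuffle(idx)
    return months[idx]


def _dates_in_months(rng, months) -> pd.Series:
    day = rng.integers(0, 28, len(months))
    base = pd.PeriodIndex(months).to_timestamp()
    return pd.Series(base + pd.to_timedelta(day, unit="D"))


def _times(rng, dates: pd.Series, lo_h=0, hi_h=12) -> pd.Series:
    secs = rng.integers(lo_h * 3600, hi_h * 3600, len(dates))
    return dates + pd.to_timedelta(secs, unit="s")


def _condition_weights(vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    """Condition concepts with their site/reference sampling weights.  The
    designated rare outlier concept sits deep in the tail (beyond rank 50
    at every reference site)."""
    cids = np.sort(_pool(vocab, "SNOMED", "Condition"))
    order = np.argsort(cids)  # deterministic
    w = _zipf_weights(len(cids))
    # Put the outlier concept at a fixed deep-tail weight rank.
    pos = int(np.where(cids == OUTLIER_CONCEPT)[0][0])
    tail_rank = min(64, len(cids) - 2)
    ranked = list(range(len(cids)))
    ranked.remove(pos)
    ranked.insert(tail_rank, pos)
    weights = np.empty(len(cids))
    for rank, i in enumerate(ranked):
        weights[i] = w[rank]
    return cids, weights / weights.sum()


def make_reference_ranks(profile: SynthProfile,
                         vocab: Optional[Vocabulary] = None
                         ) -> dict[tuple[str, str], pd.DataFrame]:
    """Full condition-concept rankings for the reference sites.  Site-level
    rank noise is bounded (+-3 positions) so tail concepts can never drift
    into a reference top-50."""
    vocab = vocab or default_vocabulary()
    cids, weights = _condition_weights(vocab)
    base_order = np.argsort(-weights, kind="stable")
    rng = _rng(profile.seed, "reference_ranks")
    rows = []
    names = dict(zip(vocab.concepts["concept_id"], vocab.concepts["concept_name"]))
    for s in range(profile.n_reference_sites):
        jitter = np.arange(len(cids)) + rng.uniform(-3, 3, len(cids))
        order = base_order[np.argsort(jitter, kind="stable")]
        for rank, i in enumerate(order, start=1):
            rows.append((f"ref_site_{s + 1}", rank, int(cids[i]),
                         names[int(cids[i])]))
    df = pd.DataFrame(rows, columns=["site", "rank", "concept_id",
                                     "concept_name"])
    return {("condition_occurrence", "condition_concept_id"): df}


def make_reference_context(profile: SynthProfile,
                           prior: Optional[PriorCycleSummary] = None
                           ) -> ReferenceContext:
    return ReferenceContext(prior_cycle_summary=prior,
                            cross_site_ranks=make_reference_ranks(profile),
                            current_date=pd.Timestamp(profile.current_date))


# ---------------------------------------------------------------------------
# Clean dataset


def generate_clean(profile: SynthProfile,
                   manifest: Optional[SchemaManifest] = None,
                   vocab: Optional[Vocabulary] = None) -> Dataset:
    manifest = manifest or load_schema_manifest()
    vocab = vocab or default_vocabulary()
    seed = profile.seed
    n = profile.n_persons

    # ------------------------------------------------------------------ dims
    rng = _rng(seed, "dims")
    n_loc = max(60, n // 10)
    n_cs = 20
    n_prov = 50
    location = pd.DataFrame({
        "location_id": np.arange(1, n_loc + 1),
        "state": rng.choice(_vset(manifest, "location", "state"), n_loc),
        "county": rng.choice(_vset(manifest, "location", "county"), n_loc),
        "country": ["US"] * n_loc,
        "zip_band": rng.choice(_vset(manifest, "location", "zip_band"), n_loc),
        "location_type": rng.choice(_vset(manifest, "location", "location_type"), n_loc),
    })
    pos_pool = _pool(vocab, "PlaceOfService")
    care_site = pd.DataFrame({
        "care_site_id": np.arange(1, n_cs + 1),
        "place_of_service_concept_id": rng.choice(pos_pool, n_cs),
        "specialty_concept_id": rng.choice(_pool(vocab, "Specialty"), n_cs),
        "care_site_type_concept_id": rng.choice(_pool(vocab, "Type"), n_cs),
        "place_of_service_source_value": rng.choice(
            ["IP", "OP", "ED", "LAB"], n_cs),
        "place_of_service": rng.choice(
            _vset(manifest, "care_site", "place_of_service"), n_cs),
        "specialty_tier": rng.choice(
            _vset(manifest, "care_site", "specialty_tier"), n_cs),
        "active_flag": rng.choice(["Y", "N"], n_cs, p=[0.9, 0.1]),
    })
    provider = pd.DataFrame({
        "provider_id": np.arange(1, n_prov + 1),
        "specialty_concept_id": rng.choice(_pool(vocab, "Specialty"), n_prov),
        "gender_concept_id": rng.choice([8507, 8532], n_prov),
        "provider_type_concept_id": rng.choice(_pool(vocab, "Type"), n_prov),
        "specialty_source_value": rng.choice(["PEDS", "CARD", "SURG", "NEO"],
                                             n_prov),
        "gender_source_value": rng.choice(["M", "F"], n_prov),
        "year_of_graduation": rng.choice(
            _vset(manifest, "provider", "year_of_graduation"), n_prov),
        "specialty_group": rng.choice(
            _vset(manifest, "provider", "specialty_group"), n_prov),
        "active_flag": rng.choice(["Y", "N"], n_prov, p=[0.95, 0.05]),
        "npi": [f"{1000000000 + i}" for i in range(n_prov)],
        "dea": [f"AB{1000000 + i}" for i in range(n_prov)],
    })

    # --------------------------------------------------------------- persons
    rng = _rng(seed, "persons")
    y0, y1 = profile.birth_year_range
    birth_lo = pd.Timestamp(f"{y0}-01-01")
    birth_hi = min(pd.Timestamp(f"{y1}-12-31"),
                   profile.start - pd.Timedelta(days=1))
    span = (birth_hi - birth_lo).days
    birth_day = birth_lo + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")
    # day-of-month capped at 28 so the component columns always round-trip
    birth_day = pd.Series(birth_day)
    birth_day = birth_day.apply(lambda t: t.replace(day=min(t.day, 28)))
    time_of_birth = _times(rng, birth_day, 0, 24)
    gender = rng.choice([8507, 8532], n)
    race = rng.choice(_pool(vocab, "Race"), n)
    eth = rng.choice(_pool(vocab, "Ethnicity"), n)
    lang = rng.choice(_pool(vocab, "Language"), n)
    person = pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "gender_concept_id": gender,
        "race_concept_id": race,
        "ethnicity_concept_id": eth,
        "language_concept_id": lang,
        "gender_source_concept_id": np.where(gender == 8507, 44950000, 44950001),
        "race_source_concept_id": rng.choice([44950002, 44950003, 44950004], n),
        "ethnicity_source_concept_id": rng.choice([44950005, 44950006], n),
        "year_of_birth": time_of_birth.dt.year.astype(str),
        "month_of_birth": time_of_birth.dt.month.astype(str),
        "day_of_birth": time_of_birth.dt.day.astype(str),
        "time_of_birth": time_of_birth,
        "gestational_age": np.round(
            np.clip(rng.normal(38.5, 2.0, n), 31, 45), 1),
        "gender_source_value": np.where(gender == 8507, "M", "F"),
        "race_source_value": pd.Series(race).map(
            dict(zip(_pool(vocab, "Race"), ["W", "B", "A", "MR", "OT"]))),
        "ethnicity_source_value": np.where(eth == 38003563, "H", "NH"),
        "language_source_value": pd.Series(lang).map(
            dict(zip(_pool(vocab, "Language"), ["EN", "ES", "ZH", "AR"]))),
        "location_id": rng.integers(1, n_loc + 1, n),
        "birth_weight_category": rng.choice(
            _vset(manifest, "person", "birth_weight_category"), n,
            p=[0.02, 0.08, 0.8, 0.1]),
        "vital_status": "alive",
    })

    # deceased cohort: visits confined to the first two thirds of the window
    n_dead = int(round(profile.death_rate * n))
    dead_ids = rng.choice(person["person_id"].to_numpy(), n_dead, replace=False) \
        if n_dead else np.array([], dtype=int)
    dead_set = set(int(x) for x in dead_ids)
    person.loc[person["person_id"].isin(dead_set), "vital_status"] = "deceased"

    # ---------------------------------------------------------------- visits
    rng = _rng(seed, "visits")
    visits_per = 1 + rng.poisson(max(profile.visits_per_person_mean - 1, 0), n)
    person_of_visit = np.repeat(person["person_id"].to_numpy(), visits_per)
    n_visits = len(person_of_visit)
    months = _month_assignment(rng, n_visits, profile)
    start_dates = _dates_in_months(rng, months)
    # deceased persons' visits stay in the early window so death can follow
    is_dead_visit = pd.Series(person_of_visit).isin(dead_set).to_numpy()
    if is_dead_visit.any():
        cutoff = profile.start + (profile.end - profile.start) * 2 // 3
        late = is_dead_visit & (start_dates > cutoff).to_numpy()
        shift_days = (start_dates[late] - cutoff).dt.days
        start_dates.loc[late] = cutoff - pd.to_timedelta(
            shift_days % 300, unit="D")
    duration = rng.integers(0, 4, n_visits)
    end_dates = start_dates + pd.to_timedelta(duration, unit="D")
    end_dates = end_dates.clip(upper=profile.end)
    start_dt = _times(rng, start_dates, 0, 12)
    end_dt = _times(rng, end_dates, 12, 24)
    u = rng.uniform(size=n_visits)
    visit_concept = np.where(u < profile.inpatient_rate, 9201,
                             np.where(u < profile.inpatient_rate + 0.1, 9203,
                                      9202))
    src_visit = pd.Series(visit_concept).map({9201: 9290, 9202: 9291, 9203: 9292})
    visit = pd.DataFrame({
        "visit_occurrence_id": np.arange(1, n_visits + 1),
        "person_id": person_of_visit,
        "visit_concept_id": visit_concept,
        "visit_type_concept_id": rng.choice(_pool(vocab, "Type"), n_visits),
        "visit_source_concept_id": src_visit,
        "admitting_source_concept_id": rng.choice(_pool(vocab, "AdmitSource"),
                                                  n_visits),
        "discharge_to_concept_id": rng.choice(_pool(vocab, "Disposition"),
                                              n_visits),
        "visit_start_date": start_dates,
        "visit_start_datetime": start_dt,
        "visit_end_date": end_dates,
        "visit_end_datetime": end_dt,
        "provider_id": rng.integers(1, n_prov + 1, n_visits),
        "care_site_id": rng.integers(1, n_cs + 1, n_visits),
        "visit_source_value": pd.Series(visit_concept).map(
            {9201: "IP", 9202: "OP", 9203: "ED"}),
        "admitting_source_value": rng.choice(["HOME", "CLINIC", "BORN"],
                                             n_visits),
        "discharge_to_source_value": rng.choice(["HOME", "SNF", "AMA", "EXP"],
                                                n_visits),
    })

    # --------------------------------------------------------------- facts
    first_visit_idx = (visit.groupby("person_id")["visit_occurrence_id"]
                       .idxmin())

    def fact_visits(label: str, guarantee_first: bool) -> pd.DataFrame:
        """Visit rows hosting facts of one domain: one guaranteed per visit
        (conditions) or per person's first visit (other domains), plus
        Poisson extras."""
        r = _rng(seed, f"facts:{label}")
        lam = profile.facts_per_visit_mean / len(("c", "d", "p", "m", "o"))
        extra = r.poisson(lam, n_visits)
        reps = extra.copy()
        if label == "condition":
            reps += 1
        idx = np.repeat(np.arange(n_visits), reps)
        if guarantee_first and label != "condition":
            idx = np.concatenate([first_visit_idx.to_numpy(), idx])
        return visit.iloc[idx].reset_index(drop=True), r

    cond_cids, cond_w = _condition_weights(vocab)

    def fact_dates(r, host) -> pd.Series:
        """Fact dates carry their own bounded-jitter month profile (thinning
        visit months would reintroduce unbounded relative noise); deceased
        persons' facts stay on their early-window visit dates so nothing
        postdates death."""
        d = _dates_in_months(r, _month_assignment(r, len(host), profile))
        if dead_set:
            mask = host["person_id"].isin(dead_set).to_numpy()
            d[mask] = host["visit_start_date"].reset_index(drop=True)[mask]
        return d

    host, r = fact_visits("condition", True)
    m = len(host)
    concept = r.choice(cond_cids, m, p=cond_w)
    # source concept: a non-standard code whose crosswalk pair is never
    # deprecated (valid pair when one exists, unknown pair otherwise; the
    # deprecated crosswalk rows use source ids ending in 9..11, never drawn)
    icd = 44820000 + (pd.Series(concept).astype(int) - 441000) % 9
    start = fact_dates(r, host)
    end = start + pd.to_timedelta(r.integers(0, 15, m), unit="D")
    condition = pd.DataFrame({
        "condition_occurrence_id": np.arange(1, m + 1),
        "person_id": host["person_id"].to_numpy(),
        "visit_occurrence_id": host["visit_occurrence_id"].to_numpy(),
        "condition_concept_id": concept,
        "condition_type_concept_id": r.choice(_pool(vocab, "Type"), m),
        "condition_source_concept_id": icd.to_numpy(),
        "condition_status_concept_id": r.choice(_pool(vocab, "Status"), m),
        "poa_concept_id": r.choice(_pool(vocab, "POA"), m),
        "condition_start_date": start.to_numpy(),
        "condition_start_datetime": _times(r, start.reset_index(drop=True)).to_numpy(),
        "condition_end_date": end.to_numpy(),
        "condition_end_datetime": _times(r, end.reset_index(drop=True), 12, 24).to_numpy(),
        "condition_source_value": [f"ICD:{460 + int(c) % 40}.{int(c) % 10}"
                                   for c in concept],
        "condition_status_source_value": r.choice(["A", "R"], m),
        "poa_source_value": r.choice(["Y", "N", "U"], m),
        "stop_reason": r.choice(_vset(manifest, "condition_occurrence",
                                      "stop_reason"), m),
    })

    host, r = fact_visits("drug", True)
    m = len(host)
    rx = _pool(vocab, "RxNorm")
    concept = r.choice(rx, m, p=_zipf_weights(len(rx), 0.6))
    start = fact_dates(r, host)
    end = (start + pd.to_timedelta(r.integers(0, 31, m), unit="D")).clip(
        upper=profile.end)
    drug = pd.DataFrame({
        "drug_exposure_id": np.arange(1, m + 1),
        "person_id": host["person_id"].to_numpy(),
        "visit_occurrence_id": host["visit_occurrence_id"].to_numpy(),
        "drug_concept_id": concept,
        "drug_type_concept_id": r.choice(_pool(vocab, "Type"), m),
        "drug_source_concept_id": 44920000 + (concept - 1125000) % 8,
        "route_concept_id": r.choice(_pool(vocab, "Route"), m),
        "dose_unit_concept_id": r.choice(_pool(vocab, "UCUM"), m),
        "drug_exposure_start_date": start.to_numpy(),
        "drug_exposure_start_datetime": _times(r, start).to_numpy(),
        "drug_exposure_end_date": end.to_numpy(),
        "drug_exposure_end_datetime": _times(r, end, 12, 24).to_numpy(),
        "quantity": np.round(np.clip(r.normal(30, 8, m), 5, 60), 1),
        "days_supply": np.clip(np.round(r.normal(14, 5, m)), 1, 30),
        "refills": r.integers(0, 4, m).astype(float),
        "drug_source_value": [f"NDC:{int(c) % 100000:05d}" for c in concept],
        "route_source_value": r.choice(["PO", "IV", "INH", "TOP"], m),
        "dose_unit_source_value": r.choice(["mg", "mL"], m),
        "drug_type_source_value": r.choice(["RX", "ADMIN"], m),
        "sig": r.choice(["qd", "bid", "tid", "prn"], m),
    })

    host, r = fact_visits("procedure", True)
    m = len(host)
    cpt = _pool(vocab, "CPT4")
    concept = r.choice(cpt, m, p=_zipf_weights(len(cpt), 0.6))
    pdate = fact_dates(r, host)
    procedure = pd.DataFrame({
        "procedure_occurrence_id": np.arange(1, m + 1),
        "person_id": host["person_id"].to_numpy(),
        "visit_occurrence_id": host["visit_occurrence_id"].to_numpy(),
        "procedure_concept_id": concept,
        "procedure_type_concept_id": r.choice(_pool(vocab, "Type"), m),
        "procedure_source_concept_id": 44930000 + (concept - 2100000) % 5,
        "modifier_concept_id": r.choice(_pool(vocab, "Modifier"), m),
        "procedure_date": pdate.to_numpy(),
        "procedure_source_value": [f"CPT:{99200 + int(c) % 100}" for c in concept],
        "modifier_source_value": r.choice(["LT", "RT", "50"], m),
        "procedure_type_source_value": r.choice(["ORDER", "BILL"], m),
    })

    units = np.sort(_pool(vocab, "UCUM"))

    def _meas_like(label, cids_, table_prefix):
        host_, r_ = fact_visits(label, True)
        m_ = len(host_)
        concept_ = r_.choice(cids_, m_, p=_zipf_weights(len(cids_), 0.5))
        # synthetic scale keyed by the UNIT so unit-stratified fences see a
        # single bounded distribution per stratum
        ci = pd.Series(concept_).astype(int)
        ui = (ci % len(units)).to_numpy()
        mu = 50 + ui * 10
        sigma = 2 + ui % 3
        val = np.clip(r_.normal(mu, sigma), mu - 3.5 * sigma, mu + 3.5 * sigma)
        unit_ = units[ui]
        date_ = fact_dates(r_, host_)
        return host_, r_, m_, concept_, mu, sigma, val, unit_, date_

    loinc = np.sort(_pool(vocab, "LOINC", "Measurement"))
    host, r, m, concept, mu, sigma, val, unit, mdate = _meas_like(
        "measurement", loinc, "measurement")
    measurement = pd.DataFrame({
        "measurement_id": np.arange(1, m + 1),
        "person_id": host["person_id"].to_numpy(),
        "visit_occurrence_id": host["visit_occurrence_id"].to_numpy(),
        "measurement_concept_id": concept,
        "measurement_type_concept_id": r.choice(_pool(vocab, "Type"), m),
        "measurement_source_concept_id": 44940000 + (concept - 3000000) % 6,
        "operator_concept_id": r.choice(_pool(vocab, "Operator"), m),
        "unit_concept_id": unit,
        "value_as_concept_id": r.choice(_pool(vocab, "Qualifier"), m),
        "priority_concept_id": r.choice(_pool(vocab, "Priority"), m),
        "specimen_concept_id": r.choice(_pool(vocab, "Specimen"), m),
        "measurement_date": mdate.to_numpy(),
        "measurement_datetime": _times(r, mdate).to_numpy(),
        "value_as_number": np.round(val, 2),
        "range_low": np.asarray(mu - 2 * sigma, dtype=float),
        "range_high": np.asarray(mu + 2 * sigma, dtype=float),
        "measurement_source_value": [f"LAB:{int(c) % 1000}" for c in concept],
        "unit_source_value": r.choice(["kg", "cm", "/min", "mmHg"], m),
        "priority_source_value": r.choice(["R", "S"], m),
        "specimen_source_value": r.choice(["BLD", "UR"], m),
        "operator_source_value": r.choice(["=", "<", ">"], m),
        "value_source_value": [f"{v:.2f}" for v in val],
    })

    obs_pool = np.sort(np.concatenate([_pool(vocab, "SNOMED", "Observation"),
                                       _pool(vocab, "LOINC", "Observation")]))
    host, r = fact_visits("observation", True)
    m = len(host)
    concept = r.choice(obs_pool, m, p=_zipf_weights(len(obs_pool), 0.5))
    odate = fact_dates(r, host)
    observation = pd.DataFrame({
        "observation_id": np.arange(1, m + 1),
        "person_id": host["person_id"].to_numpy(),
        "visit_occurrence_id": host["visit_occurrence_id"].to_numpy(),
        "observation_concept_id": concept,
        "observation_type_concept_id": r.choice(_pool(vocab, "Type"), m),
        "observation_source_concept_id": 3900000 + concept % 4,
        "value_as_concept_id": r.choice(_pool(vocab, "Qualifier"), m),
        "qualifier_concept_id": r.choice(_pool(vocab, "Qualifier"), m),
        "unit_concept_id": units[concept % len(units)],
        "observation_date": odate.to_numpy(),
        "observation_datetime": _times(r, odate).to_numpy(),
        "value_as_number": np.round(np.clip(r.normal(5, 2, m), 0, 10), 2),
        "observation_source_value": [f"OBS:{int(c) % 1000}" for c in concept],
        "unit_source_value": r.choice(["score", "unit"], m),
        "qualifier_source_value": r.choice(["POS", "NEG"], m),
    })

    # ------------------------------------------------------------------ death
    rng = _rng(seed, "death")
    if dead_set:
        last_parts = []
        for df, col in ((visit, "visit_end_date"),
                        (condition, "condition_end_date"),
                        (drug, "drug_exposure_end_date"),
                        (procedure, "procedure_date"),
                        (measurement, "measurement_date"),
                        (observation, "observation_date")):
            sub = df[df["person_id"].isin(dead_set)]
            last_parts.append(sub.groupby("person_id")[col].max())
        last = pd.concat(last_parts, axis=1).max(axis=1)
        dd = last + pd.to_timedelta(rng.integers(1, 31, len(last)), unit="D")
        cause = rng.choice(_pool(vocab, "SNOMED", "Condition"), len(last))
        death = pd.DataFrame({
            "person_id": last.index.to_numpy(),
            "cause_concept_id": cause,
            "death_type_concept_id": rng.choice(_pool(vocab, "Type"), len(last)),
            "cause_source_concept_id": 44820000 + cause % 9,
            "death_date": dd.to_numpy(),
            "cause_source_value": [f"ICD:{798 + int(c) % 2}.0" for c in cause],
            "death_type_source_value": rng.choice(["EHR", "REG"], len(last)),
            "death_location": rng.choice(
                _vset(manifest, "death", "death_location"), len(last)),
            "autopsy_flag": rng.choice(["Y", "N", "U"], len(last)),
        }).sort_values("person_id").reset_index(drop=True)
    else:
        death = pd.DataFrame({f.field_name: pd.Series(dtype=object)
                              for f in manifest.fields_of("death")})

    # ------------------------------------------------------- adt / payer / aux
    rng = _rng(seed, "adt")
    inpatient = visit[visit["visit_concept_id"] == 9201]
    m = len(inpatient)
    adt = pd.DataFrame({
        "visit_occurrence_id": inpatient["visit_occurrence_id"].to_numpy(),
        "service_concept_id": rng.choice(_pool(vocab, "Service"), m),
        "adt_type_concept_id": rng.choice(_pool(vocab, "Type"), m),
        "discharge_disposition_concept_id": rng.choice(
            _pool(vocab, "Disposition"), m),
        "prior_service_concept_id": rng.choice(_pool(vocab, "Service"), m),
        "adt_date": inpatient["visit_start_date"].to_numpy(),
        "service_source_value": rng.choice(["GEN", "ICU", "NICU"], m),
        "adt_type_source_value": rng.choice(["ADMIT", "TRANSFER"], m),
        "unit_type": rng.choice(_vset(manifest, "adt_occurrence", "unit_type"), m),
        "bed_class": rng.choice(_vset(manifest, "adt_occurrence", "bed_class"), m),
        "admit_source": rng.choice(_vset(manifest, "adt_occurrence",
                                         "admit_source"), m),
    })

    rng = _rng(seed, "payer")
    m = n_visits
    plan_start = visit["visit_start_date"] - pd.to_timedelta(
        rng.integers(0, 300, m), unit="D")
    visit_payer = pd.DataFrame({
        "visit_occurrence_id": visit["visit_occurrence_id"].to_numpy(),
        "plan_concept_id": rng.choice(_pool(vocab, "Plan"), m),
        "plan_type_concept_id": rng.choice(_pool(vocab, "Type"), m),
        "payer_concept_id": rng.choice(_pool(vocab, "Payer"), m),
        "plan_start_date": plan_start.to_numpy(),
        "plan_source_value": rng.choice(["HMO", "PPO", "MCD"], m),
        "plan_type_source_value": rng.choice(["P", "S"], m),
        "plan_class": rng.choice(_vset(manifest, "visit_payer", "plan_class"), m),
        "coverage_type": rng.choice(_vset(manifest, "visit_payer",
                                          "coverage_type"), m),
        "plan_tier": rng.choice(_vset(manifest, "visit_payer", "plan_tier"), m),
    })

    rng = _rng(seed, "fact_relationship")
    m = min(len(measurement), len(condition), 2 * n)
    mi = rng.choice(measurement["measurement_id"].to_numpy(), m, replace=False)
    ci = rng.choice(condition["condition_occurrence_id"].to_numpy(), m,
                    replace=False)
    fact_rel = pd.DataFrame({
        "domain_concept_id_1": 21,
        "fact_id_1": mi,
        "domain_concept_id_2": 19,
        "fact_id_2": ci,
        "relationship_concept_id": 44818800,
        "relationship_polarity": "forward",
    })

    rng = _rng(seed, "organism")
    org_persons = rng.choice(person["person_id"].to_numpy(),
                             int(profile.organism_rate * n), replace=False)
    m = len(org_persons)
    org_months = _month_assignment(rng, m, profile)
    morg = pd.DataFrame({
        "person_id": np.sort(org_persons),
        "organism_concept_id": rng.choice(_pool(vocab, "SNOMED", "Organism"), m),
        "organism_type_concept_id": rng.choice(_pool(vocab, "Type"), m),
        "specimen_source_concept_id": rng.choice(_pool(vocab, "Specimen"), m),
        "specimen_date": _dates_in_months(rng, org_months).to_numpy(),
        "organism_source_value": rng.choice(["ECOLI", "SAUR", "SPNEU"], m),
        "isolation_site": rng.choice(_vset(manifest, "measurement_organism",
                                           "isolation_site"), m),
        "culture_result": rng.choice(_vset(manifest, "measurement_organism",
                                           "culture_result"), m),
    })
    # keep organism specimen dates before death for the deceased
    if dead_set:
        dd = death.set_index("person_id")["death_date"]
        lim = morg["person_id"].map(dd)
        over = lim.notna() & (morg["specimen_date"] > lim)
        morg.loc[over, "specimen_date"] = (lim[over] - pd.Timedelta(days=1)).to_numpy()

    tables = {
        "person": person, "visit_occurrence": visit,
        "condition_occurrence": condition, "drug_exposure": drug,
        "procedure_occurrence": procedure, "measurement": measurement,
        "observation": observation, "death": death, "location": location,
        "care_site": care_site, "provider": provider,
        "fact_relationship": fact_rel, "visit_payer": visit_payer,
        "adt_occurrence": adt, "measurement_organism": morg,
    }
    # normalise column order and datetime dtypes to the manifest
    out = {}
    for t in manifest.tables:
        df = tables[t].copy()
        for spec in manifest.fields_of(t):
            if spec.semantic_type in ("date", "datetime"):
                df[spec.field_name] = pd.to_datetime(df[spec.field_name])
                if spec.semantic_type == "date":
                    df[spec.field_name] = df[spec.field_name].dt.normalize()
            elif spec.semantic_type == "numeric":
                df[spec.field_name] = df[spec.field_name].astype("Float64")
            elif spec.semantic_type in ("primary_key", "foreign_key_required",
                                        "foreign_key_optional", "concept_id"):
                df[spec.field_name] = df[spec.field_name].astype("Int64")
            else:
                df[spec.field_name] = df[spec.field_name].astype(object)
        out[t] = df[[f.field_name for f in manifest.fields_of(t)]]
    return Dataset(tables=out, site="synth_site")


def _value_sets(manifest: SchemaManifest) -> dict:
    return {(f.table_name, f.field_name): list(f.value_set)
            for f in manifest.fields if f.value_set}


def _vset(manifest: SchemaManifest, table: str, fieldname: str) -> list[str]:
    return list(manifest.field(table, fieldname).value_set)


# ---------------------------------------------------------------------------
# Defect injection


@dataclass
class DefectSpec:
    """Request for one class of injected defects."""

    defect_class: str
    count: int
    table: Optional[str] = None
    field: Optional[str] = None
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.defect_class not in DEFECT_CLASSES:
            raise DefectError(f"unknown defect class {self.defect_class!r}")
        if self.count < 0:
            raise DefectError("count must be non-negative")
        default_t, default_f = DEFAULT_TARGETS[self.defect_class]
        if self.table is None:
            self.table = default_t
        if self.field is None:
            self.field = default_f


@dataclass
class DefectManifest:
    specs: list[DefectSpec]


@dataclass
class RealizedDefect:
    """Ground truth for one injected defect class.

    ``expected`` maps (alias, table, field) -> exact finding delta: an int
    for count/percentage checks, a frozenset for value-list checks.
    ``allowed`` maps (alias, table, field) -> a frozenset; the corresponding
    check may flag any subset of it (enumerated cross-talk).
    """

    spec: DefectSpec
    rows: list[tuple[str, str, int]]            # (table, pk_field, pk_value)
    expected: dict[tuple[str, str, Optional[str]], object]
    allowed: dict[tuple[str, str, Optional[str]], frozenset]


@dataclass
class RealizedManifest:
    defects: list[RealizedDefect]

    def combined_expected(self) -> dict:
        out: dict = {}
        for d in self.defects:
            for k, v in d.expected.items():
                if isinstance(v, frozenset):
                    out[k] = out.get(k, frozenset()) | v
                else:
                    out[k] = out.get(k, 0) + v
        return out

    def combined_allowed(self) -> dict:
        out: dict = {}
        for d in self.defects:
            for k, v in d.allowed.items():
                out[k] = out.get(k, frozenset()) | v
        return out


def _pk_field(manifest: SchemaManifest, table: str) -> str:
    return manifest.fields_of(table)[0].field_name


def _twin(fieldname: str) -> str:
    return fieldname + "time"  # X_date -> X_datetime


def _months_of(dates) -> frozenset:
    return frozenset(str(p) for p in pd.Series(dates).dt.to_period("M"))


def inject_defects(ds: Dataset, manifest: DefectManifest, seed: int,
                   schema: Optional[SchemaManifest] = None,
                   profile: Optional[SynthProfile] = None,
                   ) -> tuple[Dataset, RealizedManifest]:
    """Plant exactly the requested defects into a copy of a clean dataset.

    Returns the defective dataset and the realized ground-truth manifest.
    Each class draws from its own random substream, so adding a class does
    not perturb the rows chosen for another.
    """
    schema = schema or load_schema_manifest()
    profile = profile or SynthProfile()
    out = ds.copy()
    realized = []
    for spec in manifest.specs:
        if spec.count == 0:
            continue
        fn = _INJECTORS[spec.defect_class]
        rng = _rng(seed, f"defect:{spec.defect_class}")
        realized.append(fn(out, spec, rng, schema, profile))
    return out, RealizedManifest(defects=realized)


def _pick(rng, eligible_index, count, cls) -> np.ndarray:
    idx = np.asarray(list(eligible_index))
    if len(idx) < count:
        raise DefectError(
            f"insufficient eligible rows for {cls}: need {count}, "
            f"have {len(idx)}")
    return np.sort(rng.choice(idx, size=count, replace=False))


def _rows_of(df, idx, table, pk) -> list:
    if pk in df.columns:
        return [(table, pk, int(v)) for v in df.loc[idx, pk]]
    return [(table, "row", int(i)) for i in idx]


def _birth_series(ds: Dataset) -> pd.Series:
    p = ds.tables["person"]
    return p.set_index("person_id")["time_of_birth"].dt.normalize()


def _inject_pre_birth(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    birth = df["person_id"].map(_birth_series(ds))
    # keep injected dates above the plausibility floor with a year to spare
    eligible = df.index[(birth > FLOOR + pd.Timedelta(days=400))
                        & df[f].notna()]
    idx = _pick(rng, eligible, spec.count, spec.defect_class)
    offs = rng.integers(1, 301, len(idx))
    new = birth.loc[idx] - pd.to_timedelta(offs, unit="D")
    df.loc[idx, f] = new
    df.loc[idx, _twin(f)] = new + pd.Timedelta(hours=8)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("PreBirth", t, f): int(len(idx))},
        allowed={("TempOutlier", t, f): _months_of(new),
                 ("TempOutlierFact", t, None): _months_of(new)})


def _inject_post_death(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    death = df["person_id"].map(
        ds.tables["death"].set_index("person_id")["death_date"].dt.normalize()) \
        if len(ds.tables["death"]) else pd.Series(pd.NaT, index=df.index)
    current = pd.Timestamp(profile.current_date)
    eligible = df.index[death.notna()
                        & (death < current - pd.Timedelta(days=2))]
    idx = _pick(rng, eligible, spec.count, spec.defect_class)
    room = (current - death.loc[idx]).dt.days.clip(upper=30)
    offs = np.array([rng.integers(1, r + 1) for r in room])
    new = death.loc[idx] + pd.to_timedelta(offs, unit="D")
    df.loc[idx, f] = new
    df.loc[idx, _twin(f)] = new + pd.Timedelta(hours=9)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("PostDeath", t, f): int(len(idx))},
        allowed={("TempOutlier", t, f): _months_of(new)})


def _inject_future_date(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    dead = set(ds.tables["death"]["person_id"].dropna()) \
        if len(ds.tables["death"]) else set()
    eligible = df.index[df[f].notna() & ~df["person_id"].isin(dead)]
    idx = _pick(rng, eligible, spec.count, spec.defect_class)
    current = pd.Timestamp(profile.current_date)
    new = current + pd.to_timedelta(rng.integers(1, 301, len(idx)), unit="D")
    df.loc[idx, f] = pd.Series(new, index=idx)
    df.loc[idx, _twin(f)] = pd.Series(new + pd.Timedelta(hours=9), index=idx)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("ImplFutureDate", t, f): int(len(idx))},
        allowed={("TempOutlier", t, f): frozenset()})


def _inject_past_floor(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    idx = _pick(rng, df.index[df[f].notna()], spec.count, spec.defect_class)
    new = FLOOR - pd.to_timedelta(rng.integers(1, 3001, len(idx)), unit="D")
    birth = df["person_id"].map(_birth_series(ds))
    pre_birth = int((pd.Series(new, index=idx) < birth.loc[idx]).sum())
    df.loc[idx, f] = pd.Series(new, index=idx)
    df.loc[idx, _twin(f)] = pd.Series(new + pd.Timedelta(hours=9), index=idx)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        # a pediatric cohort is born after the floor, so most floor
        # violations are unavoidably pre-birth as well: exact count recorded
        expected={("ImplPastDate", t, f): int(len(idx)),
                  ("PreBirth", t, f): pre_birth},
        allowed={})


def _inject_start_after_end(ds, spec, rng, schema, profile):
    t = spec.table
    df = ds.tables[t]
    start_f, end_f = {
        "visit_occurrence": ("visit_start_date", "visit_end_date"),
        "condition_occurrence": ("condition_start_date", "condition_end_date"),
        "drug_exposure": ("drug_exposure_start_date", "drug_exposure_end_date"),
    }[t]
    birth = df["person_id"].map(_birth_series(ds))
    dead = set(ds.tables["death"]["person_id"].dropna()) \
        if len(ds.tables["death"]) else set()
    eligible = df.index[(df[start_f] - pd.Timedelta(days=31) > birth)
                        & df[start_f].notna() & df[end_f].notna()
                        & ~df["person_id"].isin(dead)]
    idx = _pick(rng, eligible, spec.count, spec.defect_class)
    new = df.loc[idx, start_f] - pd.to_timedelta(
        rng.integers(1, 31, len(idx)), unit="D")
    df.loc[idx, end_f] = new
    df.loc[idx, _twin(end_f)] = new + pd.Timedelta(hours=18)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        # both endpoint-attributed instances of the pair report the count
        expected={("ImplEvent", t, start_f): int(len(idx)),
                  ("ImplEvent", t, end_f): int(len(idx))},
        allowed={("TempOutlier", t, end_f): _months_of(new)})


def _inject_date_datetime_mismatch(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    twin = _twin(f)
    idx = _pick(rng, df.index[df[f].notna() & df[twin].notna()],
                spec.count, spec.defect_class)
    df.loc[idx, twin] = df.loc[idx, twin] + pd.Timedelta(days=1)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("InconDateTime", t, f): int(len(idx))}, allowed={})


def _inject_null_field(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    idx = _pick(rng, df.index[df[f].notna()], spec.count, spec.defect_class)
    df.loc[idx, f] = pd.NaT if schema.field(t, f).semantic_type in (
        "date", "datetime") else None
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("MissData", t, f): int(len(idx))}, allowed={})


def _inject_unmapped_concept(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    idx = _pick(rng, df.index[df[f].notna() & (df[f] != 0)],
                spec.count, spec.defect_class)
    df.loc[idx, f] = 0
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("MissConceptID", t, f): int(len(idx))}, allowed={})


def _inject_invalid_vocabulary(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    vocab = default_vocabulary()
    fspec = schema.field(t, f)
    allowed = set(fspec.allowed_vocabs or ())
    # a known concept of the right domain but a disallowed vocabulary
    cands = vocab.concepts[
        (vocab.concepts["domain"] == fspec.expected_domain)
        & ~vocab.concepts["vocabulary"].isin(allowed)]
    if cands.empty:
        raise DefectError(f"no wrong-vocabulary concept available for {t}.{f}")
    bad = int(cands["concept_id"].iloc[0])
    idx = _pick(rng, df.index[df[f].notna()], spec.count, spec.defect_class)
    df.loc[idx, f] = bad
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("InvalidVocab", t, f): int(len(idx))}, allowed={})


def _inject_value_set_violation(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    idx = _pick(rng, df.index[df[f].notna()], spec.count, spec.defect_class)
    df.loc[idx, f] = "__INVALID__"
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("InvalidValue", t, f): int(len(idx))}, allowed={})


_PRIMARY_SOURCE_FIELD = {
    "visit_occurrence": "visit_source_value",
    "condition_occurrence": "condition_source_value",
    "drug_exposure": "drug_source_value",
    "procedure_occurrence": "procedure_source_value",
    "measurement": "measurement_source_value",
    "observation": "observation_source_value",
    "person": "gender_source_value",
    "death": "cause_source_value",
    "provider": "specialty_source_value",
    "care_site": "place_of_service_source_value",
    "visit_payer": "plan_source_value",
    "adt_occurrence": "service_source_value",
    "measurement_organism": "organism_source_value",
}


def _inconsource_partners(schema: SchemaManifest, table: str,
                          source_field: str) -> list[str]:
    """Concept fields whose source/concept agreement pair resolves to this
    source-value column (mirrors the catalog's pairing rule)."""
    out = []
    for fs in schema.fields_of(table):
        if fs.semantic_type != "concept_id":
            continue
        base = fs.field_name[: -len("_concept_id")]
        if schema.has_field(table, base + "_source_value"):
            partner = base + "_source_value"
        elif base.endswith("_source") and schema.has_field(table, base + "_value"):
            partner = base + "_value"
        else:
            partner = _PRIMARY_SOURCE_FIELD[table]
        if partner == source_field:
            out.append(fs.field_name)
    return out


def _inject_source_null_disagreement(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    base = f[: -len("_source_value")]
    concept_f = base + "_concept_id"
    eligible = df.index[df[f].notna() & df[concept_f].notna()
                        & (df[concept_f] != 0)]
    idx = _pick(rng, eligible, spec.count, spec.defect_class)
    df.loc[idx, f] = None
    pk = _pk_field(schema, t)
    # the source-attributed instance plus every concept-attributed instance
    # whose agreement pair resolves to this source column report the count
    expected = {("InconSource", t, f): int(len(idx))}
    for cf in _inconsource_partners(schema, t, f):
        expected[("InconSource", t, cf)] = int(len(idx))
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected=expected, allowed={})


def _inject_numeric_outlier(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    idx = _pick(rng, df.index[df[f].notna()], spec.count, spec.defect_class)
    med = float(df[f].dropna().astype(float).median())
    df.loc[idx, f] = np.round(med * 10 + rng.uniform(0, 100, len(idx)), 1)
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("NumOutlier", t, f): int(len(idx))}, allowed={})


def _inject_top_rank_outlier(ds, spec, rng, schema, profile):
    t, f = spec.table, spec.field
    df = ds.tables[t]
    if spec.count != 1:
        raise DefectError("top_rank_outlier supports count=1 (the site's "
                          "top-ranked value is a single concept)")
    counts = df.loc[df[f].notna() & (df[f] != 0), f].value_counts()
    top_count = int(counts.iloc[0])
    have = int(counts.get(OUTLIER_CONCEPT, 0))
    need = top_count - have + 10
    eligible = df.index[df[f].notna() & (df[f] != OUTLIER_CONCEPT)]
    idx = _pick(rng, eligible, need, spec.defect_class)
    df.loc[idx, f] = OUTLIER_CONCEPT
    pk = _pk_field(schema, t)
    return RealizedDefect(
        spec=spec, rows=_rows_of(df, idx, t, pk),
        expected={("UnexTop", t, f): frozenset({OUTLIER_CONCEPT})},
        allowed={})


def _inject_monthly_spike(ds, spec, rng, schema, profile):
    """Duplicate visits (with their facts) into `count` target months so each
    becomes a volume outlier."""
    t, f = spec.table, spec.field
    visits = ds.tables[t]
    months = pd.period_range(profile.start, profile.end, freq="M")
    interior = months[2:-2]
    if spec.count > len(interior):
        raise DefectError("monthly_spike: more target months than interior "
                          "months available")
    targets = pd.PeriodIndex(
        sorted(rng.choice(interior, size=spec.count, replace=False)))
    monthly = visits[f].dt.to_period("M").value_counts()
    med = float(monthly.median())
    # a doubling (plus Poisson-scale margin) clears the outlier cutoff
    boost = int(np.ceil(med + 8 * np.sqrt(med)))
    rows: list = []
    new_visit_frames = []
    fact_frames: dict[str, list] = {ft: [] for ft in FACT_TABLES}
    adt_frames, payer_frames = [], []
    next_visit_id = int(visits["visit_occurrence_id"].max()) + 1
    next_fact_id = {ft: int(ds.tables[ft].iloc[:, 0].max()) + 1
                    for ft in FACT_TABLES}
    dead = set(ds.tables["death"]["person_id"].dropna()) \
        if len(ds.tables["death"]) else set()
    for month in targets:
        src_ok = visits.index[(visits[f].dt.to_period("M") != month)
                              & ~visits["person_id"].isin(dead)]
        src_idx = rng.choice(src_ok, size=boost, replace=False)
        dup = visits.loc[src_idx].copy()
        old_ids = dup["visit_occurrence_id"].to_numpy()
        dup["visit_occurrence_id"] = np.arange(next_visit_id,
                                               next_visit_id + boost)
        id_map = dict(zip(old_ids, dup["visit_occurrence_id"]))
        next_visit_id += boost
        vmap_start: dict = {}
        new_start = _dates_in_months(rng, [month] * boost)
        dur = (dup["visit_end_date"].to_numpy()
               - dup["visit_start_date"].to_numpy())
        dup["visit_start_date"] = new_start.to_numpy()
        dup["visit_end_date"] = (new_start + pd.Series(dur)).to_numpy()
        dup["visit_start_datetime"] = (new_start + pd.Timedelta(hours=8)).to_numpy()
        dup["visit_end_datetime"] = (dup["visit_end_date"]
                                     + pd.Timedelta(hours=18)).to_numpy()
        vmap_start.update(zip(dup["visit_occurrence_id"],
                              dup["visit_start_date"]))
        new_visit_frames.append(dup)
        rows += [(t, "visit_occurrence_id", int(v))
                 for v in dup["visit_occurrence_id"]]
        # duplicate the facts of the duplicated visits into the same month
        for ft in FACT_TABLES:
            fdf = ds.tables[ft]
            sub = fdf[fdf["visit_occurrence_id"].isin(id_map)].copy()
            if sub.empty:
                continue
            pk = sub.columns[0]
            sub[pk] = np.arange(next_fact_id[ft], next_fact_id[ft] + len(sub))
            next_fact_id[ft] += len(sub)
            sub["visit_occurrence_id"] = sub["visit_occurrence_id"].map(id_map)
            for col in sub.columns:
                fs = schema.field(ft, col)
                if fs.semantic_type == "date":
                    sub[col] = sub["visit_occurrence_id"].map(vmap_start)
                elif fs.semantic_type == "datetime":
                    sub[col] = sub["visit_occurrence_id"].map(vmap_start) \
                        + pd.Timedelta(hours=9)
            fact_frames[ft].append(sub)
        # ADT rows for duplicated inpatient stays keep visit types consistent
        adt = ds.tables["adt_occurrence"]
        asub = adt[adt["visit_occurrence_id"].isin(id_map)].copy()
        if not asub.empty:
            asub["visit_occurrence_id"] = asub["visit_occurrence_id"].map(id_map)
            asub["adt_date"] = asub["visit_occurrence_id"].map(vmap_start)
            adt_frames.append(asub)
        payer = ds.tables["visit_payer"]
        psub = payer[payer["visit_occurrence_id"].isin(id_map)].copy()
        if not psub.empty:
            psub["visit_occurrence_id"] = psub["visit_occurrence_id"].map(id_map)
            payer_frames.append(psub)
    ds.tables[t] = pd.concat([visits] + new_visit_frames, ignore_index=True)
    for ft in FACT_TABLES:
        if fact_frames[ft]:
            ds.tables[ft] = pd.concat([ds.tables[ft]] + fact_frames[ft],
                                      ignore_index=True)
    if adt_frames:
        ds.tables["adt_occurrence"] = pd.concat(
            [ds.tables["adt_occurrence"]] + adt_frames, ignore_index=True)
    if payer_frames:
        ds.tables["visit_payer"] = pd.concat(
            [ds.tables["visit_payer"]] + payer_frames, ignore_index=True)
    target_set = frozenset(str(m) for m in targets)
    allowed = {}
    date_fields = {
        "condition_occurrence": ["condition_start_date", "condition_end_date"],
        "drug_exposure": ["drug_exposure_start_date", "drug_exposure_end_date"],
        "measurement": ["measurement_date"],
        "observation": ["observation_date"],
    }
    for ft, cols in date_fields.items():
        for col in cols:
            allowed[("TempOutlier", ft, col)] = target_set
    for ft in ("visit_occurrence", "condition_occurrence", "drug_exposure",
               "procedure_occurrence"):
        allowed[("TempOutlierFact", ft, None)] = target_set
    allowed[("TempOutlier", t, "visit_end_date")] = target_set
    return RealizedDefect(
        spec=spec, rows=rows,
        expected={("TempOutlier", t, f): target_set},
        allowed=allowed)


def _inject_cohort_violation(ds, spec, rng, schema, profile):
    """Add persons whose first (outpatient) visit falls at age 22-28."""
    n = spec.count
    person = ds.tables["person"]
    visits = ds.tables["visit_occurrence"]
    vocab = default_vocabulary()
    pid0 = int(person["person_id"].max()) + 1
    vid0 = int(visits["visit_occurrence_id"].max()) + 1
    pids = np.arange(pid0, pid0 + n)
    months = pd.period_range(profile.start, profile.end, freq="M")[1:-1]
    vdates = _dates_in_months(rng, rng.choice(months, n))
    age_days = rng.integers(int(22.2 * 365.25), int(28.5 * 365.25), n)
    birth = (vdates - pd.to_timedelta(age_days, unit="D")).apply(
        lambda ts: ts.replace(day=min(ts.day, 28)))
    tob = birth + pd.Timedelta(hours=6)
    gender = rng.choice([8507, 8532], n)
    newp = pd.DataFrame({
        "person_id": pids, "gender_concept_id": gender,
        "race_concept_id": rng.choice(_pool(vocab, "Race"), n),
        "ethnicity_concept_id": rng.choice(_pool(vocab, "Ethnicity"), n),
        "language_concept_id": rng.choice(_pool(vocab, "Language"), n),
        "gender_source_concept_id": np.where(gender == 8507, 44950000, 44950001),
        "race_source_concept_id": rng.choice([44950002, 44950003, 44950004], n),
        "ethnicity_source_concept_id": rng.choice([44950005, 44950006], n),
        "year_of_birth": tob.dt.year.astype(str),
        "month_of_birth": tob.dt.month.astype(str),
        "day_of_birth": tob.dt.day.astype(str),
        "time_of_birth": tob,
        "gestational_age": np.round(np.clip(rng.normal(38.5, 2.0, n), 31, 45), 1),
        "gender_source_value": np.where(gender == 8507, "M", "F"),
        "race_source_value": "W", "ethnicity_source_value": "NH",
        "language_source_value": "EN",
        "location_id": rng.integers(1, len(ds.tables["location"]) + 1, n),
        "birth_weight_category": "normal", "vital_status": "alive",
    })
    newv = pd.DataFrame({
        "visit_occurrence_id": np.arange(vid0, vid0 + n),
        "person_id": pids, "visit_concept_id": 9202,
        "visit_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "visit_source_concept_id": 9291,
        "admitting_source_concept_id": rng.choice(_pool(vocab, "AdmitSource"), n),
        "discharge_to_concept_id": rng.choice(_pool(vocab, "Disposition"), n),
        "visit_start_date": vdates.to_numpy(),
        "visit_start_datetime": (vdates + pd.Timedelta(hours=8)).to_numpy(),
        "visit_end_date": vdates.to_numpy(),
        "visit_end_datetime": (vdates + pd.Timedelta(hours=17)).to_numpy(),
        "provider_id": rng.integers(1, len(ds.tables["provider"]) + 1, n),
        "care_site_id": rng.integers(1, len(ds.tables["care_site"]) + 1, n),
        "visit_source_value": "OP",
        "admitting_source_value": "HOME", "discharge_to_source_value": "HOME",
    })
    ds.tables["person"] = pd.concat([person, newp], ignore_index=True)
    ds.tables["visit_occurrence"] = pd.concat([visits, newv], ignore_index=True)

    # one fact per clinical domain so the new persons trip no presence check
    def one_per(ft, builder):
        df = ds.tables[ft]
        pk = df.columns[0]
        fid0 = int(df[pk].max()) + 1
        add = builder(np.arange(fid0, fid0 + n))
        ds.tables[ft] = pd.concat([df, add], ignore_index=True)

    cond_cids, cond_w = _condition_weights(vocab)
    one_per("condition_occurrence", lambda ids: pd.DataFrame({
        "condition_occurrence_id": ids, "person_id": pids,
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "condition_concept_id": rng.choice(cond_cids[:20], n, p=cond_w[:20] / cond_w[:20].sum()),
        "condition_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "condition_source_concept_id": 44820000 + rng.integers(0, 9, n),
        "condition_status_concept_id": rng.choice(_pool(vocab, "Status"), n),
        "poa_concept_id": rng.choice(_pool(vocab, "POA"), n),
        "condition_start_date": vdates.to_numpy(),
        "condition_start_datetime": (vdates + pd.Timedelta(hours=9)).to_numpy(),
        "condition_end_date": vdates.to_numpy(),
        "condition_end_datetime": (vdates + pd.Timedelta(hours=16)).to_numpy(),
        "condition_source_value": "ICD:460.0",
        "condition_status_source_value": "A", "poa_source_value": "N",
        "stop_reason": "resolved",
    }))
    rx = _pool(vocab, "RxNorm")
    one_per("drug_exposure", lambda ids: pd.DataFrame({
        "drug_exposure_id": ids, "person_id": pids,
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "drug_concept_id": rng.choice(rx, n),
        "drug_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "drug_source_concept_id": 44920000 + rng.integers(0, 8, n),
        "route_concept_id": rng.choice(_pool(vocab, "Route"), n),
        "dose_unit_concept_id": rng.choice(_pool(vocab, "UCUM"), n),
        "drug_exposure_start_date": vdates.to_numpy(),
        "drug_exposure_start_datetime": (vdates + pd.Timedelta(hours=9)).to_numpy(),
        "drug_exposure_end_date": vdates.to_numpy(),
        "drug_exposure_end_datetime": (vdates + pd.Timedelta(hours=16)).to_numpy(),
        "quantity": np.round(np.clip(rng.normal(30, 8, n), 5, 60), 1),
        "days_supply": np.clip(np.round(rng.normal(14, 5, n)), 1, 30),
        "refills": rng.integers(0, 4, n).astype(float),
        "drug_source_value": "NDC:00001", "route_source_value": "PO",
        "dose_unit_source_value": "mg", "drug_type_source_value": "RX",
        "sig": "qd",
    }))
    cpt = _pool(vocab, "CPT4")
    one_per("procedure_occurrence", lambda ids: pd.DataFrame({
        "procedure_occurrence_id": ids, "person_id": pids,
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "procedure_concept_id": rng.choice(cpt, n),
        "procedure_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "procedure_source_concept_id": 44930000 + rng.integers(0, 5, n),
        "modifier_concept_id": rng.choice(_pool(vocab, "Modifier"), n),
        "procedure_date": vdates.to_numpy(),
        "procedure_source_value": "CPT:99213", "modifier_source_value": "LT",
        "procedure_type_source_value": "BILL",
    }))
    loinc = np.sort(_pool(vocab, "LOINC", "Measurement"))
    units = np.sort(_pool(vocab, "UCUM"))
    mcid = rng.choice(loinc, n)
    mu = 50 + (mcid % len(units)) * 10
    one_per("measurement", lambda ids: pd.DataFrame({
        "measurement_id": ids, "person_id": pids,
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "measurement_concept_id": mcid,
        "measurement_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "measurement_source_concept_id": 44940000 + (mcid - 3000000) % 6,
        "operator_concept_id": rng.choice(_pool(vocab, "Operator"), n),
        "unit_concept_id": units[mcid % len(units)],
        "value_as_concept_id": rng.choice(_pool(vocab, "Qualifier"), n),
        "priority_concept_id": rng.choice(_pool(vocab, "Priority"), n),
        "specimen_concept_id": rng.choice(_pool(vocab, "Specimen"), n),
        "measurement_date": vdates.to_numpy(),
        "measurement_datetime": (vdates + pd.Timedelta(hours=9)).to_numpy(),
        "value_as_number": np.asarray(mu, dtype=float),
        "range_low": np.asarray(mu - 4, dtype=float),
        "range_high": np.asarray(mu + 4, dtype=float),
        "measurement_source_value": "LAB:001", "unit_source_value": "kg",
        "priority_source_value": "R", "specimen_source_value": "BLD",
        "operator_source_value": "=", "value_source_value": "0",
    }))
    obs_pool = np.sort(np.concatenate([_pool(vocab, "SNOMED", "Observation"),
                                       _pool(vocab, "LOINC", "Observation")]))
    ocid = rng.choice(obs_pool, n)
    one_per("observation", lambda ids: pd.DataFrame({
        "observation_id": ids, "person_id": pids,
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "observation_concept_id": ocid,
        "observation_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "observation_source_concept_id": 3900000 + ocid % 4,
        "value_as_concept_id": rng.choice(_pool(vocab, "Qualifier"), n),
        "qualifier_concept_id": rng.choice(_pool(vocab, "Qualifier"), n),
        "unit_concept_id": units[ocid % len(units)],
        "observation_date": vdates.to_numpy(),
        "observation_datetime": (vdates + pd.Timedelta(hours=9)).to_numpy(),
        "value_as_number": np.round(np.clip(rng.normal(5, 2, n), 0, 10), 2),
        "observation_source_value": "OBS:001", "unit_source_value": "score",
        "qualifier_source_value": "POS",
    }))
    payer = ds.tables["visit_payer"]
    ds.tables["visit_payer"] = pd.concat([payer, pd.DataFrame({
        "visit_occurrence_id": newv["visit_occurrence_id"].to_numpy(),
        "plan_concept_id": rng.choice(_pool(vocab, "Plan"), n),
        "plan_type_concept_id": rng.choice(_pool(vocab, "Type"), n),
        "payer_concept_id": rng.choice(_pool(vocab, "Payer"), n),
        "plan_start_date": vdates.to_numpy(),
        "plan_source_value": "HMO", "plan_type_source_value": "P",
        "plan_class": "commercial", "coverage_type": "primary",
        "plan_tier": "gold",
    })], ignore_index=True)
    return RealizedDefect(
        spec=spec,
        rows=[("person", "person_id", int(p)) for p in pids],
        expected={("InconCohort", "person", None): n},
        allowed={})


_INJECTORS = {
    "pre_birth_fact": _inject_pre_birth,
    "post_death_fact": _inject_post_death,
    "future_date": _inject_future_date,
    "past_floor_date": _inject_past_floor,
    "start_after_end": _inject_start_after_end,
    "date_datetime_mismatch": _inject_date_datetime_mismatch,
    "null_field": _inject_null_field,
    "unmapped_concept": _inject_unmapped_concept,
    "invalid_vocabulary": _inject_invalid_vocabulary,
    "value_set_violation": _inject_value_set_violation,
    "source_concept_null_disagreement": _inject_source_null_disagreement,
    "monthly_spike": _inject_monthly_spike,
    "top_rank_outlier": _inject_top_rank_outlier,
    "cohort_violation": _inject_cohort_violation,
    "numeric_outlier": _inject_numeric_outlier,
}


def ground_truth_json(realized: RealizedManifest) -> str:
    def key(k):
        alias, table, fieldname = k
        return f"{alias}::{table}" + (f".{fieldname}" if fieldname else "")
    payload = {
        "defects": [{
            "class": d.spec.defect_class, "table": d.spec.table,
            "field": d.spec.field, "count": d.spec.count,
            "rows": [list(r) for r in d.rows],
            "expected": {key(k): (sorted(v) if isinstance(v, frozenset) else v)
                         for k, v in d.expected.items()},
            "allowed_crosstalk": {key(k): sorted(v)
                                  for k, v in d.allowed.items()},
        } for d in realized.defects],
    }
    return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# Cycle pairs


@dataclass
class CycleDrift:
    """Controlled differences between two consecutive cycles."""

    table_growth: dict[str, float] = dc_field(default_factory=dict)
    missingness: dict[tuple[str, str], tuple[float, float]] = \
        dc_field(default_factory=dict)


def make_cycle_pair(profile: SynthProfile, drift: CycleDrift,
                    schema: Optional[SchemaManifest] = None,
                    ) -> tuple[Dataset, Dataset, ReferenceContext]:
    """Two datasets for consecutive cycles with the requested drift.

    Growth by an exact rational factor (e.g. 1.2265) is realized exactly:
    the previous cycle's table is trimmed to a row count on which the factor
    is integral, and the current cycle duplicates rows (fresh keys, dates
    redistributed) to hit the product.  Missingness drift nulls a monotone
    superset of rows, so the current cycle's nulls contain the previous
    cycle's.
    """
    schema = schema or load_schema_manifest()
    prev = generate_clean(profile, schema)
    rng = _rng(profile.seed, "cycle_pair")

    for table, factor in drift.table_growth.items():
        frac = factor - 1.0
        # trim so that frac * n is integral at 4 decimal places of the factor
        from fractions import Fraction
        fr = Fraction(round(frac * 10000), 10000)
        df = prev.tables[table]
        n = len(df)
        denom = fr.denominator
        keep = n - (n % denom)
        if keep <= 0:
            raise ValueError(f"table {table} too small for exact growth")
        if keep < n:
            drop_n = n - keep
            # trim rows from persons holding several rows, so no presence
            # check changes, and avoid rows referenced by fact_relationship
            refs = set()
            fr_df = prev.tables["fact_relationship"]
            pkcol = df.columns[0]
            refs.update(fr_df["fact_id_1"].tolist())
            refs.update(fr_df["fact_id_2"].tolist())
            # never trim a person's first row, so presence checks are stable
            nth = df.groupby("person_id").cumcount()
            eligible = df.index[(nth > 0) & ~df[pkcol].isin(refs)]
            drop_idx = rng.choice(eligible, size=drop_n, replace=False)
            prev.tables[table] = df.drop(index=drop_idx).reset_index(drop=True)

    curr = prev.copy()

    for table, factor in drift.table_growth.items():
        df = curr.tables[table]
        n = len(df)
        add_n = round((factor - 1.0) * n)
        if add_n:
            src = rng.choice(df.index, size=add_n, replace=True)
            dup = df.loc[src].copy()
            pkcol = df.columns[0]
            dup[pkcol] = np.arange(int(df[pkcol].max()) + 1,
                                   int(df[pkcol].max()) + 1 + add_n)
            curr.tables[table] = pd.concat([df, dup], ignore_index=True)

    for (table, fieldname), (prev_pct, curr_pct) in drift.missingness.items():
        if curr_pct < prev_pct:
            prev_pct, curr_pct = curr_pct, prev_pct
            first, second = curr, prev
        else:
            first, second = prev, curr
        n = len(first.tables[table])
        k_prev = round(prev_pct / 100.0 * n)
        k_curr = round(curr_pct / 100.0 * len(second.tables[table]))
        order = rng.permutation(first.tables[table].index.to_numpy())
        is_date = schema.field(table, fieldname).semantic_type in ("date",
                                                                   "datetime")
        nullval = pd.NaT if is_date else None
        first.tables[table].loc[order[:k_prev], fieldname] = nullval
        second.tables[table].loc[order[:k_curr], fieldname] = nullval

    ctx = make_reference_context(profile, prior=summarize_dataset(prev, schema))
    return prev, curr, ctx
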