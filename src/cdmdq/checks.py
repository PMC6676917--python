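"""The check-type library: executing catalog checks against a site dataset.

Checks fall into five computational methods:

* element presence      -- MissData, MissConceptID, MissFact, MissVisitFact,
                           MissVisitLink
* element agreement     -- InconDateTime, InconVisitType, InconSource, ImplEvent
* data source agreement -- UnexDiff, UnexMiss (require the prior cycle summary)
* distribution comparison -- UnexTop, UnexTopSource, UnexFact, TempOutlier,
                           TempOutlierFact (require reference ranks / a long
                           enough monthly series)
* face validity         -- InvalidConID, InvalidVocab, InvalidValue, InvalidMap,
                           InvalidDomain, InconCohort, ImplFutureDate,
                           ImplPastDate, ImplAge, PreBirth, PostDeath,
                           NumOutlier, NumOutlierUnit, OrphanFact

Every check produces exactly one :class:`Finding`.  A check whose required
context is absent (no prior cycle, no reference ranks, too few months) is
*skipped*, which is distinct from passing.  An unexpected error inside one
check never aborts the run: it yields an engine-failure finding, the raw
material of "false alarm: bug in the DQ workflow" causes.

Conventions baked into the evaluators (see the methods note for rationale):

* a concept_id that is null **or 0** counts as unmapped (MissConceptID) and
  is excluded from vocabulary/domain/ranking checks;
* a fact timestamped exactly on the birth date is NOT a pre-birth violation
  (comparison is strictly-before at day resolution);
* the monthly-volume outlier test uses the modified z-score
  ``0.6745 * (x - median) / MAD`` with a default cutoff of 3.5, restricted
  to months inside the plausible window (floor date .. current date) and
  excluding the first and last month of the observed series, which are
  partial by construction;
* numeric outliers use Tukey fences at ``k`` x IQR (default 3.0) beyond the
  quartiles.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cdm_model import (Catalog, CheckInstance, Dataset, SchemaManifest,
                        round_half_even)

SAMPLE_CAP = 20
PLAUSIBILITY_FLOOR = pd.Timestamp("2000-01-01")

FACT_TABLES = ("condition_occurrence", "drug_exposure", "procedure_occurrence",
               "measurement", "observation")

# Tables whose facts attach to a person and may carry a pre-birth/post-death
# date; maps to the noun used in finding descriptions.
_TABLE_NOUN = {
    "visit_occurrence": "visits",
    "condition_occurrence": "conditions",
    "drug_exposure": "drug exposures",
    "procedure_occurrence": "procedures",
    "measurement": "measurements",
    "observation": "observations",
    "adt_occurrence": "ADT events",
}


class CheckContractError(ValueError):
    """An evaluator was handed a check of the wrong type."""


# ---------------------------------------------------------------------------
# Vocabulary fixture


class Vocabulary:
    """Miniature concept table + source->standard crosswalk."""

    def __init__(self, concepts: pd.DataFrame, crosswalk: pd.DataFrame):
        self.concepts = concepts
        self.crosswalk = crosswalk
        self._vocab = dict(zip(concepts["concept_id"], concepts["vocabulary"]))
        self._domain = dict(zip(concepts["concept_id"], concepts["domain"]))
        self.known_ids = frozenset(concepts["concept_id"])
        dep = crosswalk[crosswalk["status"] == "deprecated"]
        self.deprecated_pairs = frozenset(
            zip(dep["source_concept_id"], dep["target_concept_id"]))

    def vocabulary_of(self, cid: int) -> Optional[str]:
        return self._vocab.get(cid)

    def domain_of(self, cid: int) -> Optional[str]:
        return self._domain.get(cid)

    @classmethod
    def load_default(cls) -> "Vocabulary":
        base = resources.files("cdmdq.data")
        concepts = pd.read_csv(base.joinpath("concept_pool.csv"))  # type: ignore[arg-type]
        crosswalk = pd.read_csv(base.joinpath("crosswalk.csv"))  # type: ignore[arg-type]
        return cls(concepts, crosswalk)


_DEFAULT_VOCAB: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    global _DEFAULT_VOCAB
    if _DEFAULT_VOCAB is None:
        _DEFAULT_VOCAB = Vocabulary.load_default()
    return _DEFAULT_VOCAB


# ---------------------------------------------------------------------------
# Context and result containers


@dataclass
class PriorCycleSummary:
    """Per-table row counts and per-field missingness from the prior cycle."""

    row_counts: dict[str, int]
    missingness: dict[tuple[str, str], float]   # (table, field) -> percent


def summarize_dataset(ds: Dataset, manifest: SchemaManifest) -> PriorCycleSummary:
    """The summary of a cycle that the next cycle's source-agreement checks
    compare against."""
    counts = dict(ds.row_counts)
    miss: dict[tuple[str, str], float] = {}
    for table in manifest.tables:
        df = ds.tables[table]
        n = len(df)
        for spec in manifest.fields_of(table):
            m = int(df[spec.field_name].isna().sum())
            miss[(table, spec.field_name)] = (100.0 * m / n) if n else 0.0
    return PriorCycleSummary(row_counts=counts, missingness=miss)


@dataclass
class ReferenceContext:
    """External references a check may need: the previous cycle's summary,
    cross-site concept-frequency ranks, and the assessment date."""

    prior_cycle_summary: Optional[PriorCycleSummary] = None
    cross_site_ranks: Optional[dict[tuple[str, str], pd.DataFrame]] = None
    current_date: pd.Timestamp = pd.Timestamp("2017-01-15")

    def ranks_for(self, table: str, fieldname: str) -> Optional[pd.DataFrame]:
        if not self.cross_site_ranks:
            return None
        return self.cross_site_ranks.get((table, fieldname))


def load_cross_site_ranks(path: Path,
                          default_table: str = "condition_occurrence",
                          default_field: str = "condition_concept_id",
                          ) -> dict[tuple[str, str], pd.DataFrame]:
    """Read a reference rank list CSV (columns: site, rank, concept_id[,
    concept_name][, table][, field]).  Rows without explicit table/field
    columns attach to the primary diagnosis field."""
    df = pd.read_csv(path)
    if "table" not in df.columns:
        df["table"] = default_table
    if "field" not in df.columns:
        df["field"] = default_field
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for (t, f), grp in df.groupby(["table", "field"]):
        g = grp.drop(columns=["table", "field"]).reset_index(drop=True)
        for site, sg in g.groupby("site"):
            if sg["concept_id"].duplicated().any():
                raise ValueError(f"duplicate concepts in rank list for {site}")
        out[(t, f)] = g
    return out


@dataclass
class Finding:
    """The result of executing one check on one dataset."""

    check_id: str
    type_alias: str
    result_kind: str                       # count | percentage | value_list
    numeric_value: Optional[float] = None
    value_list: Optional[tuple] = None
    violation_count: int = 0
    description: str = ""
    sample_violations: tuple = ()
    observed_at: str = ""
    skipped: bool = False
    skip_reason: Optional[str] = None
    failed: bool = False
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "check_id": self.check_id, "type_alias": self.type_alias,
            "result_kind": self.result_kind,
            "numeric_value": self.numeric_value,
            "value_list": list(self.value_list) if self.value_list is not None else None,
            "violation_count": self.violation_count,
            "description": self.description,
            "sample_violations": [list(s) for s in self.sample_violations],
            "observed_at": self.observed_at,
            "skipped": self.skipped, "skip_reason": self.skip_reason,
            "failed": self.failed, "error": self.error,
        }


@dataclass(frozen=True)
class IssueCandidate:
    """A finding outside its threshold bounds, eligible to become a DQ issue."""

    check_id: str
    type_alias: str
    table: str
    fields: tuple[str, ...]
    finding: Finding


# ---------------------------------------------------------------------------
# Engine cache (per-dataset memoization shared across checks)


class _Cache:
    def __init__(self, ds: Dataset):
        self.ds = ds
        self._person_ids: Optional[frozenset] = None
        self._table_persons: dict[str, frozenset] = {}
        self._table_pks: dict[str, frozenset] = {}
        self._visits_with_facts: Optional[frozenset] = None

    def person_ids(self) -> frozenset:
        if self._person_ids is None:
            self._person_ids = frozenset(
                self.ds.tables["person"]["person_id"].dropna())
        return self._person_ids

    def persons_in(self, table: str) -> frozenset:
        if table not in self._table_persons:
            self._table_persons[table] = frozenset(
                self.ds.tables[table]["person_id"].dropna())
        return self._table_persons[table]

    def pks_of(self, table: str, pk_field: str) -> frozenset:
        key = f"{table}.{pk_field}"
        if key not in self._table_pks:
            self._table_pks[key] = frozenset(
                self.ds.tables[table][pk_field].dropna())
        return self._table_pks[key]

    def visits_with_facts(self) -> frozenset:
        if self._visits_with_facts is None:
            ids: set = set()
            for t in FACT_TABLES:
                ids.update(self.ds.tables[t]["visit_occurrence_id"].dropna())
            self._visits_with_facts = frozenset(ids)
        return self._visits_with_facts

    def birth_by_person(self) -> pd.Series:
        if not hasattr(self, "_birth"):
            p = self.ds.tables["person"]
            birth = p["time_of_birth"].dt.normalize()
            # fallback: reconstruct midnight birth date from components
            fallback = pd.to_datetime(pd.DataFrame({
                "year": pd.to_numeric(p["year_of_birth"], errors="coerce"),
                "month": pd.to_numeric(p["month_of_birth"], errors="coerce"),
                "day": pd.to_numeric(p["day_of_birth"], errors="coerce"),
            }), errors="coerce")
            self._birth = birth.fillna(fallback).set_axis(p["person_id"]).dropna()
        return self._birth

    def death_by_person(self) -> pd.Series:
        if not hasattr(self, "_death"):
            d = self.ds.tables["death"]
            self._death = (d.dropna(subset=["person_id", "death_date"])
                           .set_index("person_id")["death_date"].dt.normalize())
        return self._death


# ---------------------------------------------------------------------------
# Shared helpers


def _pct(n: int, d: int) -> float:
    return round_half_even(100.0 * n / d) if d else 0.0


def _samples(df_index: Sequence, table: str) -> tuple:
    return tuple((table, int(i)) for i in list(df_index)[:SAMPLE_CAP])


def _require(check: CheckInstance, aliases: tuple[str, ...]) -> None:
    if check.type_alias not in aliases:
        raise CheckContractError(
            f"{check.check_id}: evaluator expects one of {aliases}")


def _finding(check, cat, **kw) -> Finding:
    kind = cat.type_of(check).result_kind
    return Finding(check_id=check.check_id, type_alias=check.type_alias,
                   result_kind=kind, **kw)


def _skip(check, cat, reason: str) -> Finding:
    return _finding(check, cat, skipped=True, skip_reason=reason,
                    description=f"skipped: {reason}")


def _count_finding(check, cat, mask: pd.Series, table: str, desc: str) -> Finding:
    n = int(mask.sum())
    return _finding(check, cat, numeric_value=float(n), violation_count=n,
                    description=desc,
                    sample_violations=_samples(mask[mask].index, table))


# ---------------------------------------------------------------------------
# Element presence


def eval_element_presence(check: CheckInstance, ds: Dataset, cat: Catalog,
                          cache: Optional[_Cache] = None) -> Finding:
    """MissData / MissConceptID / MissFact / MissVisitFact / MissVisitLink."""
    _require(check, ("MissData", "MissConceptID", "MissFact", "MissVisitFact",
                     "MissVisitLink"))
    cache = cache or _Cache(ds)
    alias = check.type_alias
    table = check.table

    if alias == "MissVisitFact":
        visits = ds.tables["visit_occurrence"]
        linked = cache.visits_with_facts()
        mask = ~visits["visit_occurrence_id"].isin(linked)
        n = int(mask.sum())
        return _finding(check, cat, numeric_value=_pct(n, len(visits)),
                        violation_count=n,
                        description=f"{n} of {len(visits)} visits have no facts "
                                    f"in any clinical domain",
                        sample_violations=_samples(mask[mask].index, table))

    if alias == "MissFact":
        persons = cache.person_ids()
        present = cache.persons_in(table)
        missing = persons - present
        return _finding(check, cat, numeric_value=float(len(missing)),
                        violation_count=len(missing),
                        description=f"{len(missing)} persons have no record "
                                    f"in {table}",
                        sample_violations=tuple(
                            ("person", int(p)) for p in sorted(missing)[:SAMPLE_CAP]))

    col = ds.tables[table][check.field]
    if alias == "MissConceptID":
        mask = col.isna() | (col == 0)
        what = "missing or unmapped concept"
    else:  # MissData / MissVisitLink
        mask = col.isna()
        what = "null"
    n = int(mask.sum())
    return _finding(check, cat, numeric_value=_pct(n, len(col)),
                    violation_count=n,
                    description=f"{n} of {len(col)} records have {what} "
                                f"{table}.{check.field}",
                    sample_violations=_samples(mask[mask].index, table))


# ---------------------------------------------------------------------------
# Element agreement


def eval_element_agreement(check: CheckInstance, ds: Dataset, cat: Catalog,
                           cache: Optional[_Cache] = None) -> Finding:
    """InconDateTime / InconVisitType / InconSource / ImplEvent."""
    _require(check, ("InconDateTime", "InconVisitType", "InconSource",
                     "ImplEvent"))
    cache = cache or _Cache(ds)
    alias = check.type_alias
    table = check.table

    if alias == "InconDateTime":
        date_col = ds.tables[table][check.field]
        dt_col = ds.tables[table][check.targets[1][1]]
        both = date_col.notna() & dt_col.notna()
        mask = both & (date_col.dt.normalize() != dt_col.dt.normalize())
        return _count_finding(
            check, cat, mask, table,
            f"{int(mask.sum())} records where {check.field} disagrees with "
            f"the date part of {check.targets[1][1]}")

    if alias == "ImplEvent":
        start = ds.tables[table][check.params["start"]]
        end = ds.tables[table][check.params["end"]]
        mask = start.notna() & end.notna() & (start > end)
        return _count_finding(
            check, cat, mask, table,
            f"{int(mask.sum())} records where {check.params['start']} is after "
            f"{check.params['end']}")

    if alias == "InconSource":
        a = ds.tables[table][check.field]
        b = ds.tables[table][check.targets[1][1]]
        mask = a.isna() != b.isna()
        return _count_finding(
            check, cat, mask, table,
            f"{int(mask.sum())} records where nullness of {check.field} "
            f"disagrees with {check.targets[1][1]}")

    # InconVisitType: facts of the configured visit type in one domain that
    # have no counterpart in the other domain.
    visit_concept = int(check.params.get("visit_concept", 9201))
    other_table = check.targets[1][0]
    visits = ds.tables[check.table]
    other_ids = frozenset(ds.tables[other_table]["visit_occurrence_id"].dropna())
    mask = (visits["visit_concept_id"] == visit_concept) & \
        ~visits["visit_occurrence_id"].isin(other_ids)
    return _count_finding(
        check, cat, mask, check.table,
        f"{int(mask.sum())} visits of type {visit_concept} with no "
        f"corresponding {other_table} record")


# ---------------------------------------------------------------------------
# Face validity


def _dates_and_persons(ds, table, fieldname):
    df = ds.tables[table]
    return df[fieldname], df["person_id"]


def eval_face_validity(check: CheckInstance, ds: Dataset, cat: Catalog,
                       ctx: ReferenceContext,
                       cache: Optional[_Cache] = None,
                       vocab: Optional[Vocabulary] = None) -> Finding:
    """PreBirth / PostDeath / ImplFutureDate / ImplPastDate / ImplAge /
    InvalidConID / InvalidVocab / InvalidValue / InvalidMap / InvalidDomain /
    InconCohort / NumOutlier / NumOutlierUnit / OrphanFact."""
    _require(check, ("PreBirth", "PostDeath", "ImplFutureDate", "ImplPastDate",
                     "ImplAge", "InvalidConID", "InvalidVocab", "InvalidValue",
                     "InvalidMap", "InvalidDomain", "InconCohort", "NumOutlier",
                     "NumOutlierUnit", "OrphanFact"))
    cache = cache or _Cache(ds)
    vocab = vocab or default_vocabulary()
    alias = check.type_alias
    table = check.table

    if alias in ("PreBirth", "PostDeath", "ImplAge"):
        col, persons = _dates_and_persons(ds, table, check.field)
        dates = col.dt.normalize()
        if alias == "PreBirth":
            ref = persons.map(cache.birth_by_person())
            known = dates.notna() & ref.notna()
            mask = known & (dates < ref)
            n = int(mask.sum())
            noun = _TABLE_NOUN.get(table, "facts")
            excl = int((dates.notna() & ref.isna()).sum())
            desc = f"{n} {noun} before patient was born"
            if excl:
                desc += f" ({excl} records excluded: unknown birth datetime)"
        elif alias == "PostDeath":
            grace = pd.Timedelta(days=int(check.params.get("grace_days", 0)))
            ref = persons.map(cache.death_by_person())
            known = dates.notna() & ref.notna()
            mask = known & (dates > ref + grace)
            n = int(mask.sum())
            desc = (f"{n} {_TABLE_NOUN.get(table, 'facts')} dated after the "
                    f"patient's death")
        else:  # ImplAge
            max_years = float(check.params.get("max_years", 30))
            ref = persons.map(cache.birth_by_person())
            known = dates.notna() & ref.notna()
            age_days = (dates - ref).dt.days
            mask = known & (age_days > max_years * 365.25)
            n = int(mask.sum())
            desc = f"{n} records dated beyond age {max_years:g} years"
        return _finding(check, cat, numeric_value=float(n), violation_count=n,
                        description=desc,
                        sample_violations=_samples(mask[mask].index, table))

    if alias == "ImplFutureDate":
        col = ds.tables[table][check.field].dt.normalize()
        mask = col.notna() & (col > ctx.current_date.normalize())
        return _count_finding(check, cat, mask, table,
                              f"{int(mask.sum())} records dated after "
                              f"{ctx.current_date.date()}")

    if alias == "ImplPastDate":
        floor = pd.Timestamp(check.params.get("floor", PLAUSIBILITY_FLOOR))
        col = ds.tables[table][check.field].dt.normalize()
        mask = col.notna() & (col < floor)
        return _count_finding(check, cat, mask, table,
                              f"{int(mask.sum())} records dated before "
                              f"{floor.date()}")

    if alias in ("InvalidConID", "InvalidVocab", "InvalidDomain"):
        col = ds.tables[table][check.field]
        mapped = col.notna() & (col != 0)
        if alias == "InvalidConID":
            mask = mapped & ~col.isin(vocab.known_ids)
            desc = "concept identifiers absent from the vocabulary"
        elif alias == "InvalidVocab":
            spec = cat.manifest.field(table, check.field)
            allowed = set(spec.allowed_vocabs or ())
            vocab_of = col.map(vocab._vocab)
            mask = mapped & vocab_of.notna() & ~vocab_of.isin(allowed)
            desc = f"concepts outside the allowed vocabularies {sorted(allowed)}"
        else:
            spec = cat.manifest.field(table, check.field)
            dom = col.map(vocab._domain)
            mask = mapped & dom.notna() & (dom != spec.expected_domain)
            desc = f"concepts outside the expected domain {spec.expected_domain}"
        n = int(mask.sum())
        return _count_finding(check, cat, mask, table, f"{n} {desc}")

    if alias == "InvalidValue":
        spec = cat.manifest.field(table, check.field)
        col = ds.tables[table][check.field]
        allowed = set(spec.value_set or ())
        mask = col.notna() & ~col.astype(str).isin(allowed)
        return _count_finding(check, cat, mask, table,
                              f"{int(mask.sum())} values outside the allowed "
                              f"value set of {table}.{check.field}")

    if alias == "InvalidMap":
        # deprecated source->standard pairs, via the sibling source-concept
        # column when the table has one
        base = check.field[: -len("_concept_id")]
        sib = f"{base}_source_concept_id"
        if not cat.manifest.has_field(table, sib) or sib == check.field:
            return _finding(check, cat, numeric_value=0.0, violation_count=0,
                            description="no source-concept column to validate "
                                        "mappings against")
        df = ds.tables[table]
        pairs = list(zip(df[sib].fillna(-1), df[check.field].fillna(-1)))
        mask = pd.Series([p in vocab.deprecated_pairs for p in pairs],
                         index=df.index)
        return _count_finding(check, cat, mask, table,
                              f"{int(mask.sum())} records using a deprecated "
                              f"source-to-standard mapping")

    if alias == "InconCohort":
        max_age = float(check.params.get("max_entry_age_years", 22))
        visits = ds.tables["visit_occurrence"]
        first = (visits.dropna(subset=["person_id", "visit_start_date"])
                 .groupby("person_id")["visit_start_date"].min())
        birth = cache.birth_by_person()
        joined = pd.DataFrame({"first": first}).join(
            birth.rename("birth"), how="inner")
        entry_age = (joined["first"].dt.normalize() - joined["birth"]).dt.days \
            / 365.25
        bad = joined.index[entry_age >= max_age]
        n = len(bad)
        return _finding(check, cat, numeric_value=float(n), violation_count=n,
                        description=f"{n} persons violate the inclusion "
                                    f"criterion (first visit at or beyond age "
                                    f"{max_age:g})",
                        sample_violations=tuple(("person", int(p))
                                                for p in sorted(bad)[:SAMPLE_CAP]))

    if alias in ("NumOutlier", "NumOutlierUnit"):
        k = float(check.params.get("k_iqr", 3.0))
        df = ds.tables[table]
        col = df[check.field].astype("Float64")

        def fence_mask(values: pd.Series) -> pd.Series:
            v = values.dropna().astype(float)
            if len(v) < 20:
                return pd.Series(False, index=values.index)
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            return values.notna() & ((values < lo) | (values > hi))

        if alias == "NumOutlierUnit":
            unit_field = check.params.get("unit_field", "unit_concept_id")
            mask = pd.Series(False, index=df.index)
            for _, idx in df.groupby(unit_field, dropna=False).groups.items():
                sub = col.loc[idx]
                mask.loc[idx] = fence_mask(sub)
        else:
            mask = fence_mask(col)
        return _count_finding(check, cat, mask, table,
                              f"{int(mask.sum())} values of {table}."
                              f"{check.field} outside robust fences "
                              f"({k:g} x IQR)")

    # OrphanFact
    domain_cid = int(check.params["domain_concept_id"])
    target_table = check.targets[1][0]
    pk_field = cat.manifest.fields_of(target_table)[0].field_name
    pks = cache.pks_of(target_table, pk_field)
    fr = ds.tables["fact_relationship"]
    bad1 = (fr["domain_concept_id_1"] == domain_cid) & \
        ~fr["fact_id_1"].isin(pks)
    bad2 = (fr["domain_concept_id_2"] == domain_cid) & \
        ~fr["fact_id_2"].isin(pks)
    mask = bad1 | bad2
    return _count_finding(check, cat, mask, "fact_relationship",
                          f"{int(mask.sum())} fact_relationship records "
                          f"reference a missing {target_table} fact")


# ---------------------------------------------------------------------------
# Data source agreement


def eval_source_agreement(check: CheckInstance, ds: Dataset, cat: Catalog,
                          ctx: ReferenceContext) -> Finding:
    """UnexDiff / UnexMiss: comparison against the prior data cycle."""
    _require(check, ("UnexDiff", "UnexMiss"))
    prior = ctx.prior_cycle_summary
    if prior is None:
        return _skip(check, cat, "no prior cycle summary available")
    table = check.table

    if check.type_alias == "UnexDiff":
        prev = prior.row_counts.get(table)
        if prev is None:
            return _skip(check, cat, f"prior cycle has no count for {table}")
        if prev == 0:
            return _skip(check, cat,
                         "prior row count is zero; change not computable")
        curr = len(ds.tables[table])
        change = round_half_even(abs(curr - prev) / prev * 100.0)
        return _finding(check, cat, numeric_value=change,
                        violation_count=abs(curr - prev),
                        description=f"{change}%")

    prev_miss = prior.missingness.get((table, check.field))
    if prev_miss is None:
        return _skip(check, cat,
                     f"prior cycle has no missingness for {table}.{check.field}")
    col = ds.tables[table][check.field]
    curr_miss = (100.0 * int(col.isna().sum()) / len(col)) if len(col) else 0.0
    delta = round_half_even(curr_miss - prev_miss)
    return _finding(check, cat, numeric_value=delta,
                    violation_count=int(col.isna().sum()),
                    description=f"missingness of {table}.{check.field} changed "
                                f"by {delta:+g} percentage points "
                                f"({round_half_even(prev_miss)} -> "
                                f"{round_half_even(curr_miss)})")


# ---------------------------------------------------------------------------
# Distribution comparison


def _monthly_counts(col: pd.Series, ctx: ReferenceContext) -> pd.Series:
    """Monthly volumes of the bulk of a date column.

    The series is restricted to the plausible window (floor .. current date)
    and to the central 1-99% quantile range of the dates: thin scatter far
    outside the bulk is implausible-date territory (other checks' job) and
    would otherwise drag the median of the series toward zero.  The first
    and last remaining months are dropped as partial by construction.
    """
    dates = col.dropna()
    window = (dates >= PLAUSIBILITY_FLOOR) & \
        (dates <= ctx.current_date.normalize() + pd.Timedelta(days=31))
    dates = dates[window]
    if dates.empty:
        return pd.Series(dtype=int)
    lo, hi = dates.quantile(0.01), dates.quantile(0.99)
    months = dates.dt.to_period("M")
    keep = (months >= lo.to_period("M")) & (months <= hi.to_period("M"))
    counts = months[keep].value_counts().sort_index()
    if len(counts) >= 3:
        counts = counts.iloc[1:-1]  # boundary months are partial by construction
    return counts


def modified_zscores(values: np.ndarray) -> np.ndarray:
    """Median/MAD modified z-score.  For count data the scale is floored at
    sqrt(median) — the Poisson scale — so that a near-uniform monthly series
    does not flag ordinary sampling noise as an outlier."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = max(mad, np.sqrt(max(med, 1.0)))
    return 0.6745 * (values - med) / scale


def eval_distribution(check: CheckInstance, ds: Dataset, cat: Catalog,
                      ctx: ReferenceContext) -> Finding:
    """UnexTop / UnexTopSource / UnexFact / TempOutlier / TempOutlierFact."""
    _require(check, ("UnexTop", "UnexTopSource", "UnexFact", "TempOutlier",
                     "TempOutlierFact"))
    alias = check.type_alias
    table = check.table

    if alias in ("TempOutlier", "TempOutlierFact"):
        fieldname = check.field if alias == "TempOutlier" \
            else str(check.params["date_field"])
        cutoff = float(check.params.get("cutoff", 3.5))
        min_months = int(check.params.get("min_months", 12))
        counts = _monthly_counts(ds.tables[table][fieldname], ctx)
        if len(counts) < min_months:
            return _skip(check, cat,
                         f"only {len(counts)} months observed "
                         f"(minimum {min_months})")
        z = modified_zscores(counts.to_numpy(dtype=float))
        flagged = tuple(str(m) for m, zz in zip(counts.index, z)
                        if abs(zz) > cutoff)
        return _finding(check, cat, value_list=flagged,
                        violation_count=len(flagged),
                        description=f"{len(flagged)} outlier month(s) in "
                                    f"{table}.{fieldname} volume: "
                                    f"{', '.join(flagged) or 'none'}")

    ranks = ctx.ranks_for(table, check.field)
    if ranks is None:
        return _skip(check, cat,
                     f"no cross-site reference ranks for {table}.{check.field}")
    col = ds.tables[table][check.field]
    col = col[col.notna() & (col != 0)]
    site_counts = col.value_counts()

    if alias == "UnexFact":
        known = frozenset(ranks["concept_id"])
        unexpected = tuple(int(c) for c in site_counts.index if c not in known)
        return _finding(check, cat, value_list=unexpected,
                        violation_count=len(unexpected),
                        description=f"{len(unexpected)} concept(s) in {table}."
                                    f"{check.field} absent from all reference "
                                    f"site inventories")

    # UnexTop / UnexTopSource
    k = int(check.params.get("k", 1))
    top_n = int(check.params.get("top", 50))
    site_top = list(site_counts.index[:k])
    in_ref_top: set = set()
    for _, grp in ranks.groupby("site"):
        grp = grp.sort_values("rank")
        in_ref_top.update(grp["concept_id"].iloc[:top_n])
    flagged = tuple(c for c in site_top if c not in in_ref_top)
    names = {}
    if "concept_name" in ranks.columns:
        names = dict(zip(ranks["concept_id"], ranks["concept_name"]))
    vocab = default_vocabulary()
    parts = []
    for c in flagged:
        name = names.get(c)
        if name is None and isinstance(c, (int, np.integer)):
            row = vocab.concepts[vocab.concepts["concept_id"] == c]
            name = row["concept_name"].iloc[0] if len(row) else None
        parts.append(f"{name} (OMOP concept_id: {c})" if name else str(c))
    return _finding(check, cat, value_list=flagged,
                    violation_count=len(flagged),
                    description="; ".join(parts) if parts else
                    f"top-{k} values all appear in reference top-{top_n}")


# ---------------------------------------------------------------------------
# Dispatch


_METHOD_EVAL: dict[str, Callable] = {}
for _alias in ("MissData", "MissConceptID", "MissFact", "MissVisitFact",
               "MissVisitLink"):
    _METHOD_EVAL[_alias] = "presence"
for _alias in ("InconDateTime", "InconVisitType", "InconSource", "ImplEvent"):
    _METHOD_EVAL[_alias] = "agreement"
for _alias in ("UnexDiff", "UnexMiss"):
    _METHOD_EVAL[_alias] = "source"
for _alias in ("UnexTop", "UnexTopSource", "UnexFact", "TempOutlier",
               "TempOutlierFact"):
    _METHOD_EVAL[_alias] = "distribution"
for _alias in ("PreBirth", "PostDeath", "ImplFutureDate", "ImplPastDate",
               "ImplAge", "InvalidConID", "InvalidVocab", "InvalidValue",
               "InvalidMap", "InvalidDomain", "InconCohort", "NumOutlier",
               "NumOutlierUnit", "OrphanFact"):
    _METHOD_EVAL[_alias] = "face"


def evaluate_check(check: CheckInstance, ds: Dataset, cat: Catalog,
                   ctx: ReferenceContext, cache: Optional[_Cache] = None,
                   vocab: Optional[Vocabulary] = None) -> Finding:
    method = _METHOD_EVAL.get(check.type_alias)
    if method is None:
        raise CheckContractError(f"no evaluator for alias {check.type_alias!r}")
    if method == "presence":
        return eval_element_presence(check, ds, cat, cache)
    if method == "agreement":
        return eval_element_agreement(check, ds, cat, cache)
    if method == "source":
        return eval_source_agreement(check, ds, cat, ctx)
    if method == "distribution":
        return eval_distribution(check, ds, cat, ctx)
    return eval_face_validity(check, ds, cat, ctx, cache, vocab)


def run_checks(ds: Dataset, cat: Catalog, ctx: ReferenceContext,
               data_version: str = "",
               vocab: Optional[Vocabulary] = None) -> list[Finding]:
    """Execute every catalog check against the dataset.

    Exactly one finding per check, in deterministic (check_id) order.  A
    check lacking required context is reported as skipped; an internal error
    in one check yields an engine-failure finding and does not abort the run.
    """
    cache = _Cache(ds)
    vocab = vocab or default_vocabulary()
    findings = []
    for check in sorted(cat.checks, key=lambda c: c.check_id):
        try:
            f = evaluate_check(check, ds, cat, ctx, cache, vocab)
        except Exception as exc:  # noqa: BLE001 - engine failures are findings
            f = _finding(check, cat, failed=True, error=f"{type(exc).__name__}: {exc}",
                         description="engine failure while evaluating check")
        f.observed_at = data_version
        findings.append(f)
    return findings


def apply_thresholds(finding: Finding, check: CheckInstance
                     ) -> Optional[IssueCandidate]:
    """Gate a finding by the check's threshold bounds.

    Bounds are inclusive-acceptable: a candidate is created only when the
    numeric value falls strictly outside [lower, upper].  Value-list checks
    yield a candidate iff the flagged list is non-empty.  Skipped and failed
    findings never produce candidates.
    """
    if finding.check_id != check.check_id:
        raise CheckContractError("finding does not belong to this check")
    if finding.skipped or finding.failed:
        return None
    if finding.result_kind == "value_list":
        outside = bool(finding.value_list)
    else:
        if finding.numeric_value is None:
            return None
        v = finding.numeric_value
        lo = check.lower_threshold if check.lower_threshold is not None else -np.inf
        hi = check.upper_threshold if check.upper_threshold is not None else np.inf
        outside = v < lo or v > hi
    if not outside:
        return None
    fields = tuple(f for _, f in check.targets if f is not None)
    return IssueCandidate(check_id=check.check_id, type_alias=check.type_alias,
                          table=check.table, fields=fields, finding=finding)


def findings_to_candidates(findings: Sequence[Finding],
                           cat: Catalog) -> list[IssueCandidate]:
    out = []
    for f in findings:
        cand = apply_thresholds(f, cat.check(f.check_id))
        if cand is not None:
            out.append(cand)
    return out


def write_findings_jsonl(findings: Sequence[Finding], path: Path) -> None:
    import json
    with Path(path).open("w", encoding="utf-8") as fh:
        for f in findings:
            fh.write(json.dumps(f.to_dict(), separators=(",", ":")) + "\n")
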