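"""CDM schema model, dataset ingestion, pre-workflow conformance validation,
and check-catalog loading.

A site submits its data as one CSV file per CDM table.  The schema manifest
(one :class:`FieldSpec` per column) drives typed parsing, the integrity
validation that runs *before* any data-quality check, and the binding of
check instances to fields.

CSV conventions: comma-separated, UTF-8, RFC-4180 quoting, ISO-8601 dates;
an empty string is a null.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEMANTIC_TYPES = frozenset({
    "primary_key", "foreign_key_required", "foreign_key_optional",
    "concept_id", "source_value", "date", "datetime", "numeric",
    "categorical", "free_text",
})
METHOD_CATEGORIES = frozenset({
    "element_agreement", "element_presence", "source_agreement",
    "distribution_comparison", "face_validity",
})
HARMONIZED_CATEGORIES = frozenset({
    "completeness", "temporal_plausibility", "atemporal_plausibility",
    "value_conformance", "relational_conformance",
})


class CatalogError(ValueError):
    """Raised for malformed schema manifests or check catalogs."""


class DatasetError(ValueError):
    """Raised when a site dataset cannot be loaded against the manifest."""


def _data_path(name: str):
    return resources.files("cdmdq.data").joinpath(name)


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Percentages are reported to 2 decimals, round-half-even."""
    return float(round(float(x), ndigits))


# ---------------------------------------------------------------------------
# Schema manifest


@dataclass(frozen=True)
class FieldSpec:
    """One CDM column: the unit to which checks bind."""

    table_name: str
    field_name: str
    semantic_type: str
    nullable: bool = True
    value_set: Optional[tuple[str, ...]] = None
    allowed_vocabs: Optional[tuple[str, ...]] = None
    expected_domain: Optional[str] = None
    fk_ref: Optional[tuple[str, str]] = None
    conventions_version: str = "2.4.0"

    def __post_init__(self):
        if self.semantic_type not in SEMANTIC_TYPES:
            raise CatalogError(
                f"unknown semantic type {self.semantic_type!r} for "
                f"{self.table_name}.{self.field_name}")
        if self.value_set is not None and self.semantic_type != "categorical":
            raise CatalogError(
                f"value_set only allowed on categorical fields: "
                f"{self.table_name}.{self.field_name}")
        if self.semantic_type == "primary_key" and self.nullable:
            raise CatalogError(
                f"primary key must be non-nullable: "
                f"{self.table_name}.{self.field_name}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.table_name, self.field_name)


@dataclass
class SchemaManifest:
    fields: list[FieldSpec]
    tables: list[str]
    conventions_version: str = "2.4.0"

    def __post_init__(self):
        seen = set()
        for f in self.fields:
            if f.key in seen:
                raise CatalogError(f"duplicate field {f.key}")
            seen.add(f.key)
            if f.table_name not in self.tables:
                raise CatalogError(
                    f"field {f.key} references unknown table {f.table_name}")
        self._by_key = {f.key: f for f in self.fields}
        self._by_table: dict[str, list[FieldSpec]] = {}
        for f in self.fields:
            self._by_table.setdefault(f.table_name, []).append(f)

    def field(self, table: str, name: str) -> FieldSpec:
        try:
            return self._by_key[(table, name)]
        except KeyError:
            raise CatalogError(f"unknown field {table}.{name}") from None

    def has_field(self, table: str, name: str) -> bool:
        return (table, name) in self._by_key

    def fields_of(self, table: str) -> list[FieldSpec]:
        return self._by_table.get(table, [])

    def __len__(self) -> int:
        return len(self.fields)


def load_schema_manifest(path: Optional[Path] = None,
                         conventions_version: str = "2.4.0") -> SchemaManifest:
    """Load a schema manifest CSV; defaults to the packaged reference manifest."""
    src = Path(path) if path is not None else _data_path("schema.csv")
    fields: list[FieldSpec] = []
    tables: list[str] = []
    with src.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            t = row["table"]
            if t not in tables:
                tables.append(t)
            fields.append(FieldSpec(
                table_name=t,
                field_name=row["field"],
                semantic_type=row["semantic_type"],
                nullable=row["nullable"] == "1",
                value_set=tuple(row["value_set"].split("|")) if row["value_set"] else None,
                allowed_vocabs=tuple(row["allowed_vocabs"].split("|")) if row["allowed_vocabs"] else None,
                expected_domain=row["expected_domain"] or None,
                fk_ref=tuple(row["fk_ref"].split(".")) if row["fk_ref"] else None,  # type: ignore[arg-type]
                conventions_version=conventions_version,
            ))
    return SchemaManifest(fields=fields, tables=tables,
                          conventions_version=conventions_version)


# ---------------------------------------------------------------------------
# Check catalog


@dataclass(frozen=True)
class CheckTypeSpec:
    alias: str
    name: str
    method_category: str
    harmonized_category: str
    scope: str          # field | field_pair | table | cross_table
    result_kind: str    # count | percentage | value_list
    reconstructed: bool = False

    def __post_init__(self):
        if self.method_category not in METHOD_CATEGORIES:
            raise CatalogError(f"bad method category for {self.alias}")
        if self.harmonized_category not in HARMONIZED_CATEGORIES:
            raise CatalogError(f"bad harmonized category for {self.alias}")


@dataclass(frozen=True)
class CheckInstance:
    """A check type bound to concrete target(s) with threshold bounds.

    ``targets`` is a tuple of (table, field) pairs; a table-level target has
    field ``None``.  The first target is the primary one: it determines the
    field a finding is attributed to.
    """

    check_id: str
    type_alias: str
    targets: tuple[tuple[str, Optional[str]], ...]
    lower_threshold: Optional[float] = None
    upper_threshold: Optional[float] = None
    params: Mapping[str, object] = dc_field(default_factory=dict)

    def __post_init__(self):
        if (self.lower_threshold is not None and self.upper_threshold is not None
                and self.lower_threshold > self.upper_threshold):
            raise CatalogError(
                f"{self.check_id}: lower threshold {self.lower_threshold} "
                f"exceeds upper threshold {self.upper_threshold}")

    @property
    def table(self) -> str:
        return self.targets[0][0]

    @property
    def field(self) -> Optional[str]:
        return self.targets[0][1]


def _target_str(t: tuple[str, Optional[str]]) -> str:
    return t[0] if t[1] is None else f"{t[0]}.{t[1]}"


def make_check_id(alias: str, targets: Sequence[tuple[str, Optional[str]]]) -> str:
    # Target order is significant (the primary target comes first); two
    # agreement checks over the same pair differ only by primary.
    return f"{alias}::" + "+".join(_target_str(t) for t in targets)


@dataclass
class Catalog:
    check_types: list[CheckTypeSpec]
    checks: list[CheckInstance]
    manifest: SchemaManifest
    version: str = "reference"

    def __post_init__(self):
        self._types = {t.alias: t for t in self.check_types}
        if len(self._types) != len(self.check_types):
            raise CatalogError("duplicate check-type alias")
        self._by_id = {}
        for c in self.checks:
            if c.type_alias not in self._types:
                raise CatalogError(f"unknown check type alias {c.type_alias!r}")
            for table, fieldname in c.targets:
                if table not in self.manifest.tables:
                    raise CatalogError(f"{c.check_id}: unknown table {table!r}")
                if fieldname is not None and not self.manifest.has_field(table, fieldname):
                    raise CatalogError(
                        f"{c.check_id}: unknown field {table}.{fieldname}")
            if c.check_id in self._by_id:
                raise CatalogError(f"duplicate check id {c.check_id}")
            self._by_id[c.check_id] = c

    def type_of(self, check: CheckInstance | str) -> CheckTypeSpec:
        alias = check if isinstance(check, str) else check.type_alias
        return self._types[alias]

    def check(self, check_id: str) -> CheckInstance:
        return self._by_id[check_id]

    def __len__(self) -> int:
        return len(self.checks)


def load_check_types(path: Optional[Path] = None) -> list[CheckTypeSpec]:
    src = Path(path) if path is not None else _data_path("check_types.csv")
    out = []
    with src.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(CheckTypeSpec(
                alias=row["alias"], name=row["name"],
                method_category=row["method_category"],
                harmonized_category=row["harmonized_category"],
                scope=row["scope"], result_kind=row["result_kind"],
                reconstructed=row["reconstructed"] == "1"))
    return out


def _parse_target(s: str, manifest: SchemaManifest) -> tuple[str, Optional[str]]:
    if "." in s:
        table, fieldname = s.split(".", 1)
        return (table, fieldname)
    if s not in manifest.tables:
        raise CatalogError(f"unknown target {s!r}")
    return (s, None)


def load_catalog(path: Optional[Path] = None,
                 manifest: Optional[SchemaManifest] = None,
                 check_types_path: Optional[Path] = None,
                 version: str = "reference") -> Catalog:
    """Load a check catalog CSV; defaults to the packaged reference catalog."""
    if manifest is None:
        manifest = load_schema_manifest()
    src = Path(path) if path is not None else _data_path("catalog.csv")
    checks = []
    with src.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            targets = tuple(_parse_target(s, manifest)
                            for s in row["targets"].split("+"))
            lo = float(row["lower_threshold"]) if row["lower_threshold"] != "" else None
            hi = float(row["upper_threshold"]) if row["upper_threshold"] != "" else None
            params = json.loads(row["params"]) if row.get("params") else {}
            checks.append(CheckInstance(
                check_id=make_check_id(row["type_alias"], targets),
                type_alias=row["type_alias"], targets=targets,
                lower_threshold=lo, upper_threshold=hi, params=params))
    return Catalog(check_types=load_check_types(check_types_path),
                   checks=checks, manifest=manifest, version=version)


def serialize_catalog(cat: Catalog, path: Path) -> None:
    """Write a catalog back to CSV (inverse of :func:`load_catalog`)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["type_alias", "targets", "lower_threshold",
                    "upper_threshold", "params"])
        for c in cat.checks:
            w.writerow([
                c.type_alias,
                "+".join(_target_str(t) for t in c.targets),
                "" if c.lower_threshold is None else _fmt_num(c.lower_threshold),
                "" if c.upper_threshold is None else _fmt_num(c.upper_threshold),
                json.dumps(dict(c.params), separators=(",", ":")) if c.params else "",
            ])


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


# ---------------------------------------------------------------------------
# Dataset loading


@dataclass
class Dataset:
    tables: dict[str, pd.DataFrame]
    site: str = "site"

    @property
    def row_counts(self) -> dict[str, int]:
        return {t: len(df) for t, df in self.tables.items()}

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def copy(self) -> "Dataset":
        return Dataset(tables={t: df.copy() for t, df in self.tables.items()},
                       site=self.site)


_PANDAS_KIND = {
    "primary_key": "id", "foreign_key_required": "id",
    "foreign_key_optional": "id", "concept_id": "id",
    "source_value": "str", "free_text": "str", "categorical": "str",
    "date": "date", "datetime": "datetime", "numeric": "float",
}


def _convert_column(col: pd.Series, spec: FieldSpec, table: str) -> pd.Series:
    kind = _PANDAS_KIND[spec.semantic_type]
    try:
        if kind == "id":
            return pd.to_numeric(col, errors="raise").astype("Int64")
        if kind == "float":
            return pd.to_numeric(col, errors="raise").astype("Float64")
        if kind in ("date", "datetime"):
            out = pd.to_datetime(col, errors="raise", format="mixed")
            return out
        return col
    except (ValueError, TypeError):
        # locate the first offending cell for the error message
        for i, v in col.items():
            if pd.isna(v):
                continue
            try:
                if kind in ("date", "datetime"):
                    pd.to_datetime(v)
                else:
                    float(v)
            except (ValueError, TypeError):
                raise DatasetError(
                    f"unparseable cell in {table}.{spec.field_name} "
                    f"at row {i}: {v!r}") from None
        raise


def load_cdm_dataset(data_dir: Path, manifest: SchemaManifest,
                     site: str = "site") -> Dataset:
    """Read one CSV per manifest table into a typed :class:`Dataset`.

    Missing table files and unknown columns are hard errors; row order is
    preserved.
    """
    data_dir = Path(data_dir)
    tables: dict[str, pd.DataFrame] = {}
    for table in manifest.tables:
        path = data_dir / f"{table}.csv"
        if not path.exists():
            raise DatasetError(f"table file absent: {table}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        expected = [f.field_name for f in manifest.fields_of(table)]
        unknown = [c for c in df.columns if c not in expected]
        if unknown:
            raise DatasetError(f"unknown columns in {table}: {unknown}")
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns in {table}: {missing}")
        for spec in manifest.fields_of(table):
            df[spec.field_name] = _convert_column(df[spec.field_name], spec, table)
        tables[table] = df[expected]
    return Dataset(tables=tables, site=site)


def write_cdm_dataset(ds: Dataset, out_dir: Path,
                      manifest: SchemaManifest) -> None:
    """Write a dataset as one CSV per table (inverse of :func:`load_cdm_dataset`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for table in manifest.tables:
        df = ds.tables[table].copy()
        for spec in manifest.fields_of(table):
            col = df[spec.field_name]
            if spec.semantic_type == "date":
                df[spec.field_name] = col.dt.strftime("%Y-%m-%d")
            elif spec.semantic_type == "datetime":
                df[spec.field_name] = col.dt.strftime("%Y-%m-%dT%H:%M:%S")
            elif spec.semantic_type == "numeric":
                df[spec.field_name] = col.astype(object)
            elif _PANDAS_KIND[spec.semantic_type] == "id":
                df[spec.field_name] = col.astype(object)
        df.to_csv(out_dir / f"{table}.csv", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Pre-workflow integrity / conformance validation


@dataclass(frozen=True)
class ConformanceViolation:
    kind: str           # mandatory_null | duplicate_key | dangling_fk
    table: str
    field: str
    detail: str
    row_count: int = 1


@dataclass
class ConformanceReport:
    violations: list[ConformanceViolation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def by_kind(self, kind: str) -> list[ConformanceViolation]:
        return [v for v in self.violations if v.kind == kind]


def validate_conformance(ds: Dataset, manifest: SchemaManifest) -> ConformanceReport:
    """Integrity constraints validated before the DQ workflow proper:
    mandatory-field nulls, duplicate primary keys, dangling required FKs.
    """
    out: list[ConformanceViolation] = []
    for table in manifest.tables:
        df = ds.tables[table]
        for spec in manifest.fields_of(table):
            col = df[spec.field_name]
            if not spec.nullable:
                n = int(col.isna().sum())
                if n:
                    out.append(ConformanceViolation(
                        "mandatory_null", table, spec.field_name,
                        f"{n} null value(s) in mandatory field", n))
            if spec.semantic_type == "primary_key":
                dup = int(col.duplicated().sum())
                if dup:
                    out.append(ConformanceViolation(
                        "duplicate_key", table, spec.field_name,
                        f"{dup} duplicated key value(s)", dup))
            if spec.semantic_type == "foreign_key_required" and spec.fk_ref:
                ref_table, ref_field = spec.fk_ref
                refs = set(ds.tables[ref_table][ref_field].dropna())
                dangling = int((~col.dropna().isin(refs)).sum())
                if dangling:
                    out.append(ConformanceViolation(
                        "dangling_fk", table, spec.field_name,
                        f"{dangling} value(s) absent from {ref_table}.{ref_field}",
                        dangling))
    return ConformanceReport(violations=out)


# ---------------------------------------------------------------------------
# Catalog statistics


@dataclass
class CatalogStats:
    total_checks: int
    check_types: int
    category_counts: dict[str, int]
    category_percentages: dict[str, float]
    fields_with_one: int
    fields_with_two: int
    fields_with_three_plus: int
    fields_uncovered: int
    table_level_checks: int

    def to_dict(self) -> dict:
        return {
            "total_checks": self.total_checks,
            "check_types": self.check_types,
            "category_counts": dict(self.category_counts),
            "category_percentages": dict(self.category_percentages),
            "fields_with_one_check": self.fields_with_one,
            "fields_with_two_checks": self.fields_with_two,
            "fields_with_three_plus_checks": self.fields_with_three_plus,
            "fields_uncovered": self.fields_uncovered,
            "table_level_checks": self.table_level_checks,
        }


def catalog_stats(cat: Catalog) -> CatalogStats:
    """Aggregate composition of a catalog.

    A check is attributed to its primary target field when its scope is
    field-shaped; table- and cross-table-scoped checks count as table-level.
    The four coverage counts partition the manifest's fields.
    """
    per_field: dict[tuple[str, str], int] = {}
    cat_counts = {k: 0 for k in sorted(HARMONIZED_CATEGORIES)}
    table_level = 0
    for c in cat.checks:
        ts = cat.type_of(c)
        cat_counts[ts.harmonized_category] += 1
        if ts.scope in ("field", "field_pair") and c.field is not None:
            key = (c.table, c.field)
            per_field[key] = per_field.get(key, 0) + 1
        else:
            table_level += 1
    total = len(cat.checks)
    pct = {k: round_half_even(100.0 * v / total) if total else 0.0
           for k, v in cat_counts.items()}
    one = sum(1 for v in per_field.values() if v == 1)
    two = sum(1 for v in per_field.values() if v == 2)
    three = sum(1 for v in per_field.values() if v >= 3)
    uncovered = len(cat.manifest) - len(per_field)
    return CatalogStats(
        total_checks=total, check_types=len({c.type_alias for c in cat.checks}),
        category_counts=cat_counts, category_percentages=pct,
        fields_with_one=one, fields_with_two=two, fields_with_three_plus=three,
        fields_uncovered=uncovered, table_level_checks=table_level)
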