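"""Construct the shipped reference schema manifest and check catalog.

The network publishes only aggregate statistics about its check catalog
(total checks, check types, harmonized-category shares, per-field coverage
counts, table-level checks).  This script reconstructs a concrete catalog
that reproduces every one of those aggregates exactly, following the
documented per-field assignment patterns (concept-identifier fields carry
vocabulary/mapping/completeness checks, date fields carry temporal
plausibility checks, source-value fields carry source/concept agreement
checks, numeric fields carry outlier checks).  The output is committed as
package data; re-running the script is deterministic.

Outputs (written into src/cdmdq/data/):
    schema.csv       one row per CDM field
    check_types.csv  the 30 check-type records
    catalog.csv      the 685 check instances
    concept_pool.csv miniature vocabulary fixture
    crosswalk.csv    source->standard mapping fixture (with deprecated rows)
"""
from __future__ import annotations

import csv
import io
import json
from collections import Counter
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "cdmdq" / "data"

# ---------------------------------------------------------------------------
# Check types: 23 aliases named by the network, 7 reconstructed variants.
# Columns: alias, name, method_category, harmonized_category, scope,
#          result_kind, reconstructed
CHECK_TYPES = [
    # element presence -------------------------------------------------------
    ("MissData", "missing or unpopulated values", "element_presence", "completeness", "field", "percentage", 0),
    ("MissConceptID", "missing or unmapped concept identifier", "element_presence", "completeness", "field", "percentage", 0),
    ("MissFact", "persons lacking an expected fact", "element_presence", "completeness", "field", "count", 0),
    ("MissVisitFact", "visits without clinical facts", "element_presence", "completeness", "table", "percentage", 0),
    ("MissVisitLink", "facts lacking an encounter link", "element_presence", "completeness", "field", "percentage", 1),
    # element agreement ------------------------------------------------------
    ("InconDateTime", "inconsistent date and datetime", "element_agreement", "temporal_plausibility", "field_pair", "count", 0),
    ("InconVisitType", "inconsistent visit types across domains", "element_agreement", "atemporal_plausibility", "cross_table", "count", 0),
    ("InconSource", "inconsistent nullness of source value and concept", "element_agreement", "atemporal_plausibility", "field_pair", "count", 0),
    ("ImplEvent", "event start after event end", "element_agreement", "temporal_plausibility", "field_pair", "count", 0),
    # source agreement -------------------------------------------------------
    ("UnexDiff", "unexpected change in record count between cycles", "source_agreement", "temporal_plausibility", "table", "percentage", 0),
    ("UnexMiss", "unexpected change in completeness between cycles", "source_agreement", "completeness", "field", "percentage", 0),
    # distribution comparison ------------------------------------------------
    ("UnexTop", "unexpected most frequent values", "distribution_comparison", "atemporal_plausibility", "field", "value_list", 0),
    ("UnexTopSource", "unexpected most frequent source values", "distribution_comparison", "atemporal_plausibility", "field", "value_list", 1),
    ("UnexFact", "unexpected concepts absent from reference inventories", "distribution_comparison", "atemporal_plausibility", "field", "value_list", 0),
    ("TempOutlier", "outlier months in longitudinal fact volume", "distribution_comparison", "temporal_plausibility", "field", "value_list", 0),
    ("TempOutlierFact", "outlier months in table-level fact volume", "distribution_comparison", "temporal_plausibility", "table", "value_list", 1),
    # face validity ----------------------------------------------------------
    ("InvalidConID", "concept identifier absent from vocabulary", "face_validity", "value_conformance", "field", "count", 0),
    ("InvalidVocab", "concept from a vocabulary not allowed for the field", "face_validity", "value_conformance", "field", "count", 0),
    ("InvalidValue", "value outside the allowed value set", "face_validity", "value_conformance", "field", "count", 0),
    ("InvalidMap", "deprecated source-to-standard mapping", "face_validity", "value_conformance", "field_pair", "count", 0),
    ("InvalidDomain", "concept domain inconsistent with the field", "face_validity", "value_conformance", "field", "count", 1),
    ("InconCohort", "inclusion criteria violation", "face_validity", "atemporal_plausibility", "table", "count", 0),
    ("ImplFutureDate", "fact dated in the future", "face_validity", "temporal_plausibility", "field", "count", 0),
    ("ImplPastDate", "fact dated before the plausibility floor", "face_validity", "temporal_plausibility", "field", "count", 0),
    ("ImplAge", "fact dated at an implausible age", "face_validity", "temporal_plausibility", "field", "count", 1),
    ("PreBirth", "fact dated before birth", "face_validity", "temporal_plausibility", "field_pair", "count", 0),
    ("PostDeath", "fact dated after death", "face_validity", "temporal_plausibility", "field_pair", "count", 0),
    ("NumOutlier", "numeric value outside robust fences", "face_validity", "atemporal_plausibility", "field", "count", 0),
    ("NumOutlierUnit", "numeric value outside unit-stratified robust fences", "face_validity", "atemporal_plausibility", "field", "count", 1),
    ("OrphanFact", "fact relationship referencing a missing fact", "face_validity", "relational_conformance", "cross_table", "count", 1),
]

# ---------------------------------------------------------------------------
# Schema manifest.  Role tags drive check assignment:
#   UNC  uncovered (primary keys, mandatory FKs, untransmitted / free text)
#   DHA  date, high coverage, paired start/end           (10 checks)
#   DHB  date, high coverage, unpaired                   (9 checks)
#   D2   date, two checks (MissData + one temporal)
#   TWIN datetime twin of a DHA/DHB field (MissData only)
#   F1   one-check MissData field (optional FK / birth datetime)
#   FV   encounter-link FK: one MissVisitLink check
#   CA9/CA10/CA11  clinical concept-id field (MissFact applies)
#   CB9/CB10       non-clinical concept-id field (UnexMiss instead of MissFact)
#   CL   lesser concept-id field: MissData + UnexFact
#   S1   source-value field: InconSource
#   S2   source-value field: InconSource + UnexTopSource
#   V1   categorical field: InvalidValue
#   N2   numeric: MissData + NumOutlier (or NumOutlierUnit)
# Tuples: (table, field, role, semantic_type override or None)

SCHEMA: list[tuple[str, str, str]] = []


def T(table, *fields):
    for f in fields:
        SCHEMA.append((table, f[0], f[1]))


T("person",
  ("person_id", "PK"),
  ("gender_concept_id", "CB10"),
  ("race_concept_id", "CB10"),
  ("ethnicity_concept_id", "CB9"),
  ("language_concept_id", "CL"),
  ("gender_source_concept_id", "CL"),
  ("race_source_concept_id", "CL"),
  ("ethnicity_source_concept_id", "CL"),
  ("year_of_birth", "V1"),
  ("month_of_birth", "V1"),
  ("day_of_birth", "V1"),
  ("time_of_birth", "F1"),
  ("gestational_age", "N2"),
  ("gender_source_value", "S2"),
  ("race_source_value", "S2"),
  ("ethnicity_source_value", "S2"),
  ("language_source_value", "S1"),
  ("location_id", "F1"),
  ("birth_weight_category", "V1"),
  ("vital_status", "V1"))

T("visit_occurrence",
  ("visit_occurrence_id", "PK"),
  ("person_id", "FKR"),
  ("visit_concept_id", "CA10"),
  ("visit_type_concept_id", "CA10"),
  ("visit_source_concept_id", "CA10"),
  ("admitting_source_concept_id", "CA9"),
  ("discharge_to_concept_id", "CA10"),
  ("visit_start_date", "DHA"),
  ("visit_start_datetime", "TWIN"),
  ("visit_end_date", "DHA"),
  ("visit_end_datetime", "TWIN"),
  ("provider_id", "F1"),
  ("care_site_id", "F1"),
  ("visit_source_value", "S2"),
  ("admitting_source_value", "S1"),
  ("discharge_to_source_value", "S1"))

T("condition_occurrence",
  ("condition_occurrence_id", "PK"),
  ("person_id", "FKR"),
  ("visit_occurrence_id", "FV"),
  ("condition_concept_id", "CA11"),
  ("condition_type_concept_id", "CA10"),
  ("condition_source_concept_id", "CA10"),
  ("condition_status_concept_id", "CA9"),
  ("poa_concept_id", "CA9"),
  ("condition_start_date", "DHA"),
  ("condition_start_datetime", "TWIN"),
  ("condition_end_date", "DHA"),
  ("condition_end_datetime", "TWIN"),
  ("condition_source_value", "S2"),
  ("condition_status_source_value", "S1"),
  ("poa_source_value", "S1"),
  ("stop_reason", "V1"))

T("drug_exposure",
  ("drug_exposure_id", "PK"),
  ("person_id", "FKR"),
  ("visit_occurrence_id", "FV"),
  ("drug_concept_id", "CA11"),
  ("drug_type_concept_id", "CA9"),
  ("drug_source_concept_id", "CA10"),
  ("route_concept_id", "CA10"),
  ("dose_unit_concept_id", "CA9"),
  ("drug_exposure_start_date", "DHA"),
  ("drug_exposure_start_datetime", "TWIN"),
  ("drug_exposure_end_date", "DHA"),
  ("drug_exposure_end_datetime", "TWIN"),
  ("quantity", "N2"),
  ("days_supply", "N2"),
  ("refills", "N2"),
  ("drug_source_value", "S2"),
  ("route_source_value", "S2"),
  ("dose_unit_source_value", "S1"),
  ("drug_type_source_value", "S1"),
  ("sig", "FT"))

T("procedure_occurrence",
  ("procedure_occurrence_id", "PK"),
  ("person_id", "FKR"),
  ("visit_occurrence_id", "FV"),
  ("procedure_concept_id", "CA10"),
  ("procedure_type_concept_id", "CA9"),
  ("procedure_source_concept_id", "CA10"),
  ("modifier_concept_id", "CA9"),
  ("procedure_date", "D2"),
  ("procedure_source_value", "S2"),
  ("modifier_source_value", "S1"),
  ("procedure_type_source_value", "S1"))

T("measurement",
  ("measurement_id", "PK"),
  ("person_id", "FKR"),
  ("visit_occurrence_id", "FV"),
  ("measurement_concept_id", "CA10"),
  ("measurement_type_concept_id", "CA10"),
  ("measurement_source_concept_id", "CA10"),
  ("operator_concept_id", "CA9"),
  ("unit_concept_id", "CA10"),
  ("value_as_concept_id", "CA10"),
  ("priority_concept_id", "CA9"),
  ("specimen_concept_id", "CA10"),
  ("measurement_date", "DHB"),
  ("measurement_datetime", "TWIN"),
  ("value_as_number", "N2U"),
  ("range_low", "N2"),
  ("range_high", "N2"),
  ("measurement_source_value", "S2"),
  ("unit_source_value", "S1"),
  ("priority_source_value", "S1"),
  ("specimen_source_value", "S1"),
  ("operator_source_value", "S1"),
  ("value_source_value", "FT"))

T("observation",
  ("observation_id", "PK"),
  ("person_id", "FKR"),
  ("visit_occurrence_id", "FV"),
  ("observation_concept_id", "CA10"),
  ("observation_type_concept_id", "CA9"),
  ("observation_source_concept_id", "CA10"),
  ("value_as_concept_id", "CA10"),
  ("qualifier_concept_id", "CA10"),
  ("unit_concept_id", "CA10"),
  ("observation_date", "DHB"),
  ("observation_datetime", "TWIN"),
  ("value_as_number", "N2U"),
  ("observation_source_value", "S2"),
  ("unit_source_value", "S1"),
  ("qualifier_source_value", "S1"))

T("death",
  ("person_id", "FKR"),
  ("cause_concept_id", "CB10"),
  ("death_type_concept_id", "CB9"),
  ("cause_source_concept_id", "CL"),
  ("death_date", "D2"),
  ("cause_source_value", "S2"),
  ("death_type_source_value", "S1"),
  ("death_location", "V1"),
  ("autopsy_flag", "V1"))

T("location",
  ("location_id", "PK"),
  ("state", "V1"),
  ("county", "V1"),
  ("country", "V1"),
  ("zip_band", "V1"),
  ("location_type", "V1"))

T("care_site",
  ("care_site_id", "PK"),
  ("place_of_service_concept_id", "CB10"),
  ("specialty_concept_id", "CL"),
  ("care_site_type_concept_id", "CL"),
  ("place_of_service_source_value", "S2"),
  ("place_of_service", "V1"),
  ("specialty_tier", "V1"),
  ("active_flag", "V1"))

T("provider",
  ("provider_id", "PK"),
  ("specialty_concept_id", "CB10"),
  ("gender_concept_id", "CB9"),
  ("provider_type_concept_id", "CL"),
  ("specialty_source_value", "S2"),
  ("gender_source_value", "S1"),
  ("year_of_graduation", "V1"),
  ("specialty_group", "V1"),
  ("active_flag", "V1"),
  ("npi", "FT"),
  ("dea", "FT"))

T("fact_relationship",
  ("domain_concept_id_1", "CL"),
  ("fact_id_1", "FKR"),
  ("domain_concept_id_2", "CL"),
  ("fact_id_2", "FKR"),
  ("relationship_concept_id", "CL"),
  ("relationship_polarity", "V1"))

T("visit_payer",
  ("visit_occurrence_id", "FV"),
  ("plan_concept_id", "CB10"),
  ("plan_type_concept_id", "CL"),
  ("payer_concept_id", "CL"),
  ("plan_start_date", "D2"),
  ("plan_source_value", "S2"),
  ("plan_type_source_value", "S1"),
  ("plan_class", "V1"),
  ("coverage_type", "V1"),
  ("plan_tier", "V1"))

T("adt_occurrence",
  ("visit_occurrence_id", "FV"),
  ("service_concept_id", "CB10"),
  ("adt_type_concept_id", "CL"),
  ("discharge_disposition_concept_id", "CL"),
  ("prior_service_concept_id", "CL"),
  ("adt_date", "D2"),
  ("service_source_value", "S2"),
  ("adt_type_source_value", "S1"),
  ("unit_type", "V1"),
  ("bed_class", "V1"),
  ("admit_source", "V1"))

T("measurement_organism",
  ("person_id", "FKR"),
  ("organism_concept_id", "CB10"),
  ("organism_type_concept_id", "CL"),
  ("specimen_source_concept_id", "CL"),
  ("specimen_date", "D2"),
  ("organism_source_value", "S2"),
  ("isolation_site", "V1"),
  ("culture_result", "V1"))

# ---------------------------------------------------------------------------
# Value sets for categorical fields (pipe-joined in the CSV).
STATES = ("PA WA DE OH NY NJ CA TX FL IL MA MD VA NC GA CO MN MO TN WI").split()
VALUE_SETS = {
    ("person", "year_of_birth"): [str(y) for y in range(1985, 2018)],
    ("person", "month_of_birth"): [str(m) for m in range(1, 13)],
    ("person", "day_of_birth"): [str(d) for d in range(1, 29)],
    ("person", "birth_weight_category"): ["very_low", "low", "normal", "high"],
    ("person", "vital_status"): ["alive", "deceased"],
    ("condition_occurrence", "stop_reason"): ["resolved", "ongoing", "ruled_out", "transferred"],
    ("location", "state"): STATES,
    ("location", "county"): [f"county_{i:02d}" for i in range(1, 21)],
    ("location", "country"): ["US"],
    ("location", "zip_band"): [f"{z:03d}" for z in (100, 152, 190, 191, 197, 432, 981)],
    ("location", "location_type"): ["home", "facility", "po_box"],
    ("care_site", "place_of_service"): ["inpatient", "outpatient", "emergency", "laboratory"],
    ("care_site", "specialty_tier"): ["primary", "secondary", "tertiary"],
    ("care_site", "active_flag"): ["Y", "N"],
    ("provider", "year_of_graduation"): [str(y) for y in range(1970, 2016)],
    ("provider", "specialty_group"): ["pediatrics", "surgery", "radiology", "pathology", "other"],
    ("provider", "active_flag"): ["Y", "N"],
    ("fact_relationship", "relationship_polarity"): ["forward", "reverse"],
    ("visit_payer", "plan_class"): ["commercial", "medicaid", "medicare", "self_pay", "other"],
    ("visit_payer", "coverage_type"): ["primary", "secondary"],
    ("visit_payer", "plan_tier"): ["gold", "silver", "bronze", "none"],
    ("adt_occurrence", "unit_type"): ["icu", "nicu", "picu", "ward", "ed", "or"],
    ("adt_occurrence", "bed_class"): ["standard", "isolation", "intensive"],
    ("adt_occurrence", "admit_source"): ["ed", "transfer", "direct", "newborn"],
    ("death", "death_location"): ["hospital", "home", "hospice", "other"],
    ("death", "autopsy_flag"): ["Y", "N", "U"],
    ("measurement_organism", "isolation_site"): ["blood", "urine", "csf", "wound", "respiratory"],
    ("measurement_organism", "culture_result"): ["positive", "negative", "contaminated"],
}

# Allowed vocabularies / expected concept domains per concept field.
# (vocabulary, domain) defaults by field-name heuristics; overrides below.
VOCAB_RULES = {
    ("visit_occurrence", "visit_concept_id"): ("Visit", "Visit"),
    ("visit_occurrence", "visit_source_concept_id"): ("Visit|SourceVisit", "Visit"),
    ("visit_occurrence", "admitting_source_concept_id"): ("AdmitSource", "Visit"),
    ("visit_occurrence", "discharge_to_concept_id"): ("Disposition", "Disposition"),
    ("condition_occurrence", "condition_concept_id"): ("SNOMED", "Condition"),
    ("condition_occurrence", "condition_source_concept_id"): ("ICD9CM|ICD10CM", "Condition"),
    ("condition_occurrence", "condition_status_concept_id"): ("Status", "Status"),
    ("condition_occurrence", "poa_concept_id"): ("POA", "Status"),
    ("drug_exposure", "drug_concept_id"): ("RxNorm", "Drug"),
    ("drug_exposure", "drug_source_concept_id"): ("NDC", "Drug"),
    ("drug_exposure", "route_concept_id"): ("Route", "Route"),
    ("drug_exposure", "dose_unit_concept_id"): ("UCUM", "Unit"),
    ("procedure_occurrence", "procedure_concept_id"): ("CPT4|SNOMED", "Procedure"),
    ("procedure_occurrence", "procedure_source_concept_id"): ("CPT4|ICD9Proc", "Procedure"),
    ("procedure_occurrence", "modifier_concept_id"): ("Modifier", "Modifier"),
    ("measurement", "measurement_concept_id"): ("LOINC", "Measurement"),
    ("measurement", "measurement_source_concept_id"): ("LOINC|Local", "Measurement"),
    ("measurement", "operator_concept_id"): ("Operator", "Operator"),
    ("measurement", "unit_concept_id"): ("UCUM", "Unit"),
    ("measurement", "value_as_concept_id"): ("Qualifier", "Qualifier"),
    ("measurement", "priority_concept_id"): ("Priority", "Priority"),
    ("measurement", "specimen_concept_id"): ("Specimen", "Specimen"),
    ("observation", "observation_concept_id"): ("LOINC|SNOMED", "Observation"),
    ("observation", "observation_source_concept_id"): ("LOINC|Local", "Observation"),
    ("observation", "value_as_concept_id"): ("Qualifier", "Qualifier"),
    ("observation", "qualifier_concept_id"): ("Qualifier", "Qualifier"),
    ("observation", "unit_concept_id"): ("UCUM", "Unit"),
    ("person", "gender_concept_id"): ("Gender", "Gender"),
    ("person", "race_concept_id"): ("Race", "Race"),
    ("person", "ethnicity_concept_id"): ("Ethnicity", "Ethnicity"),
    ("person", "language_concept_id"): ("Language", "Language"),
    ("person", "gender_source_concept_id"): ("Local", "Gender"),
    ("person", "race_source_concept_id"): ("Local", "Race"),
    ("person", "ethnicity_source_concept_id"): ("Local", "Ethnicity"),
    ("death", "cause_concept_id"): ("SNOMED", "Condition"),
    ("death", "death_type_concept_id"): ("Type", "Type"),
    ("death", "cause_source_concept_id"): ("ICD9CM|ICD10CM", "Condition"),
    ("care_site", "place_of_service_concept_id"): ("PlaceOfService", "PlaceOfService"),
    ("care_site", "specialty_concept_id"): ("Specialty", "Specialty"),
    ("care_site", "care_site_type_concept_id"): ("Type", "Type"),
    ("provider", "specialty_concept_id"): ("Specialty", "Specialty"),
    ("provider", "gender_concept_id"): ("Gender", "Gender"),
    ("provider", "provider_type_concept_id"): ("Type", "Type"),
    ("fact_relationship", "domain_concept_id_1"): ("Domain", "Domain"),
    ("fact_relationship", "domain_concept_id_2"): ("Domain", "Domain"),
    ("fact_relationship", "relationship_concept_id"): ("Relationship", "Relationship"),
    ("visit_payer", "plan_concept_id"): ("Plan", "Plan"),
    ("visit_payer", "plan_type_concept_id"): ("Type", "Type"),
    ("visit_payer", "payer_concept_id"): ("Payer", "Payer"),
    ("adt_occurrence", "service_concept_id"): ("Service", "Service"),
    ("adt_occurrence", "adt_type_concept_id"): ("Type", "Type"),
    ("adt_occurrence", "discharge_disposition_concept_id"): ("Disposition", "Disposition"),
    ("adt_occurrence", "prior_service_concept_id"): ("Service", "Service"),
    ("measurement_organism", "organism_concept_id"): ("SNOMED", "Organism"),
    ("measurement_organism", "organism_type_concept_id"): ("Type", "Type"),
    ("measurement_organism", "specimen_source_concept_id"): ("Specimen", "Specimen"),
}

# Default *_type_concept_id rule
for t, f, r in SCHEMA:
    if f.endswith("_type_concept_id") and (t, f) not in VOCAB_RULES:
        VOCAB_RULES[(t, f)] = ("Type", "Type")

PRIMARY_SOURCE = {
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

IMPL_EVENT_PAIRS = {
    ("visit_occurrence", "visit_start_date"): ("visit_start_date", "visit_end_date"),
    ("visit_occurrence", "visit_end_date"): ("visit_start_date", "visit_end_date"),
    ("condition_occurrence", "condition_start_date"): ("condition_start_date", "condition_end_date"),
    ("condition_occurrence", "condition_end_date"): ("condition_start_date", "condition_end_date"),
    ("drug_exposure", "drug_exposure_start_date"): ("drug_exposure_start_date", "drug_exposure_end_date"),
    ("drug_exposure", "drug_exposure_end_date"): ("drug_exposure_start_date", "drug_exposure_end_date"),
}

D2_TEMPORAL = {
    ("procedure_occurrence", "procedure_date"): "ImplFutureDate",
    ("death", "death_date"): "ImplFutureDate",
    ("adt_occurrence", "adt_date"): "ImplFutureDate",
    ("visit_payer", "plan_start_date"): "ImplPastDate",
    ("measurement_organism", "specimen_date"): "ImplFutureDate",
}

FIELDS = {(t, f) for t, f, _ in SCHEMA}
ROLE = {(t, f): r for t, f, r in SCHEMA}


def source_partner(table: str, concept_field: str) -> str:
    base = concept_field[: -len("_concept_id")]
    cand = base + "_source_value"
    if (table, cand) in FIELDS:
        return cand
    if base.endswith("_source"):
        cand = base + "_value"
        if (table, cand) in FIELDS:
            return cand
    return PRIMARY_SOURCE[table]


def concept_partner(table: str, source_field: str) -> str:
    base = source_field[: -len("_source_value")]
    for cand in (base + "_concept_id", base + "_source_concept_id"):
        if (table, cand) in FIELDS:
            return cand
    raise KeyError(f"no concept partner for {table}.{source_field}")


def build_checks():
    """Return list of dicts: alias, targets (list of 'table.field' or 'table'),
    lower, upper, params."""
    checks = []

    def add(alias, targets, lower=None, upper=None, **params):
        checks.append({
            "type_alias": alias,
            "targets": targets,
            "lower_threshold": lower,
            "upper_threshold": upper,
            "params": params or None,
        })

    for table, field, role in SCHEMA:
        tf = f"{table}.{field}"
        if role in ("PK", "FKR", "FT"):
            continue
        if role == "F1":
            add("MissData", [tf], 0, 10)
        elif role == "TWIN":
            add("MissData", [tf], 0, 10)
        elif role == "FV":
            add("MissVisitLink", [tf], 0, 10)
        elif role == "V1":
            add("InvalidValue", [tf], 0, 0)
        elif role == "S1":
            add("InconSource", [tf, f"{table}.{concept_partner(table, field)}"], 0, 0)
        elif role == "S2":
            add("InconSource", [tf, f"{table}.{concept_partner(table, field)}"], 0, 0)
            add("UnexTopSource", [tf], k=1, top=50)
        elif role == "N2":
            add("MissData", [tf], 0, 10)
            add("NumOutlier", [tf], 0, 0, k_iqr=3.0)
        elif role == "N2U":
            add("MissData", [tf], 0, 10)
            add("NumOutlierUnit", [tf], 0, 0, k_iqr=3.0,
                unit_field="unit_concept_id")
        elif role == "CL":
            add("MissData", [tf], 0, 10)
            add("UnexFact", [tf])
        elif role == "D2":
            add("MissData", [tf], 0, 10)
            alias = D2_TEMPORAL[(table, field)]
            if alias == "ImplPastDate":
                add(alias, [tf], 0, 0, floor="2000-01-01")
            else:
                add(alias, [tf], 0, 0)
        elif role in ("DHA", "DHB"):
            add("MissData", [tf], 0, 10)
            add("UnexMiss", [tf], -10, 10)
            add("ImplPastDate", [tf], 0, 0, floor="2000-01-01")
            add("ImplFutureDate", [tf], 0, 0)
            if role == "DHA":
                start, end = IMPL_EVENT_PAIRS[(table, field)]
                other = end if field == start else start
                add("ImplEvent", [tf, f"{table}.{other}"], 0, 0,
                    start=start, end=end)
            add("PreBirth", [tf, "person.time_of_birth"], 0, 0)
            add("PostDeath", [tf, "death.death_date"], 0, 0, grace_days=0)
            add("InconDateTime", [tf, f"{table}.{field}time".replace("datetime", "date")], 0, 0)
            # twin name: X_date -> X_datetime
            checks[-1]["targets"][1] = f"{table}.{field}time"
            add("TempOutlier", [tf], cutoff=3.5, min_months=12)
            add("ImplAge", [tf], 0, 0, max_years=30)
        elif role.startswith("CA") or role.startswith("CB"):
            size = int(role[2:])
            kind = role[:2]
            add("MissData", [tf], 0, 10)
            add("MissConceptID", [tf], 0, 10)
            if kind == "CA":
                add("MissFact", [tf], 0, 0)
                if size == 11:
                    add("UnexMiss", [tf], -10, 10)
            else:
                add("UnexMiss", [tf], -10, 10)
            add("InvalidConID", [tf], 0, 0)
            add("InvalidVocab", [tf], 0, 0)
            add("InvalidMap", [tf], 0, 0)
            add("InvalidDomain", [tf], 0, 0)
            add("InconSource", [tf, f"{table}.{source_partner(table, field)}"], 0, 0)
            add("UnexTop", [tf], k=1, top=50)
            if size >= 10:
                add("UnexFact", [tf])
        else:
            raise AssertionError(f"unhandled role {role}")

    # ------------------------------------------------------------------ table level
    for table in ("visit_occurrence", "condition_occurrence", "drug_exposure",
                  "procedure_occurrence", "measurement", "observation", "death"):
        add("UnexDiff", [table], 0, 15)
    for table, date_field in (("visit_occurrence", "visit_start_date"),
                              ("condition_occurrence", "condition_start_date"),
                              ("drug_exposure", "drug_exposure_start_date"),
                              ("procedure_occurrence", "procedure_date")):
        add("TempOutlierFact", [table], cutoff=3.5, min_months=12,
            date_field=date_field)
    add("MissVisitFact", ["visit_occurrence"], 0, 5)
    add("InconCohort", ["person"], 0, 0, max_entry_age_years=22)
    add("InconVisitType", ["visit_occurrence", "adt_occurrence"], 0, 0,
        visit_concept=9201)
    for domain_cid, table in ((19, "condition_occurrence"), (13, "drug_exposure"),
                              (10, "procedure_occurrence"), (21, "measurement")):
        add("OrphanFact", ["fact_relationship", table], 0, 0,
            domain_concept_id=domain_cid)
    return checks


# ---------------------------------------------------------------------------
# Concept pool + crosswalk fixtures.

def build_pool():
    pool = []   # concept_id, concept_name, vocabulary, domain, standard, code
    xwalk = []  # source_concept_id, target_concept_id, status

    def c(cid, name, vocab, domain, standard="S", code=""):
        pool.append((cid, name, vocab, domain, standard, code))

    # SNOMED conditions (standard). Ids in the 4xx/44x million-ish range.
    cond_names = ["Acute upper respiratory infection", "Otitis media", "Asthma",
                  "Attention deficit hyperactivity disorder", "Fever",
                  "Acute pharyngitis", "Viral gastroenteritis", "Atopic dermatitis",
                  "Allergic rhinitis", "Acute bronchiolitis", "Constipation",
                  "Urinary tract infection", "Pneumonia", "Croup", "Obesity",
                  "Anemia", "Migraine", "Epilepsy", "Type 1 diabetes mellitus",
                  "Scoliosis", "Anxiety disorder", "Depressive disorder",
                  "Conjunctivitis", "Sinusitis", "Influenza", "Varicella",
                  "Eczema herpeticum", "Appendicitis", "Fracture of radius",
                  "Concussion", "Dehydration", "Failure to thrive",
                  "Gastroesophageal reflux", "Food allergy", "Speech delay",
                  "Autism spectrum disorder", "Seizure disorder", "Bronchitis",
                  "Laryngitis", "Impetigo"]
    for i, name in enumerate(cond_names):
        c(441000 + i, name, "SNOMED", "Condition")
    # Long tail of less frequent conditions so that reference top-50 rank
    # comparisons are non-degenerate.
    for i in range(len(cond_names), 70):
        c(441000 + i, f"Uncommon pediatric condition {i}", "SNOMED", "Condition")
    c(4171519, "Shooting pain", "SNOMED", "Condition")
    # ICD9CM condition source concepts (non-standard) + crosswalk.
    for i in range(12):
        cid = 44820000 + i
        c(cid, f"ICD9 condition code {460 + i}", "ICD9CM", "Condition", "N",
          f"{460 + i}.0")
        status = "deprecated" if i >= 9 else "valid"
        xwalk.append((cid, 441000 + i, status))
    # RxNorm drugs (standard) and NDC source drugs (non-standard).
    drug_names = ["Amoxicillin", "Azithromycin", "Albuterol", "Ibuprofen",
                  "Acetaminophen", "Cetirizine", "Fluticasone", "Montelukast",
                  "Methylphenidate", "Omeprazole", "Ondansetron", "Prednisolone",
                  "Cephalexin", "Clindamycin", "Diphenhydramine", "Epinephrine",
                  "Insulin glargine", "Lamotrigine", "Levetiracetam", "Loratadine",
                  "Melatonin", "Miralax", "Mupirocin", "Nystatin", "Oseltamivir"]
    for i, name in enumerate(drug_names):
        c(1125000 + i, name, "RxNorm", "Drug")
    for i in range(8):
        cid = 44920000 + i
        c(cid, f"NDC package {i}", "NDC", "Drug", "N", f"00093-{4155 + i}-73")
        xwalk.append((cid, 1125000 + i, "valid"))
    # Procedures.
    proc_names = ["Office visit procedure", "Immunization administration",
                  "Venipuncture", "Throat culture", "Radiograph of chest",
                  "Tympanostomy", "Appendectomy", "Laceration repair",
                  "Nebulizer treatment", "Lumbar puncture", "Circumcision",
                  "Fracture reduction", "Hearing screening", "Vision screening",
                  "Developmental screening"]
    for i, name in enumerate(proc_names):
        c(2100000 + i, name, "CPT4", "Procedure", "S", f"99{200 + i}")
    for i in range(5):
        cid = 44930000 + i
        c(cid, f"ICD9 procedure {i}", "ICD9Proc", "Procedure", "N", f"38.{90 + i}")
        xwalk.append((cid, 2100000 + i, "valid"))
    # Measurements (LOINC).
    meas_names = ["Body weight", "Body height", "Heart rate", "Respiratory rate",
                  "Systolic blood pressure", "Diastolic blood pressure",
                  "Hemoglobin", "Hematocrit", "White blood cell count",
                  "Platelet count", "Sodium", "Potassium", "Glucose",
                  "Creatinine", "Bilirubin total", "Lead blood level",
                  "Hemoglobin A1c", "C-reactive protein", "Ferritin", "TSH"]
    for i, name in enumerate(meas_names):
        c(3000000 + i, name, "LOINC", "Measurement", "S", f"{8302 + i}-2")
    for i in range(6):
        cid = 44940000 + i
        c(cid, f"Local lab code {i}", "Local", "Measurement", "N", f"LAB{i:03d}")
        xwalk.append((cid, 3000000 + i, "valid"))
    # Observations.
    obs_names = ["Tobacco smoke exposure", "Breastfeeding status",
                 "Immunization status", "Dietary intake", "Physical activity",
                 "Housing status", "School attendance", "Developmental milestone",
                 "Pain severity score", "Fall risk"]
    for i, name in enumerate(obs_names):
        c(4000000 + i, name, "SNOMED", "Observation")
    for i in range(4):
        c(3900000 + i, f"Observation panel {i}", "LOINC", "Observation", "S",
          f"{62600 + i}-1")
    # Organisms.
    org_names = ["Escherichia coli", "Staphylococcus aureus",
                 "Streptococcus pneumoniae", "Haemophilus influenzae",
                 "Klebsiella pneumoniae", "Pseudomonas aeruginosa",
                 "Candida albicans", "Group B streptococcus"]
    for i, name in enumerate(org_names):
        c(4300000 + i, name, "SNOMED", "Organism")
    # Visit / ADT related.
    c(9201, "Inpatient visit", "Visit", "Visit")
    c(9202, "Outpatient visit", "Visit", "Visit")
    c(9203, "Emergency room visit", "Visit", "Visit")
    for i, name in enumerate(["Source inpatient", "Source outpatient", "Source ED"]):
        c(9290 + i, name, "SourceVisit", "Visit", "N")
    for i, name in enumerate(["Transfer from home", "Transfer from clinic",
                              "Born in hospital"]):
        c(9310 + i, name, "AdmitSource", "Visit")
    for i, name in enumerate(["Discharged home", "Transferred to SNF",
                              "Left against advice", "Expired"]):
        c(9320 + i, name, "Disposition", "Disposition")
    # Type concepts.
    for i, name in enumerate(["EHR encounter record", "EHR order", "EHR billing",
                              "Claim", "Lab feed", "Registry", "EHR problem list",
                              "EHR medication list", "Vital sign record",
                              "EHR note derived"]):
        c(44818700 + i, name, "Type", "Type")
    # Units (UCUM).
    for i, (name, code) in enumerate([("kilogram", "kg"), ("centimeter", "cm"),
                                      ("per minute", "/min"),
                                      ("millimeter mercury", "mm[Hg]"),
                                      ("gram per deciliter", "g/dL"),
                                      ("percent", "%"),
                                      ("milligram", "mg"), ("milliliter", "mL"),
                                      ("week", "wk")]):
        c(8600 + i, name, "UCUM", "Unit", "S", code)
    # Routes.
    for i, name in enumerate(["Oral", "Intravenous", "Inhalation", "Topical",
                              "Intramuscular"]):
        c(4132160 + i, name, "Route", "Route")
    # Demographics.
    c(8507, "Male", "Gender", "Gender")
    c(8532, "Female", "Gender", "Gender")
    for i, name in enumerate(["White", "Black or African American", "Asian",
                              "Multiple race", "Other race"]):
        c(8510 + i, name, "Race", "Race")
    c(38003563, "Hispanic or Latino", "Ethnicity", "Ethnicity")
    c(38003564, "Not Hispanic or Latino", "Ethnicity", "Ethnicity")
    for i, name in enumerate(["English", "Spanish", "Mandarin", "Arabic"]):
        c(4182340 + i, name, "Language", "Language")
    for i, dom in enumerate(["Gender", "Gender", "Race", "Race", "Race",
                             "Ethnicity", "Ethnicity", "Language", "Language"]):
        c(44950000 + i, f"Local {dom.lower()} code {i}", "Local", dom, "N",
          f"DEM{i}")
    # Specialty / place of service / plan / payer / service.
    for i, name in enumerate(["General pediatrics", "Pediatric cardiology",
                              "Pediatric surgery", "Neonatology",
                              "Pediatric neurology", "Radiology"]):
        c(38004440 + i, name, "Specialty", "Specialty")
    for i, name in enumerate(["Inpatient hospital", "Outpatient clinic",
                              "Emergency department", "Independent laboratory"]):
        c(8710 + i, name, "PlaceOfService", "PlaceOfService")
    for i, name in enumerate(["HMO plan", "PPO plan", "Medicaid managed care",
                              "CHIP plan", "Self pay"]):
        c(8810 + i, name, "Plan", "Plan")
    for i, name in enumerate(["Commercial payer", "State medicaid",
                              "Federal payer"]):
        c(8830 + i, name, "Payer", "Payer")
    for i, name in enumerate(["General pediatrics service", "Intensive care",
                              "Neonatal intensive care", "Surgery service",
                              "Emergency service", "Oncology service"]):
        c(8850 + i, name, "Service", "Service")
    # Qualifier / operator / priority / specimen / modifier / status / POA /
    # relationship / domain.
    for i, name in enumerate(["Positive", "Negative", "Abnormal", "Normal"]):
        c(4123500 + i, name, "Qualifier", "Qualifier")
    for i, name in enumerate(["=", "<", ">", "<=", ">="]):
        c(4172700 + i, name, "Operator", "Operator")
    for i, name in enumerate(["Routine", "Stat", "Timed"]):
        c(8900 + i, name, "Priority", "Priority")
    for i, name in enumerate(["Blood specimen", "Urine specimen", "CSF specimen",
                              "Swab specimen", "Tissue specimen"]):
        c(8920 + i, name, "Specimen", "Specimen")
    for i, name in enumerate(["Bilateral", "Left", "Right", "Repeat"]):
        c(8940 + i, name, "Modifier", "Modifier")
    for i, name in enumerate(["Active", "Resolved", "Admitting", "Final"]):
        c(8960 + i, name, "Status", "Status")
    for i, name in enumerate(["Present on admission", "Not present on admission",
                              "Unknown POA"]):
        c(8980 + i, name, "POA", "Status")
    for i, name in enumerate(["Measurement of condition", "Drug for condition",
                              "Parent of", "Child of"]):
        c(44818800 + i, name, "Relationship", "Relationship")
    for cid, name in ((19, "Condition domain"), (13, "Drug domain"),
                      (10, "Procedure domain"), (21, "Measurement domain")):
        c(cid, name, "Domain", "Domain")
    assert len({p[0] for p in pool}) == len(pool), "duplicate concept ids"
    return pool, xwalk


# ---------------------------------------------------------------------------

def verify(checks):
    type_info = {t[0]: t for t in CHECK_TYPES}
    n = len(checks)
    aliases = {c["type_alias"] for c in checks}
    cat = Counter(type_info[c["type_alias"]][3] for c in checks)
    field_cov = Counter()
    table_level = 0
    for c in checks:
        primary = c["targets"][0]
        if "." in primary and type_info[c["type_alias"]][4] in ("field", "field_pair"):
            field_cov[primary] += 1
        else:
            table_level += 1
    cov_counts = Counter(field_cov.values())
    n_fields = len(SCHEMA)
    covered = len(field_cov)
    one = sum(1 for v in field_cov.values() if v == 1)
    two = sum(1 for v in field_cov.values() if v == 2)
    three = sum(1 for v in field_cov.values() if v >= 3)
    uncovered = n_fields - covered

    print(f"total checks          : {n}")
    print(f"check types used      : {len(aliases)} / {len(CHECK_TYPES)}")
    print(f"harmonized categories : {dict(cat)}")
    print(f"fields total          : {n_fields}")
    print(f"coverage 1/2/3+/0     : {one}/{two}/{three}/{uncovered}")
    print(f"table-level checks    : {table_level}")
    print(f"coverage histogram    : {dict(sorted(cov_counts.items()))}")

    assert n == 685, n
    assert len(aliases) == 30, sorted(set(type_info) - aliases)
    assert cat["completeness"] == 201, cat
    assert cat["temporal_plausibility"] == 78, cat
    assert cat["atemporal_plausibility"] == 198, cat
    assert cat["value_conformance"] == 204, cat
    assert cat["relational_conformance"] == 4, cat
    assert n_fields == 189, n_fields
    assert (one, two, three, uncovered) == (66, 47, 52, 24)
    assert table_level == 18, table_level


SEMTYPE = {
    "PK": "primary_key", "FKR": "foreign_key_required", "FT": "free_text",
    "F1": "foreign_key_optional", "FV": "foreign_key_optional",
    "TWIN": "datetime", "DHA": "date", "DHB": "date", "D2": "date",
    "S1": "source_value", "S2": "source_value", "V1": "categorical",
    "N2": "numeric", "N2U": "numeric",
}


def semtype(table, field, role):
    if role.startswith(("CA", "CB")) or role == "CL":
        return "concept_id"
    st = SEMTYPE[role]
    if (table, field) in (("person", "time_of_birth"),):
        return "datetime"
    if field in ("year_of_birth", "month_of_birth", "day_of_birth",
                 "year_of_graduation"):
        return "categorical"
    return st


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    checks = build_checks()
    verify(checks)
    pool, xwalk = build_pool()

    with open(OUT / "check_types.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["alias", "name", "method_category", "harmonized_category",
                    "scope", "result_kind", "reconstructed"])
        w.writerows(CHECK_TYPES)

    with open(OUT / "schema.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["table", "field", "semantic_type", "nullable", "value_set",
                    "allowed_vocabs", "expected_domain", "fk_ref"])
        for table, field, role in SCHEMA:
            st = semtype(table, field, role)
            nullable = "0" if role in ("PK", "FKR") else "1"
            vs = "|".join(VALUE_SETS.get((table, field), []))
            vocab, domain = VOCAB_RULES.get((table, field), ("", ""))
            fk_ref = ""
            if role == "FKR" and field == "person_id":
                fk_ref = "person.person_id"
            elif role == "FKR" and field == "visit_occurrence_id":
                fk_ref = "visit_occurrence.visit_occurrence_id"
            w.writerow([table, field, st, nullable, vs, vocab, domain, fk_ref])

    with open(OUT / "catalog.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["type_alias", "targets", "lower_threshold",
                    "upper_threshold", "params"])
        for c in checks:
            w.writerow([
                c["type_alias"], "+".join(c["targets"]),
                "" if c["lower_threshold"] is None else c["lower_threshold"],
                "" if c["upper_threshold"] is None else c["upper_threshold"],
                json.dumps(c["params"], separators=(",", ":")) if c["params"] else "",
            ])

    with open(OUT / "concept_pool.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["concept_id", "concept_name", "vocabulary", "domain",
                    "standard", "source_code"])
        w.writerows(sorted(pool))

    with open(OUT / "crosswalk.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_concept_id", "target_concept_id", "status"])
        w.writerows(sorted(xwalk))

    for name in ("schema.csv", "check_types.csv", "catalog.csv",
                 "concept_pool.csv", "crosswalk.csv"):
        print(name, (OUT / name).stat().st_size, "bytes")


if __name__ == "__main__":
    main()
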