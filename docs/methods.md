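# Methods

## The assessment model

One *data cycle* assesses one site's CDM submission in four steps:

1. **Checks.** Every instance in the check catalog is evaluated against the
   dataset, producing exactly one finding — a count, a percentage, or a list
   of flagged values — plus a bounded sample of offending rows. Integrity
   constraints (mandatory fields, unique keys, required foreign keys) are
   *not* checks: they are validated before the workflow and abort it unless
   overridden, so every check can assume a structurally sound dataset.
2. **Threshold gating and reconciliation.** A finding becomes an issue
   candidate when its value falls strictly outside the closed interval
   [lower_threshold, upper_threshold] (list-valued findings: when the list
   is non-empty). Each candidate is matched against the warehouse for a
   *similar* prior-cycle issue — same check type, same target field set,
   status persistent or under review. The signed difference of the two
   findings, in native units, is gated by per-check-type bounds
   (missingness-type checks default to −10…+10 percentage points,
   inclusive). Within bounds the candidate aligns and inherits its
   predecessor's status; outside, a difference-investigation issue is
   opened referencing both findings. List-valued findings reconcile by set
   comparison: aligned iff nothing newly flagged.
3. **Publication.** New issues (including difference issues) become tracker
   documents; under-review issues redirect to their predecessor's existing
   document; persistent issues are not propagated. Labels encode cycle,
   status, domain and cause.
4. **Adjudication.** Status and cause edits are made by humans on the
   tracker documents and synchronized back (`sync_from_tracker`); the state
   machine rejects illegal moves, and every accepted transition is appended
   to an audit trail from which the current status can be replayed.

## Check evaluators: conventions and edge cases

* **Unmapped concepts.** A concept_id that is null *or 0* counts as unmapped
  (`MissConceptID`); 0 is the conventional "no matching concept" sentinel.
  Unmapped values are excluded from vocabulary, domain, mapping and ranking
  checks so a single unmapped record trips exactly one check.
* **Pre-birth boundary.** A fact dated exactly on the birth date is not a
  violation; the comparison is strictly-before at day resolution (birth
  datetime normalized to midnight, with a fallback to the year/month/day
  component columns when the birth timestamp is null). Records whose person
  has no usable birth reference are excluded from the denominator and noted
  in the finding description.
* **Post-death grace.** Default grace window 0 days; configurable per check
  for networks where discharge paperwork legitimately postdates death.
* **Date/datetime agreement** compares only rows where both columns are
  present; nullness asymmetries belong to completeness checks.
* **Mapping validity** (`InvalidMap`) flags only source→standard pairs that
  the packaged crosswalk explicitly marks deprecated. Pairs absent from the
  crosswalk are not violations: the fixture crosswalk is a miniature
  stand-in for a full vocabulary, and treating unknown pairs as errors would
  make its coverage, not the data, the thing under test.
* **Monthly-volume outliers** (`TempOutlier`): the series is the per-month
  count of a date column, restricted to the plausible window (floor date …
  current date) and to the central 1–99 % quantile range of the dates (thin
  scatter far outside the bulk is the business of the implausible-date
  checks, and would otherwise drag the series median toward zero). The
  first and last remaining months are dropped as partial. A month is
  flagged when |0.6745 (x − median) / scale| > 3.5 with
  scale = max(MAD, √median). The √median floor is the Poisson scale of
  count data: without it a near-uniform series has a near-zero MAD and
  ordinary sampling noise flags as an outlier. Fewer than 12 usable months
  skips the check.
* **Numeric outliers**: Tukey fences at k × IQR (default 3.0) beyond the
  quartiles; strata with fewer than 20 values are not assessed. The
  unit-stratified variant applies the same fences per unit_concept_id group.
* **Rank outliers** (`UnexTop`): the site's top-k values (default k = 1) are
  flagged when absent from every reference site's top-50. `UnexFact` flags
  values absent from the reference sites' entire inventories.
* **Skipped ≠ passed.** Source-agreement checks without a prior-cycle
  summary, distribution checks without reference ranks for that field, and
  temporal series that are too short are reported as *skipped*; skipped and
  failed findings never produce candidates. An exception inside one check
  yields an engine-failure record (the raw material of "false alarm: bug in
  the DQ workflow" causes) and never aborts the run.

## The reference catalog

The network publishes only aggregates about its catalog: 685 checks from 30
types; harmonized shares 29.34 % completeness, 11.38 % temporal
plausibility, 28.9 % atemporal plausibility, 29.78 % value conformance,
0.59 % relational conformance; 66 / 47 / 52 fields with one / two / three-
or-more checks, 24 fields with none, and 18 table-level checks. The shipped
catalog (`src/cdmdq/data/catalog.csv`, generated by
`scripts/build_reference_catalog.py`) reconstructs a concrete catalog
reproducing every one of those aggregates over a 189-field schema manifest,
following the published per-field patterns: concept-identifier fields carry
vocabulary/mapping/completeness checks, date fields carry the temporal
plausibility family, source-value fields carry source/concept agreement,
numeric fields carry MissData + outlier checks, optional foreign keys carry
MissData alone, and primary keys / mandatory foreign keys / untransmitted
free-text fields carry none.

Two reconciliations are worth noting. At two-decimal rounding the shipped
counts give 11.39 % temporal plausibility and 0.58 % relational conformance
(the published 11.38 / 0.59 are internally inconsistent with any integer
split of 685); the counts 78 and 4 are authoritative here. And 23 of the 30
type aliases are named in the literature; the remaining 7 (`MissVisitLink`,
`ImplAge`, `TempOutlierFact`, `NumOutlierUnit`, `UnexTopSource`,
`InvalidDomain`, `OrphanFact`) are parameterized variants of the named
methods, marked `reconstructed` in `check_types.csv`. Check coverage is
attributed to a check's *primary* (first) target field; secondary pair
members (the birth timestamp in PreBirth pairs, datetime twins in
InconDateTime pairs) are not double-counted — the published coverage
partition cannot hold otherwise.

Thresholds are data, not code: they live in the catalog file. Plausibility
and conformance checks default to [0, 0] (any violation is an issue);
missingness-style percentages default to [0, 10]; cross-cycle record growth
to [0, 15]; cross-cycle missingness drift to [−10, 10].

## The synthetic test bed

`generate_clean` emulates one pediatric site: a cohort born before the
observation window (ages 0–21 at window start), 1 + Poisson visits per
person, facts in five clinical domains with standard concepts and
non-standard source codes drawn from a packaged ~260-concept vocabulary
fixture, ADT events for every inpatient stay, a payer row per visit, and a
small death cohort (2 % by default) whose facts all precede death.

Cleanliness is structural, not statistical, so it holds for every seed:

* numeric values are clipped inside their robust fences (scales are keyed
  by unit so unit-stratified fences see one bounded distribution each);
* monthly volumes are assigned by bounded-jitter quota (±10 % around a flat
  profile), and fact tables get their own quota rather than thinning visit
  months — thinning would reintroduce unbounded relative noise;
* every person has at least one fact per clinical domain and every visit at
  least one fact, so presence checks read zero;
* all dates are confined to [birth, current date] and [floor, window end].

What the generator does **not** emulate: seasonality or trend in volumes,
clinically coherent code co-occurrence, realistic visit-to-fact date
coupling (fact months are sampled independently of the hosting visit's
month), inter-site heterogeneity beyond rank jitter, or free-text content.
Passing tests therefore demonstrate that the engine recovers exactly the
defects injected under known, well-behaved conditions — not that the checks
are calibrated for the messiness of real site data, where thresholds would
need tuning against observed distributions.

`inject_defects` plants exactly *n* defects of each requested class through
per-class random substreams (adding a class never perturbs another) and
returns a realized manifest with: the altered row keys, the exact finding
delta every check should report, and the *enumerated cross-talk* a class
unavoidably produces. Two classes are inherently cross-talking: a fact
dated before the 2000-01-01 plausibility floor in a cohort born after it is
necessarily also pre-birth (the manifest records the exact PreBirth
increment), and a start-after-end defect is reported by both
endpoint-attributed instances of the pair check. The monthly-spike class
duplicates visits *with their facts* into the target months (keeping
visit-fact linkage and ADT consistency), so the fact-table volume checks
may flag the same months; the manifest lists them as allowed subsets.

`make_cycle_pair` produces consecutive-cycle datasets with exact drift:
growth by a rational factor is realized by trimming the previous cycle's
table to a row count on which the factor is integral (never trimming a
person's first row, never trimming rows referenced by fact_relationship)
and duplicating rows with fresh keys; missingness drift nulls a monotone
superset of rows so the current cycle's nulls contain the previous cycle's.

## Numerical and interface choices

* Percentages are reported to two decimals, round-half-even.
* Check ids are deterministic: `alias::primary_target[+secondary…]`, with
  targets in declared order (primary first) so the two direction-attributed
  instances of one agreement pair stay distinct.
* Execution order is sorted by check id; findings are invariant under row
  permutation of the input tables.
* CSV conventions: UTF-8, RFC 4180, ISO-8601 dates, empty string ≡ null.
* The warehouse is a JSON-lines file plus a cycles index; issue ids are
  `site:cycle_date:check_id:ordinal`. Single-writer per site per cycle.
* A solution-proposed issue whose fix does not materialize next cycle is
  treated as new, with a note naming the failed predecessor.
* Exit codes: 0 success, 2 conformance failure, 3 catalog error,
  4 warehouse conflict, 1 other.

## Problem sizes

The test suite and acceptance script scale their fixtures to what the
properties require: 200–600 persons for the worked examples, 1 000 persons
for the defect-recovery matrix (15 classes × up to three injection sizes,
n ∈ {1, 5, 50} for row-level classes; list-valued statistics use the sizes
they can express — a top-1 rank outlier is a single concept, and a 36-month
series holds at most a few spiked months), 2 000 persons for the
11 557-pre-birth fixture, and 8–40 persons for the brute-force row-scan
oracles. A 10 000-person site generates in a few seconds and a full
685-check run takes well under a second of CPU.

## Known limitations

* The 685-check-to-field assignment is a reconstruction; only the published
  aggregates are authoritative. Per-field threshold values are defaults,
  not the network's operational values (most were never published).
* The vocabulary fixture is a miniature stand-in; `InvalidVocab` /
  `InvalidMap` exercise the mechanism, not real OMOP vocabulary coverage.
* The reconciler matches on (check type, field set) only — the similarity
  notion of the source workflow — so two candidates from the same check in
  one cycle would tie-break deterministically rather than match
  semantically.
* The tracker backend is a filesystem adapter; a live issue-tracker adapter
  satisfies the same two-method contract but is out of scope.
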