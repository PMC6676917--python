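# cdmdq

Continuous data-quality (DQ) assessment for clinical research networks that
pool electronic-health-record data in an OMOP-style common data model (CDM).
Networks ingest a fresh CDM submission from each member hospital every *data
cycle*; before that data can support research, someone has to ask: are the
key fields populated, are the coded values conformant with the network's
vocabularies and conventions, are dates clinically plausible, and did
anything shift suspiciously since the last submission?

`cdmdq` packages that assessment as a reusable engine:

* a **check catalog** of 685 check instances drawn from 30 check types,
  spanning five computational methods (element presence, element agreement,
  data-source agreement, distribution comparison, face validity) and the
  harmonized DQ terminology (completeness, temporal/atemporal plausibility,
  value/relational conformance);
* a **cross-cycle reconciler** that matches each flagged finding against the
  prior cycle's issue history and opens a *difference-investigation* issue
  only when the change exceeds configured bounds (e.g. ±10 percentage points
  of missingness);
* an **issue warehouse** with a status lifecycle (new → under review →
  solution proposed / persistent / withdrawn) and a cause taxonomy
  (ETL error, data characteristic, false alarm), persisted as diff-able
  JSON lines;
* a **tracker adapter** that renders each issue as a Markdown document with
  a machine-readable label block (cycle, status, domain, cause) and syncs
  label edits back into the warehouse;
* a **synthetic-data module** that generates pediatric CDM fixtures and
  injects exactly *n* defects of any of 15 classes, with realized ground
  truth for sensitivity/specificity testing.

The statistics at the core are deliberately simple and robust: a finding is
promoted to an issue when its value leaves the closed interval
[lower_threshold, upper_threshold]; cross-cycle record-count change is
|curr − prev| / prev × 100; monthly fact volumes are screened with the
modified z-score 0.6745 (x − median) / max(MAD, √median) at cutoff 3.5;
numeric outliers use Tukey fences at 3 × IQR.

## Worked example

Generate a synthetic site, then run one assessment cycle:

```bash
dq synth --out site_a --seed 5 --n-persons 200
dq run --data-dir site_a --warehouse wh.jsonl --reports reports \
      --site site_a --cycle-date 2016-04-01 --ranks site_a/reference_ranks.csv
```

prints

```json
{
 "site": "site_a",
 "cycle_date": "2016-04-01",
 "checks_run": 685,
 "checks_skipped": 135,
 "engine_failures": 0,
 "candidates": 0,
 "new_issues": 0,
 "aligned_issues": 0,
 "difference_issues": 0,
 "documents_created": 0,
 "conformance_violations": 0,
 "elapsed_seconds": 0.388
}
```

All 685 checks ran; 135 were skipped because their required context (a prior
cycle summary, or reference ranks for that particular field) was absent —
skipped is reported honestly, never conflated with passing. The clean
synthetic site produces zero candidates, so no issues are recorded and no
tracker documents are written. Re-running the same cycle without `--force`
exits with code 4 (`cycle already recorded`).

The same pipeline is available as a library:

```python
from cdmdq import (SynthProfile, generate_clean, load_schema_manifest,
                   load_catalog, run_checks, findings_to_candidates,
                   make_reference_context)

manifest = load_schema_manifest()          # 189-field CDM manifest
catalog = load_catalog(manifest=manifest)  # 685 checks / 30 types
profile = SynthProfile(n_persons=1000, seed=1)
ds = generate_clean(profile, manifest)
findings = run_checks(ds, catalog, make_reference_context(profile))
candidates = findings_to_candidates(findings, catalog)   # -> []
```

`dq catalog validate` prints the catalog composition (total checks, check
types, harmonized-category shares, per-field coverage); `dq warehouse sync`
pulls edited status/cause labels from rendered issue documents back into the
warehouse, rejecting illegal lifecycle moves.

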