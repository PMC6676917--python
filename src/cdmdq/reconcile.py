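"""Cross-cycle difference investigation.

Each issue candidate of the current cycle is matched against the issue
warehouse: a *similar* issue persisted from the previous cycle when it has
the same check type and the same target field set and its status is
persistent or under review.  The signed difference between the numerical
findings of the two cycles is then gated by per-check-type bounds (for
missingness-type checks the network accepts a -10 to +10 percentage-point
swing).  Within bounds, the current issue aligns with — and inherits the
status of — its predecessor; outside them, a new difference-investigation
issue is opened referencing both findings.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .checks import Finding, IssueCandidate

PERCENTAGE_DEFAULT = (-10.0, 10.0)
COUNT_DEFAULT = (0.0, 0.0)


@dataclass
class ReconcileConfig:
    """Per-check-type difference bounds; defaults by result kind."""

    per_alias: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    default_percentage: tuple[float, float] = PERCENTAGE_DEFAULT
    default_count: tuple[float, float] = COUNT_DEFAULT

    def __post_init__(self):
        for alias, (lo, hi) in self.per_alias.items():
            if lo > hi:
                raise ValueError(f"inverted difference bounds for {alias}")

    def bounds_for(self, alias: str, result_kind: str) -> tuple[float, float]:
        if alias in self.per_alias:
            return self.per_alias[alias]
        if result_kind == "percentage":
            return self.default_percentage
        return self.default_count

    @classmethod
    def load(cls, path: Optional[Path] = None) -> "ReconcileConfig":
        if path is None:
            src = resources.files("cdmdq.data").joinpath("reconcile_defaults.yaml")
            raw = yaml.safe_load(src.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
        per = {k: tuple(v) for k, v in (raw.get("per_alias") or {}).items()}
        return cls(per_alias=per,
                   default_percentage=tuple(raw.get("default_percentage",
                                                    PERCENTAGE_DEFAULT)),
                   default_count=tuple(raw.get("default_count", COUNT_DEFAULT)))


@dataclass
class DifferenceIssue:
    """A candidate whose change versus the prior cycle exceeded bounds."""

    candidate: IssueCandidate
    prior_issue_id: str
    prior_value: Optional[float]
    delta: Optional[float]
    note: str = ""


@dataclass
class AlignedIssue:
    candidate: IssueCandidate
    prior_issue_id: str
    inherited_status: str
    delta: Optional[float] = None


@dataclass
class NewIssue:
    candidate: IssueCandidate
    note: str = ""


@dataclass
class ReconciledSet:
    """Partition of the cycle's candidates."""

    new_issues: list[NewIssue] = dc_field(default_factory=list)
    aligned_issues: list[AlignedIssue] = dc_field(default_factory=list)
    difference_issues: list[DifferenceIssue] = dc_field(default_factory=list)
    skipped: list[IssueCandidate] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return (len(self.new_issues) + len(self.aligned_issues)
                + len(self.difference_issues) + len(self.skipped))


def find_prior_match(cand: IssueCandidate, wh, prev_cycle) -> Optional[object]:
    """The unique prior-cycle issue with the same check type and target
    field set, still persistent or under review.

    Ties (which stable check ids should preclude) break deterministically on
    the most recent status change.
    """
    matches = []
    for iss in wh.issues_of_cycle(prev_cycle):
        if iss.status not in ("persistent", "under_review"):
            continue
        if iss.type_alias != cand.type_alias:
            continue
        if frozenset(iss.fields) != frozenset(cand.fields) or \
                iss.table != cand.table:
            continue
        matches.append(iss)
    if not matches:
        return None
    if len(matches) > 1:
        matches.sort(key=lambda i: (i.last_status_change(), i.issue_id),
                     reverse=True)
    return matches[0]


def compute_cycle_difference(curr: Finding, prev: Finding) -> float:
    """Signed difference (current minus previous) in the finding's native
    units: percentage points for percentage findings, counts otherwise."""
    if curr.numeric_value is None or prev.numeric_value is None:
        raise ValueError("cycle difference requires numeric findings")
    if curr.type_alias != prev.type_alias:
        raise ValueError("cycle difference requires findings of one check type")
    return float(curr.numeric_value) - float(prev.numeric_value)


def reconcile_issues(cands: list[IssueCandidate], wh, prev_cycle,
                     cfg: Optional[ReconcileConfig] = None) -> ReconciledSet:
    """Partition candidates into new / aligned / difference-investigation /
    skipped.  Difference bounds are inclusive, mirroring check thresholds."""
    cfg = cfg or ReconcileConfig()
    rset = ReconciledSet()
    for cand in cands:
        f = cand.finding
        if f.skipped or f.failed:
            rset.skipped.append(cand)
            continue
        prior = find_prior_match(cand, wh, prev_cycle) if prev_cycle else None
        if prior is None:
            note = ""
            if prev_cycle is not None:
                sp = [i for i in wh.issues_of_cycle(prev_cycle)
                      if i.status == "solution_proposed"
                      and i.type_alias == cand.type_alias
                      and frozenset(i.fields) == frozenset(cand.fields)
                      and i.table == cand.table]
                if sp:
                    note = (f"recurred although a solution was proposed in "
                            f"{sp[0].issue_id}; treating as new")
            rset.new_issues.append(NewIssue(candidate=cand, note=note))
            continue
        if f.result_kind == "value_list":
            # set comparison: aligned iff nothing newly flagged
            prior_set = set(prior.finding.value_list or ())
            curr_set = set(f.value_list or ())
            new_elems = curr_set - prior_set
            if not new_elems:
                rset.aligned_issues.append(AlignedIssue(
                    candidate=cand, prior_issue_id=prior.issue_id,
                    inherited_status=prior.status))
            else:
                rset.difference_issues.append(DifferenceIssue(
                    candidate=cand, prior_issue_id=prior.issue_id,
                    prior_value=None, delta=None,
                    note=f"newly flagged: {sorted(new_elems)}"))
            continue
        delta = compute_cycle_difference(f, prior.finding)
        lo, hi = cfg.bounds_for(cand.type_alias, f.result_kind)
        if lo <= delta <= hi:
            rset.aligned_issues.append(AlignedIssue(
                candidate=cand, prior_issue_id=prior.issue_id,
                inherited_status=prior.status, delta=delta))
        else:
            rset.difference_issues.append(DifferenceIssue(
                candidate=cand, prior_issue_id=prior.issue_id,
                prior_value=prior.finding.numeric_value, delta=delta,
                note=f"difference {delta:+g} outside bounds [{lo:g}, {hi:g}]"))
    return rset
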