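"""The DQ issue warehouse: issues persisted across data cycles with a
status lifecycle, a cause taxonomy, cycle metadata and an audit trail.

Statuses: an issue is *new* when first identified, *under review* while the
site investigates, and from there *solution proposed* (a fix lands next
cycle), *persistent* (expected to remain), or *withdrawn* (a false alarm).
A persistent issue may be reopened for review at a cycle boundary.

Causes are assigned once an issue has been reviewed, and fall into three
coarse classes: ETL (programming error / conventions ambiguity),
characteristic (a true property of the site's data), or false alarm (a
workflow bug or an ETL improvement since the prior cycle).

Storage is a single JSON-lines file (one issue per line) with a sidecar
cycles index — diff-able, serverless, portable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Optional

from .checks import Finding
from .reconcile import ReconciledSet

STATUSES = ("new", "under_review", "solution_proposed", "persistent",
            "withdrawn")
CAUSES = ("etl_programming_error", "etl_conventions_ambiguity",
          "char_incomplete_capture", "char_data_entry_error",
          "char_true_anomaly", "char_ehr_configuration",
          "char_admin_workflow", "false_alarm_workflow_bug",
          "false_alarm_etl_improvement")

_TRANSITIONS = {
    "new": ("under_review",),
    "under_review": ("solution_proposed", "persistent", "withdrawn"),
    "solution_proposed": (),
    "persistent": (),          # reopening requires a cycle boundary
    "withdrawn": (),
}
_CYCLE_BOUNDARY_TRANSITIONS = {"persistent": ("under_review",)}


class LifecycleError(ValueError):
    """An illegal status transition or cause assignment."""


class WarehouseError(ValueError):
    pass


def cause_class(cause: str) -> str:
    """Coarse class of a fine-grained cause: etl | characteristic | false_alarm."""
    if cause.startswith("etl_"):
        return "etl"
    if cause.startswith("char_"):
        return "characteristic"
    if cause.startswith("false_alarm_"):
        return "false_alarm"
    raise LifecycleError(f"unknown cause {cause!r}")


@dataclass(frozen=True)
class DataCycle:
    site: str
    cycle_date: str                 # ISO date, first day of the cycle month
    conventions_version: str = "2.4.0"
    data_version: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.site, self.cycle_date)


@dataclass
class DQIssue:
    issue_id: str
    check_id: str
    type_alias: str
    table: str
    fields: tuple[str, ...]
    finding: Finding
    status: str
    site: str
    cycle_date: str
    data_version: str = ""
    conventions_version: str = "2.4.0"
    cause: Optional[str] = None
    tracker_link: Optional[str] = None
    linked_prior: Optional[str] = None
    note: str = ""
    audit: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.status not in STATUSES:
            raise LifecycleError(f"unknown status {self.status!r}")
        if self.cause is not None and self.cause not in CAUSES:
            raise LifecycleError(f"unknown cause {self.cause!r}")
        if self.cause is not None and self.status == "new":
            raise LifecycleError("a cause may not be set on a new issue")

    def last_status_change(self) -> str:
        return self.audit[-1]["at"] if self.audit else ""

    def replay_status(self, initial: str = "new") -> str:
        """Reproduce the current status from the audit trail."""
        status = initial
        for entry in self.audit:
            assert entry["from"] == status, "broken audit trail"
            status = entry["to"]
        return status

    def to_dict(self) -> dict:
        return {
            "issue_id": self.issue_id, "check_id": self.check_id,
            "type_alias": self.type_alias, "table": self.table,
            "fields": list(self.fields), "finding": self.finding.to_dict(),
            "status": self.status, "cause": self.cause, "site": self.site,
            "cycle_date": self.cycle_date, "data_version": self.data_version,
            "conventions_version": self.conventions_version,
            "tracker_link": self.tracker_link,
            "linked_prior": self.linked_prior, "note": self.note,
            "audit": list(self.audit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DQIssue":
        fd = dict(d["finding"])
        fd["sample_violations"] = tuple(tuple(s) for s in fd["sample_violations"])
        if fd.get("value_list") is not None:
            fd["value_list"] = tuple(fd["value_list"])
        return cls(
            issue_id=d["issue_id"], check_id=d["check_id"],
            type_alias=d["type_alias"], table=d["table"],
            fields=tuple(d["fields"]), finding=Finding(**fd),
            status=d["status"], cause=d.get("cause"), site=d["site"],
            cycle_date=d["cycle_date"], data_version=d.get("data_version", ""),
            conventions_version=d.get("conventions_version", "2.4.0"),
            tracker_link=d.get("tracker_link"),
            linked_prior=d.get("linked_prior"), note=d.get("note", ""),
            audit=list(d.get("audit", [])))


def transition_status(iss: DQIssue, to: str, actor: str,
                      at: str = "", cycle_boundary: bool = False) -> DQIssue:
    """Move an issue through its lifecycle; illegal moves are rejected with
    the list of legal ones.  The transition is appended to the audit trail."""
    if to not in STATUSES:
        raise LifecycleError(f"unknown status {to!r}")
    legal = _TRANSITIONS.get(iss.status, ())
    if cycle_boundary:
        legal = legal + _CYCLE_BOUNDARY_TRANSITIONS.get(iss.status, ())
    if to not in legal:
        raise LifecycleError(
            f"illegal transition {iss.status} -> {to}; legal moves from "
            f"{iss.status}: {sorted(legal) or 'none'}")
    entry = {"from": iss.status, "to": to, "actor": actor, "at": at}
    return replace(iss, status=to, audit=iss.audit + [entry])


def assign_cause(iss: DQIssue, cause: str) -> DQIssue:
    """Record the adjudicated cause; rejected while the issue is still new."""
    if cause not in CAUSES:
        raise LifecycleError(f"unknown cause {cause!r}")
    if iss.status == "new":
        raise LifecycleError("cannot assign a cause to a new issue; review "
                             "it first")
    return replace(iss, cause=cause)


class Warehouse:
    """In-memory issue store with JSON-lines persistence."""

    def __init__(self):
        self.issues: dict[str, DQIssue] = {}
        self.cycles: list[DataCycle] = []

    # ------------------------------------------------------------ recording

    def has_cycle(self, cycle: DataCycle) -> bool:
        return any(c.key == cycle.key for c in self.cycles)

    def record_cycle(self, cycle: DataCycle, rset: ReconciledSet,
                     force: bool = False) -> list[DQIssue]:
        """Store a reconciled cycle.  Issue ids are deterministic
        (site : cycle date : check id : ordinal)."""
        if self.has_cycle(cycle) and not force:
            raise WarehouseError(
                f"cycle already recorded: {cycle.site} {cycle.cycle_date}")
        if not self.has_cycle(cycle):
            self.cycles.append(cycle)
        ordinals: dict[str, int] = {}

        def mk_id(check_id: str) -> str:
            k = ordinals.get(check_id, 0)
            ordinals[check_id] = k + 1
            return f"{cycle.site}:{cycle.cycle_date}:{check_id}:{k}"

        stored = []

        def store(iss: DQIssue):
            self.issues[iss.issue_id] = iss
            stored.append(iss)

        for item in rset.new_issues:
            c = item.candidate
            store(DQIssue(
                issue_id=mk_id(c.check_id), check_id=c.check_id,
                type_alias=c.type_alias, table=c.table, fields=c.fields,
                finding=c.finding, status="new", site=cycle.site,
                cycle_date=cycle.cycle_date,
                data_version=cycle.data_version,
                conventions_version=cycle.conventions_version,
                note=item.note))
        for item in rset.aligned_issues:
            c = item.candidate
            store(DQIssue(
                issue_id=mk_id(c.check_id), check_id=c.check_id,
                type_alias=c.type_alias, table=c.table, fields=c.fields,
                finding=c.finding, status=item.inherited_status,
                site=cycle.site, cycle_date=cycle.cycle_date,
                data_version=cycle.data_version,
                conventions_version=cycle.conventions_version,
                linked_prior=item.prior_issue_id))
        for item in rset.difference_issues:
            c = item.candidate
            store(DQIssue(
                issue_id=mk_id(c.check_id) + ":diff", check_id=c.check_id,
                type_alias=c.type_alias, table=c.table, fields=c.fields,
                finding=c.finding, status="new", site=cycle.site,
                cycle_date=cycle.cycle_date,
                data_version=cycle.data_version,
                conventions_version=cycle.conventions_version,
                linked_prior=item.prior_issue_id, note=item.note))
        return stored

    # -------------------------------------------------------------- queries

    def issues_of_cycle(self, cycle: DataCycle) -> list[DQIssue]:
        return [i for i in self.issues.values()
                if i.site == cycle.site and i.cycle_date == cycle.cycle_date]

    def query_issues(self, **filters) -> list[DQIssue]:
        """Filter issues; conjunctive over keys {site, cycle, status,
        cause_class, domain, check_type}.  Deterministic order."""
        known = {"site", "cycle", "status", "cause_class", "domain",
                 "check_type"}
        unknown = set(filters) - known
        if unknown:
            raise WarehouseError(f"unknown filter key(s): {sorted(unknown)}")
        out = []
        for iss in self.issues.values():
            if "site" in filters and iss.site != filters["site"]:
                continue
            if "cycle" in filters and iss.cycle_date != filters["cycle"]:
                continue
            if "status" in filters and iss.status != filters["status"]:
                continue
            if "cause_class" in filters:
                if iss.cause is None or \
                        cause_class(iss.cause) != filters["cause_class"]:
                    continue
            if "domain" in filters and iss.table != filters["domain"]:
                continue
            if "check_type" in filters and iss.type_alias != filters["check_type"]:
                continue
            out.append(iss)
        return sorted(out, key=lambda i: (i.cycle_date, i.issue_id))

    def update(self, iss: DQIssue) -> None:
        if iss.issue_id not in self.issues:
            raise WarehouseError(f"unknown issue {iss.issue_id}")
        self.issues[iss.issue_id] = iss

    # -------------------------------------------------------- persistence

    def save(self, path: Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            for iid in sorted(self.issues):
                fh.write(json.dumps(self.issues[iid].to_dict(),
                                    separators=(",", ":")) + "\n")
        cycles_path = path.with_suffix(path.suffix + ".cycles.json")
        cycles_path.write_text(json.dumps(
            [{"site": c.site, "cycle_date": c.cycle_date,
              "conventions_version": c.conventions_version,
              "data_version": c.data_version} for c in self.cycles],
            indent=1) + "\n")

    @classmethod
    def load(cls, path: Path) -> "Warehouse":
        wh = cls()
        path = Path(path)
        if path.exists():
            with path.open(encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        iss = DQIssue.from_dict(json.loads(line))
                        wh.issues[iss.issue_id] = iss
        cycles_path = path.with_suffix(path.suffix + ".cycles.json")
        if cycles_path.exists():
            for d in json.loads(cycles_path.read_text()):
                wh.cycles.append(DataCycle(**d))
        return wh


@dataclass
class SyncConflict:
    issue_id: str
    detail: str


@dataclass
class SyncReport:
    applied: list[str] = dc_field(default_factory=list)
    conflicts: list[SyncConflict] = dc_field(default_factory=list)
    unparseable: list[str] = dc_field(default_factory=list)


def sync_from_tracker(wh: Warehouse, reports_dir: Path,
                      actor: str = "tracker-sync") -> SyncReport:
    """Apply status/cause label edits from rendered issue documents back to
    the warehouse.  Illegal transitions are reported as conflicts and leave
    the warehouse unchanged; unparseable documents are listed and skipped."""
    from .reporting import parse_document

    report = SyncReport()
    for path in sorted(Path(reports_dir).rglob("*.md")):
        try:
            doc = parse_document(path.read_text(encoding="utf-8"))
        except Exception:  # noqa: BLE001 - malformed docs are report content
            report.unparseable.append(str(path))
            continue
        iss = wh.issues.get(doc.issue_id)
        if iss is None:
            report.conflicts.append(SyncConflict(
                doc.issue_id or str(path), "unknown issue id"))
            continue
        changed = False
        if doc.status and doc.status != iss.status:
            try:
                iss = transition_status(iss, doc.status, actor=actor)
                changed = True
            except LifecycleError as exc:
                report.conflicts.append(SyncConflict(iss.issue_id, str(exc)))
                continue
        if doc.cause and doc.cause != iss.cause:
            try:
                iss = assign_cause(iss, doc.cause)
                changed = True
            except LifecycleError as exc:
                report.conflicts.append(SyncConflict(iss.issue_id, str(exc)))
                continue
        if changed:
            wh.update(iss)
            report.applied.append(iss.issue_id)
    return report
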