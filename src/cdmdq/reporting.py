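"""Tracker-style issue documents and the pluggable tracker adapter.

Each DQ issue is rendered as one Markdown document with a YAML front-matter
label block.  The body carries the check type, the finding (verbatim), its
numeric value, and a repository-relative hyperlink to the module holding the
check's programming logic; labels encode the data cycle, status, domain and
(once adjudicated) cause, and are the machine-readable channel through which
status/cause edits flow back into the warehouse.

The default tracker backend is a filesystem directory — offline, diff-able
and testable.  A live issue-tracker adapter can implement the same
two-method contract (``create(document) -> ref``, ``get(ref) -> document``).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Protocol

import yaml

from .cdm_model import Catalog
from .warehouse import CAUSES, DQIssue, STATUSES, Warehouse

_METHOD_MODULE = "src/cdmdq/checks.py"


@dataclass(frozen=True)
class ReportConfig:
    source_root: str = ""   # prefix for the source hyperlink, e.g. a repo URL


@dataclass(frozen=True)
class IssueDocument:
    issue_id: str
    site: str
    title: str
    body: str
    labels: tuple[str, ...]

    def to_markdown(self) -> str:
        front = {
            "issue_id": self.issue_id,
            "site": self.site,
            "labels": list(self.labels),
        }
        fm = yaml.safe_dump(front, sort_keys=True, default_flow_style=False)
        return f"---\n{fm}---\n\n# {self.title}\n\n{self.body}\n"


def _kebab(s: str) -> str:
    return s.replace("_", "-")


def _snake(s: str) -> str:
    return s.replace("-", "_")


def issue_labels(iss: DQIssue) -> tuple[str, ...]:
    """Label scheme: exactly one cycle, one status and one domain label,
    plus a cause label once assigned."""
    labels = [
        f"cycle:{iss.cycle_date[:7]}",
        f"status:{_kebab(iss.status)}",
        f"domain:{iss.table}",
    ]
    if iss.cause:
        labels.append(f"cause:{_kebab(iss.cause)}")
    return tuple(labels)


def render_issue(iss: DQIssue, cat: Catalog,
                 cfg: Optional[ReportConfig] = None) -> IssueDocument:
    """Deterministic Markdown document for one issue.

    The header names the source field(s); the body carries the check-type
    name, the finding description verbatim, the numeric value, and a link to
    the implementing module.
    """
    cfg = cfg or ReportConfig()
    check = cat.check(iss.check_id)          # raises KeyError if unresolvable
    ts = cat.type_of(check)
    fields = ", ".join(f"{t}.{f}" for t, f in check.targets if f is not None) \
        or iss.table
    title = f"{fields} — {iss.type_alias}"
    link = (cfg.source_root.rstrip("/") + "/" if cfg.source_root else "") \
        + _METHOD_MODULE
    lines = [
        f"- **Check type:** {ts.name} (`{iss.type_alias}`, "
        f"{ts.method_category.replace('_', ' ')})",
        f"- **Finding:** {iss.finding.description}",
    ]
    if iss.finding.numeric_value is not None:
        lines.append(f"- **Value:** {iss.finding.numeric_value:g}")
    if iss.finding.value_list:
        lines.append("- **Flagged:** "
                     + ", ".join(str(v) for v in iss.finding.value_list))
    if check.lower_threshold is not None or check.upper_threshold is not None:
        lines.append(f"- **Thresholds:** [{check.lower_threshold}, "
                     f"{check.upper_threshold}]")
    if iss.linked_prior:
        lines.append(f"- **Prior issue:** {iss.linked_prior}")
    if iss.note:
        lines.append(f"- **Note:** {iss.note}")
    lines.append(f"- **Check logic:** [{_METHOD_MODULE}]({link})")
    lines.append(f"- **Data version:** {iss.data_version or 'n/a'} "
                 f"(conventions {iss.conventions_version})")
    return IssueDocument(issue_id=iss.issue_id, site=iss.site, title=title,
                         body="\n".join(lines), labels=issue_labels(iss))


@dataclass
class ParsedDocument:
    issue_id: str
    labels: tuple[str, ...]
    status: Optional[str] = None
    cause: Optional[str] = None


def parse_document(text: str) -> ParsedDocument:
    """Read back a rendered document's machine-managed metadata."""
    if not text.startswith("---\n"):
        raise ValueError("missing front matter")
    end = text.index("\n---", 4)
    front = yaml.safe_load(text[4:end + 1])
    labels = tuple(front.get("labels") or ())
    status = cause = None
    for lab in labels:
        if lab.startswith("status:"):
            status = _snake(lab.split(":", 1)[1])
            if status not in STATUSES:
                raise ValueError(f"unknown status label {lab!r}")
        elif lab.startswith("cause:"):
            cause = _snake(lab.split(":", 1)[1])
            if cause not in CAUSES:
                raise ValueError(f"unknown cause label {lab!r}")
    return ParsedDocument(issue_id=front["issue_id"], labels=labels,
                          status=status, cause=cause)


# ---------------------------------------------------------------------------
# Tracker adapter contract


class TrackerAdapter(Protocol):
    def create(self, doc: IssueDocument) -> str: ...
    def get(self, ref: str) -> str: ...


class FilesystemTracker:
    """Default backend: one Markdown file per issue under
    ``<root>/issues/<site>/<issue_id>.md``.  Creation is idempotent by
    issue id."""

    def __init__(self, root: Path):
        self.root = Path(root)

    def _path(self, site: str, issue_id: str) -> Path:
        safe = issue_id.replace("/", "_").replace(":", "_")
        return self.root / "issues" / site / f"{safe}.md"

    def create(self, doc: IssueDocument) -> str:
        path = self._path(doc.site, doc.issue_id)
        if not path.exists():
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(doc.to_markdown(), encoding="utf-8")
        return str(path.relative_to(self.root))

    def get(self, ref: str) -> str:
        return (self.root / ref).read_text(encoding="utf-8")


@dataclass
class PublishResult:
    refs: list[tuple[str, str]] = dc_field(default_factory=list)
    errors: list[tuple[str, str]] = dc_field(default_factory=list)

    @property
    def created(self) -> int:
        return len(self.refs)


def publish(stored: list[DQIssue], cat: Catalog, backend: TrackerAdapter,
            wh: Optional[Warehouse] = None,
            cfg: Optional[ReportConfig] = None) -> PublishResult:
    """Propagate a recorded cycle to the tracker.

    New issues (including difference-investigation issues, which are new by
    construction) get a document; under-review issues redirect to the
    existing document of their predecessor; persistent issues are not
    propagated.  Returned refs are written back as tracker links when a
    warehouse is supplied.  A backend failure on one issue does not stop the
    rest.
    """
    result = PublishResult()
    for iss in sorted(stored, key=lambda i: i.issue_id):
        try:
            if iss.status == "new":
                ref = backend.create(render_issue(iss, cat, cfg))
            elif iss.status == "under_review":
                prior = wh.issues.get(iss.linked_prior) if wh else None
                ref = prior.tracker_link if prior and prior.tracker_link else None
                if ref is None:
                    continue
            else:
                continue   # persistent / later states are not propagated
        except Exception as exc:  # noqa: BLE001 - per-issue error record
            result.errors.append((iss.issue_id, f"{type(exc).__name__}: {exc}"))
            continue
        result.refs.append((iss.issue_id, ref))
        if wh is not None and iss.issue_id in wh.issues:
            wh.issues[iss.issue_id].tracker_link = ref
    return result
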