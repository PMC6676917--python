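"""Issue documents, label scheme, tracker adapter and propagation rules."""
import pytest

from cdmdq.checks import Finding
from cdmdq.reporting import (FilesystemTracker, ReportConfig, parse_document,
                             publish, render_issue)
from cdmdq.warehouse import DQIssue, Warehouse, assign_cause, transition_status

PB_CID = "PreBirth::visit_occurrence.visit_start_date+person.time_of_birth"


def table1_issue(status="persistent", cause="char_true_anomaly"):
    f = Finding(check_id=PB_CID, type_alias="PreBirth", result_kind="count",
                numeric_value=11557.0, violation_count=11557,
                description="11557 visits before patient was born",
                observed_at="ETLv8")
    iss = DQIssue(issue_id="s1:2016-04-01:" + PB_CID + ":0", check_id=PB_CID,
                  type_alias="PreBirth", table="visit_occurrence",
                  fields=("visit_start_date", "time_of_birth"), finding=f,
                  status="new", site="s1", cycle_date="2016-04-01",
                  data_version="ETLv8", conventions_version="2.2.0")
    iss = transition_status(iss, "under_review", "site")
    if status != "under_review":
        iss = transition_status(iss, status, "dcc")
    if cause:
        iss = assign_cause(iss, cause)
    return iss


def mk(status, issue_id, linked_prior=None):
    f = Finding(check_id=PB_CID, type_alias="PreBirth", result_kind="count",
                numeric_value=1.0, violation_count=1, description="1 visit")
    return DQIssue(issue_id=issue_id, check_id=PB_CID, type_alias="PreBirth",
                   table="visit_occurrence",
                   fields=("visit_start_date", "time_of_birth"), finding=f,
                   status=status, site="s1", cycle_date="2016-09-01",
                   linked_prior=linked_prior)


def test_render_table1_style_issue(catalog):
    doc = render_issue(table1_issue(), catalog)
    assert "11557 visits before patient was born" in doc.body
    assert doc.title.startswith("visit_occurrence.visit_start_date")
    assert set(doc.labels) == {"cycle:2016-04", "status:persistent",
                               "domain:visit_occurrence",
                               "cause:char-true-anomaly"}
    assert "checks.py" in doc.body   # hyperlink to the check's source module


def test_render_is_deterministic_and_label_axes_complete(catalog):
    iss = table1_issue()
    d1, d2 = render_issue(iss, catalog), render_issue(iss, catalog)
    assert d1.to_markdown() == d2.to_markdown()
    for issue in (iss, mk("new", "n1")):
        labels = render_issue(issue, catalog).labels
        for axis in ("cycle:", "status:", "domain:"):
            assert sum(1 for l in labels if l.startswith(axis)) == 1


def test_render_unresolvable_check_errors(catalog):
    bad = mk("new", "n1")
    bad.check_id = "MissData::no.such_check"
    with pytest.raises(KeyError):
        render_issue(bad, catalog)


def test_document_parses_back_to_status_and_labels(catalog):
    doc = render_issue(table1_issue(), catalog)
    parsed = parse_document(doc.to_markdown())
    assert parsed.issue_id == doc.issue_id
    assert parsed.status == "persistent"
    assert parsed.cause == "char_true_anomaly"
    assert set(parsed.labels) == set(doc.labels)


def test_publish_propagation_rules(catalog, tmp_path):
    """Two new + one under-review (existing ref) + one persistent: two
    documents created, the prior ref returned, nothing for persistent."""
    wh = Warehouse()
    prior = mk("under_review", "p1")
    prior.tracker_link = "issues/s1/p1.md"
    wh.issues["p1"] = prior
    n1, n2 = mk("new", "n1"), mk("new", "n2")
    ur = mk("under_review", "u1", linked_prior="p1")
    pe = mk("persistent", "pe1")
    for i in (n1, n2, ur, pe):
        wh.issues[i.issue_id] = i
    backend = FilesystemTracker(tmp_path)
    res = publish([n1, n2, ur, pe], catalog, backend, wh)
    created = list((tmp_path / "issues").rglob("*.md"))
    assert len(created) == 2
    assert len(res.refs) == 3
    assert dict(res.refs)["u1"] == "issues/s1/p1.md"
    assert "pe1" not in dict(res.refs)
    assert wh.issues["n1"].tracker_link is not None
    # republish: idempotent by issue id
    res2 = publish([n1, n2, ur, pe], catalog, backend, wh)
    assert len(list((tmp_path / "issues").rglob("*.md"))) == 2


def test_publish_empty_set(catalog, tmp_path):
    res = publish([], catalog, FilesystemTracker(tmp_path), Warehouse())
    assert res.refs == [] and res.errors == []
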