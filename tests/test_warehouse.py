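"""Issue lifecycle, warehouse persistence, queries and tracker sync."""
import itertools

import pytest

from cdmdq.checks import Finding, IssueCandidate
from cdmdq.reconcile import AlignedIssue, NewIssue, ReconciledSet
from cdmdq.warehouse import (CAUSES, DQIssue, DataCycle, LifecycleError,
                             STATUSES, Warehouse, WarehouseError, assign_cause,
                             cause_class, sync_from_tracker, transition_status)

CID = "MissData::person.gestational_age"


def mk_issue(status="new", issue_id="s1:2016-04-01:x:0", cause=None):
    f = Finding(check_id=CID, type_alias="MissData", result_kind="percentage",
                numeric_value=12.0, violation_count=24, description="12%")
    return DQIssue(issue_id=issue_id, check_id=CID, type_alias="MissData",
                   table="person", fields=("gestational_age",), finding=f,
                   status=status, site="s1", cycle_date="2016-04-01",
                   cause=cause)


def mk_candidate(cid=CID):
    f = Finding(check_id=cid, type_alias="MissData", result_kind="percentage",
                numeric_value=12.0, violation_count=24, description="12%")
    return IssueCandidate(check_id=cid, type_alias="MissData", table="person",
                          fields=("gestational_age",), finding=f)


LEGAL = {("new", "under_review"), ("under_review", "solution_proposed"),
         ("under_review", "persistent"), ("under_review", "withdrawn")}


@pytest.mark.parametrize("frm,to", list(itertools.permutations(STATUSES, 2)))
def test_status_transition_matrix(frm, to):
    iss = mk_issue(frm)
    if (frm, to) in LEGAL:
        out = transition_status(iss, to, "tester")
        assert out.status == to
        assert out.audit[-1]["from"] == frm and out.audit[-1]["to"] == to
    else:
        with pytest.raises(LifecycleError, match="legal moves"):
            transition_status(iss, to, "tester")


def test_persistent_reopens_only_at_cycle_boundary():
    iss = mk_issue("persistent")
    with pytest.raises(LifecycleError):
        transition_status(iss, "under_review", "x")
    out = transition_status(iss, "under_review", "x", cycle_boundary=True)
    assert out.status == "under_review"


def test_audit_trail_replays_to_current_status():
    iss = mk_issue("new")
    iss = transition_status(iss, "under_review", "site", at="t1")
    iss = transition_status(iss, "persistent", "dcc", at="t2")
    assert iss.replay_status() == "persistent"
    assert iss.last_status_change() == "t2"


def test_cause_rules():
    with pytest.raises(LifecycleError):
        assign_cause(mk_issue("new"), "char_true_anomaly")
    iss = assign_cause(mk_issue("persistent"), "char_true_anomaly")
    assert iss.cause == "char_true_anomaly"
    iss2 = assign_cause(mk_issue("withdrawn"), "false_alarm_etl_improvement")
    assert cause_class(iss2.cause) == "false_alarm"
    assert {cause_class(c) for c in CAUSES} == \
        {"etl", "characteristic", "false_alarm"}


def test_record_cycle_and_duplicate_guard():
    wh = Warehouse()
    cycle = DataCycle("s1", "2016-04-01")
    rset = ReconciledSet(new_issues=[NewIssue(mk_candidate()),
                                     NewIssue(mk_candidate("MissData::person.time_of_birth")),
                                     NewIssue(mk_candidate("MissData::person.location_id"))])
    stored = wh.record_cycle(cycle, rset)
    assert len(stored) == 3 and all(i.status == "new" for i in stored)
    assert all(i.issue_id.startswith("s1:2016-04-01:") for i in stored)
    with pytest.raises(WarehouseError, match="already recorded"):
        wh.record_cycle(cycle, rset)
    wh.record_cycle(cycle, rset, force=True)   # --force path


def test_aligned_issues_reference_priors():
    wh = Warehouse()
    c1 = DataCycle("s1", "2016-04-01")
    stored = wh.record_cycle(c1, ReconciledSet(
        new_issues=[NewIssue(mk_candidate())]))
    prior = transition_status(stored[0], "under_review", "site")
    prior = transition_status(prior, "persistent", "dcc")
    wh.update(prior)
    c2 = DataCycle("s1", "2016-09-01")
    stored2 = wh.record_cycle(c2, ReconciledSet(aligned_issues=[
        AlignedIssue(candidate=mk_candidate(), prior_issue_id=prior.issue_id,
                     inherited_status="persistent", delta=0.0)]))
    assert stored2[0].status == "persistent"
    assert stored2[0].linked_prior == prior.issue_id
    assert not [i for i in stored2 if i.status == "new"]


def test_query_filters_are_conjunctive():
    wh = Warehouse()
    a = mk_issue("new", "s1:2016-04-01:a:0")
    b = transition_status(mk_issue("new", "s1:2016-04-01:b:0"), "under_review", "x")
    b = transition_status(b, "persistent", "x")
    b = assign_cause(b, "etl_programming_error")
    c = transition_status(mk_issue("new", "s2:2016-04-01:c:0"), "under_review", "x")
    c = assign_cause(c, "etl_conventions_ambiguity")
    for i in (a, b, c):
        wh.issues[i.issue_id] = i
    assert [i.issue_id for i in wh.query_issues(status="new")] == [a.issue_id]
    etl = wh.query_issues(cause_class="etl")
    assert {i.issue_id for i in etl} == {b.issue_id, c.issue_id}
    # conjunction equals intersection of single-filter results
    both = wh.query_issues(cause_class="etl", site="s1")
    inter = {i.issue_id for i in wh.query_issues(cause_class="etl")} & \
        {i.issue_id for i in wh.query_issues(site="s1")}
    assert {i.issue_id for i in both} == inter
    assert len(wh.query_issues()) == 3
    with pytest.raises(WarehouseError, match="unknown filter"):
        wh.query_issues(color="red")


def test_warehouse_serialization_roundtrip(tmp_path):
    wh = Warehouse()
    cycle = DataCycle("s1", "2016-04-01", "2.2.0", "ETLv8")
    wh.record_cycle(cycle, ReconciledSet(new_issues=[NewIssue(mk_candidate())]))
    iss = next(iter(wh.issues.values()))
    iss = transition_status(iss, "under_review", "site", at="t1")
    wh.update(iss)
    path = tmp_path / "wh.jsonl"
    wh.save(path)
    wh2 = Warehouse.load(path)
    assert {k: v.to_dict() for k, v in wh.issues.items()} == \
        {k: v.to_dict() for k, v in wh2.issues.items()}
    assert wh2.cycles == wh.cycles


def test_sync_applies_legal_edits_and_reports_conflicts(tmp_path, catalog):
    from cdmdq.reporting import FilesystemTracker, render_issue

    wh = Warehouse()
    cid = ("PreBirth::visit_occurrence.visit_start_date+person.time_of_birth")
    f = Finding(check_id=cid, type_alias="PreBirth", result_kind="count",
                numeric_value=3.0, violation_count=3,
                description="3 visits before patient was born")
    iss = DQIssue(issue_id="s1:2016-04-01:pb:0", check_id=cid,
                  type_alias="PreBirth", table="visit_occurrence",
                  fields=("visit_start_date", "time_of_birth"), finding=f,
                  status="new", site="s1", cycle_date="2016-04-01")
    wh.issues[iss.issue_id] = iss
    tracker = FilesystemTracker(tmp_path)
    ref = tracker.create(render_issue(iss, catalog))
    # unchanged labels -> no-op
    rep0 = sync_from_tracker(wh, tmp_path / "issues")
    assert rep0.applied == [] and rep0.conflicts == []
    # site relabels to under-review -> applied
    doc_path = tmp_path / ref
    doc_path.write_text(doc_path.read_text().replace("status:new",
                                                     "status:under-review"))
    rep1 = sync_from_tracker(wh, tmp_path / "issues")
    assert rep1.applied == [iss.issue_id]
    assert wh.issues[iss.issue_id].status == "under_review"
    # illegal direct jump -> conflict, warehouse unchanged
    wh.issues[iss.issue_id] = iss   # back to new
    doc_path.write_text(doc_path.read_text().replace("status:under-review",
                                                     "status:withdrawn"))
    rep2 = sync_from_tracker(wh, tmp_path / "issues")
    assert rep2.conflicts and wh.issues[iss.issue_id].status == "new"
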