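"""Cross-cycle reconciliation: matching, difference gating, partitioning."""
import pytest
from hypothesis import given, settings, strategies as st

from cdmdq.checks import Finding, IssueCandidate
from cdmdq.reconcile import (ReconcileConfig, compute_cycle_difference,
                             find_prior_match, reconcile_issues)
from cdmdq.warehouse import DQIssue, DataCycle, Warehouse, transition_status

CID = "MissData::condition_occurrence.condition_end_date"
PREV = DataCycle("s1", "2016-04-01")
CURR = DataCycle("s1", "2016-09-01")


def mk_finding(value, cid=CID, alias="MissData", kind="percentage"):
    return Finding(check_id=cid, type_alias=alias, result_kind=kind,
                   numeric_value=value, violation_count=int(value),
                   description=f"{value}")


def mk_candidate(value, cid=CID, alias="MissData",
                 table="condition_occurrence", fields=("condition_end_date",)):
    return IssueCandidate(check_id=cid, type_alias=alias, table=table,
                          fields=tuple(fields), finding=mk_finding(value, cid, alias))


def mk_prior(value, status="persistent", issue_id="s1:2016-04-01:x:0"):
    iss = DQIssue(issue_id=issue_id, check_id=CID, type_alias="MissData",
                  table="condition_occurrence", fields=("condition_end_date",),
                  finding=mk_finding(value), status="new", site="s1",
                  cycle_date="2016-04-01")
    iss = transition_status(iss, "under_review", "site")
    if status != "under_review":
        iss = transition_status(iss, status, "dcc")
    return iss


def wh_with(*issues):
    wh = Warehouse()
    for i in issues:
        wh.issues[i.issue_id] = i
    return wh


def test_cycle_difference_worked_examples():
    assert compute_cycle_difference(mk_finding(50), mk_finding(30)) == 20
    assert compute_cycle_difference(mk_finding(50), mk_finding(55)) == -5
    assert compute_cycle_difference(mk_finding(50), mk_finding(50)) == 0
    with pytest.raises(ValueError):
        compute_cycle_difference(
            mk_finding(1), mk_finding(1, alias="MissConceptID"))


def test_prior_match_requires_live_status():
    assert find_prior_match(mk_candidate(50), wh_with(mk_prior(30)), PREV) \
        is not None
    withdrawn = mk_prior(30, "withdrawn")
    assert find_prior_match(mk_candidate(50), wh_with(withdrawn), PREV) is None
    assert find_prior_match(mk_candidate(50), Warehouse(), PREV) is None


def test_missingness_worked_example_opens_difference_issue():
    """30% -> 50% missingness exceeds the accepted -10..+10 point swing;
    55% -> 50% does not."""
    rset = reconcile_issues([mk_candidate(50.0)], wh_with(mk_prior(30.0)),
                            PREV, ReconcileConfig())
    assert len(rset.difference_issues) == 1 and not rset.new_issues
    assert rset.difference_issues[0].delta == 20.0
    rset2 = reconcile_issues([mk_candidate(50.0)], wh_with(mk_prior(55.0)),
                             PREV, ReconcileConfig())
    assert not rset2.difference_issues and not rset2.new_issues
    assert rset2.aligned_issues[0].inherited_status == "persistent"


def test_boundary_delta_is_within_bounds():
    rset = reconcile_issues([mk_candidate(40.0)], wh_with(mk_prior(30.0)),
                            PREV, ReconcileConfig())
    assert rset.aligned_issues and not rset.difference_issues  # delta == +10


def test_identical_cycles_align_everything():
    rset = reconcile_issues([mk_candidate(30.0)], wh_with(mk_prior(30.0)),
                            PREV, ReconcileConfig())
    assert len(rset.aligned_issues) == 1
    assert not rset.new_issues and not rset.difference_issues


def test_solution_proposed_recurrence_is_new_with_note():
    rset = reconcile_issues([mk_candidate(30.0)],
                            wh_with(mk_prior(30.0, "solution_proposed")),
                            PREV, ReconcileConfig())
    assert len(rset.new_issues) == 1
    assert "solution" in rset.new_issues[0].note


def test_skipped_findings_partition_to_skipped():
    f = Finding(check_id=CID, type_alias="MissData", result_kind="percentage",
                skipped=True, skip_reason="no prior")
    cand = IssueCandidate(check_id=CID, type_alias="MissData",
                          table="condition_occurrence",
                          fields=("condition_end_date",), finding=f)
    rset = reconcile_issues([cand], Warehouse(), PREV, ReconcileConfig())
    assert rset.skipped == [cand]


def test_value_list_set_reconciliation():
    prior = mk_prior(0)
    prior.finding = Finding(check_id=CID, type_alias="MissData",
                            result_kind="value_list", value_list=(1, 2, 3))
    cand_sub = mk_candidate(0)
    cand_sub.finding.result_kind = "value_list"
    cand_sub.finding.value_list = (2, 3)
    rset = reconcile_issues([cand_sub], wh_with(prior), PREV)
    assert rset.aligned_issues
    cand_new = mk_candidate(0)
    cand_new.finding.result_kind = "value_list"
    cand_new.finding.value_list = (2, 9)
    rset2 = reconcile_issues([cand_new], wh_with(prior), PREV)
    assert rset2.difference_issues


@settings(max_examples=100, derandomize=True)
@given(values=st.lists(st.floats(0, 100), min_size=0, max_size=12),
       priors=st.lists(st.tuples(st.floats(0, 100),
                                 st.sampled_from(["persistent", "under_review",
                                                  "withdrawn"])),
                       min_size=0, max_size=3))
def test_partition_property_and_bruteforce_equivalence(values, priors):
    """new/aligned/difference/skipped partition the candidates, and the
    outcome per candidate equals a brute-force pairwise evaluation."""
    wh = Warehouse()
    for k, (v, status) in enumerate(priors):
        wh.issues[f"p{k}"] = mk_prior(v, status, issue_id=f"p{k}")
    cands = [mk_candidate(v) for v in values]
    cfg = ReconcileConfig()
    rset = reconcile_issues(cands, wh, PREV, cfg)
    assert len(rset) == len(cands)
    live = [wh.issues[k] for k in sorted(wh.issues)
            if wh.issues[k].status in ("persistent", "under_review")]
    for cand in cands:
        # brute force: any live prior with same alias+fields?
        match = live[-1] if live else None
        if match is None:
            assert any(n.candidate is cand for n in rset.new_issues)
        else:
            delta = cand.finding.numeric_value - match.finding.numeric_value
            if -10 <= delta <= 10:
                assert any(a.candidate is cand for a in rset.aligned_issues)
            else:
                assert any(d.candidate is cand
                           for d in rset.difference_issues)
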