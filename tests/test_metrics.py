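"""Hierarchical metrics: worked examples, oracle agreement, cohort report."""

import numpy as np
import pytest

from oncotoc import (
    CUP_MARKER,
    call_rate,
    evaluate_cohort,
    sample_hppv,
    sample_hsens,
    worked_example_fixtures,
)
from oncotoc.hierarchy import UnknownCodeError
from oncotoc.propagation import CallResult
from conftest import make_small_hierarchy, random_hierarchy, random_path


def mk_call(sid, path, top1=None, top2=None, score=0.9):
    top1 = top1 or (path[0] if path else "X")
    return CallResult(
        sample_id=sid,
        called_path=list(path),
        call_score=score,
        top1_major=top1,
        top2_majors=top2 or (top1, top1),
        threshold_used=0.55,
    )


class TestWorkedExamples:
    """The four canonical path configurations on the toy three-level tree."""

    EXPECTED = [(1.0, 1.0), (1.0, 2 / 3), (2 / 3, 2 / 3), (1.0, 1.0)]

    def test_hppv_hsens_values(self):
        h, cases = worked_example_fixtures()
        got = [
            (sample_hppv(p, t, h), sample_hsens(p, t, h)) for p, t in cases
        ]
        assert got == [pytest.approx(e) for e in self.EXPECTED]

    def test_disjoint_majors_score_zero(self, toy_h):
        assert sample_hsens(["B"], ["A"], toy_h) == 0.0
        assert sample_hppv(["B"], ["A"], toy_h) == 0.0

    def test_empty_paths_rejected(self, toy_h):
        with pytest.raises(ValueError):
            sample_hppv([], ["A"], toy_h)
        with pytest.raises(ValueError):
            sample_hsens(["A"], [], toy_h)


def oracle_metrics(pred, truth, h):
    """Independent set-arithmetic oracle: descendants found by scanning every
    node's root path rather than via subtree traversal."""
    terminal = truth[-1]
    closure = set(truth)
    for code in h.nodes:
        if code == h.root_code or code == terminal:
            continue
        if terminal in h.path_to_root(code)[:-1]:
            closure.add(code)
    pred_set, truth_set = set(pred), set(truth)
    return (
        len(pred_set & closure) / len(pred_set),
        len(truth_set & pred_set) / len(truth_set),
    )


@pytest.mark.parametrize("n_pairs", [1000])
def test_agreement_with_brute_force_oracle(n_pairs):
    """hPPV/hSens match the set-arithmetic oracle on random path pairs over
    random small hierarchies."""
    rng = np.random.default_rng(123)
    for _ in range(n_pairs):
        h = random_hierarchy(rng, max_depth=3, max_nodes=15)
        pred, truth = random_path(h, rng), random_path(h, rng)
        exp_ppv, exp_sens = oracle_metrics(pred, truth, h)
        assert sample_hppv(pred, truth, h) == pytest.approx(exp_ppv)
        assert sample_hsens(pred, truth, h) == pytest.approx(exp_sens)


def test_metrics_bounded_and_perfect_iff_covering():
    rng = np.random.default_rng(7)
    for _ in range(200):
        h = random_hierarchy(rng, max_depth=3, max_nodes=12)
        pred, truth = random_path(h, rng), random_path(h, rng)
        ppv, sens = sample_hppv(pred, truth, h), sample_hsens(pred, truth, h)
        assert 0.0 <= ppv <= 1.0 and 0.0 <= sens <= 1.0
        if ppv == sens == 1.0:
            assert set(truth) <= set(pred) or set(pred) <= set(truth).union(
                h.descendants(truth[-1])
            )


class TestCohortEvaluation:
    def test_perfect_cohort_all_ones(self, small_h):
        truths = {"s0": "MA1", "s1": "MB2", "s2": "MC1"}
        calls = [mk_call(s, small_h.path_to_root(c)) for s, c in truths.items()]
        rep = evaluate_cohort(calls, truths, small_h)
        assert rep.call_rate == 1.0
        assert rep.hppv_mean == rep.hsens_mean == rep.top1_ppv == rep.top2_ppv == 1.0
        assert rep.confusion_major.values.sum() == 3
        assert all(np.diag(rep.confusion_major.loc[list(small_h.majors), list(small_h.majors)]) == 1)

    def test_worked_example_cohort_mean(self):
        """Cases (a)-(c): hPPV mean = (1 + 1 + 2/3)/3 = 8/9."""
        h, cases = worked_example_fixtures()
        calls = [mk_call(f"s{i}", p) for i, (p, _) in enumerate(cases[:3])]
        truths = {f"s{i}": t[-1] for i, (_, t) in enumerate(cases[:3])}
        rep = evaluate_cohort(calls, truths, h)
        assert rep.hppv_mean == pytest.approx(8 / 9)
        assert rep.hsens_mean == pytest.approx((1 + 2 / 3 + 2 / 3) / 3)

    def test_top2_credit(self, small_h):
        calls = [
            mk_call("s0", ["MB"], top1="MB", top2=("MB", "MA")),  # truth MA: top2 only
        ]
        rep = evaluate_cohort(calls, {"s0": "MA"}, small_h)
        assert rep.top1_ppv == 0.0
        assert rep.top2_ppv == 1.0
        assert rep.top2_ppv >= rep.top1_ppv

    def test_no_calls_excluded_from_accuracy_but_counted_in_call_rate(self, small_h):
        calls = [
            mk_call("s0", small_h.path_to_root("MA1")),
            mk_call("s1", []),  # no-call
        ]
        rep = evaluate_cohort(calls, {"s0": "MA1", "s1": "MB"}, small_h)
        assert rep.call_rate == 0.5
        assert rep.hppv_mean == 1.0  # only the called sample contributes

    def test_cup_contributes_to_call_rate_only(self, small_h):
        calls = [
            mk_call("s0", small_h.path_to_root("MA1")),
            mk_call("cup0", small_h.path_to_root("MB1")),
            mk_call("cup1", []),
        ]
        truths = {"s0": "MA1", "cup0": CUP_MARKER, "cup1": CUP_MARKER}
        rep = evaluate_cohort(calls, truths, small_h)
        assert rep.call_rate_cup == 0.5
        assert rep.call_rate_non_cup == 1.0
        assert rep.hppv_mean == 1.0

    def test_flat_hierarchy_hppv_equals_top1(self):
        from oncotoc import LabelHierarchy

        h = LabelHierarchy.from_records(
            [{"code": "r", "parent": None}]
            + [{"code": c, "parent": "r"} for c in "ABCD"]
        )
        rng = np.random.default_rng(5)
        truths, calls = {}, []
        for i in range(40):
            t, p = rng.choice(list("ABCD"), size=2)
            truths[f"s{i}"] = str(t)
            calls.append(mk_call(f"s{i}", [str(p)], top1=str(p)))
        rep = evaluate_cohort(calls, truths, h)
        assert rep.hppv_mean == pytest.approx(rep.top1_ppv)

    def test_unknown_truth_code_rejected(self, small_h):
        with pytest.raises(UnknownCodeError):
            evaluate_cohort([mk_call("s0", ["MA"])], {"s0": "GHOST"}, small_h)

    def test_report_round_trips_to_json(self, small_h, tmp_path):
        calls = [mk_call("s0", small_h.path_to_root("MA1"))]
        rep = evaluate_cohort(calls, {"s0": "MA1"}, small_h)
        rep.save(tmp_path / "m.json")
        import json

        doc = json.loads((tmp_path / "m.json").read_text())
        assert doc["call_rate"] == 1.0
        assert doc["confusion_major"]["counts"]


class TestCallRate:
    def test_retrospective_cup_ratio(self):
        """372 called of 443 -> 0.8397..., the 84.0% operating point."""
        calls = [mk_call(f"s{i}", ["MA"]) for i in range(372)]
        calls += [mk_call(f"n{i}", []) for i in range(443 - 372)]
        assert call_rate(calls) == pytest.approx(372 / 443)
        assert round(100 * call_rate(calls), 1) == 84.0

    def test_limits(self):
        assert call_rate([mk_call("a", ["MA"])]) == 1.0
        assert call_rate([mk_call("a", [])]) == 0.0
        with pytest.raises(ValueError):
            call_rate([])
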