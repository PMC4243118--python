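import itertools
import math
import random

import numpy as np
import pytest

from litppi import (
    ComplexSet,
    clustering_wise_ppv,
    clustering_wise_sn,
    confusion_matrix,
    evaluate_all,
    fraction_matched,
    geometric_accuracy,
    mmr,
    mmr_rowmax,
    overlap_score,
)
from litppi.evaluation import ConfusionMatrix


def brute_force_mmr(pred: ComplexSet, ref: ComplexSet) -> float:
    """Independent oracle: enumerate every one-to-one mapping exhaustively."""
    n, m = len(ref), len(pred)
    if m == 0:
        return 0.0
    W = [[overlap_score(r, p) for p in pred.members] for r in ref.members]
    k = min(n, m)
    best = 0.0
    for rows in itertools.combinations(range(n), k):
        for cols in itertools.permutations(range(m), k):
            best = max(best, sum(W[i][j] for i, j in zip(rows, cols)))
    return best / n


class TestOverlapScore:
    def test_half_shared_equal_sizes_gives_quarter(self):
        a = {f"p{i}" for i in range(10)}
        b = {f"p{i}" for i in range(5, 15)}
        assert overlap_score(a, b) == pytest.approx(0.25)

    def test_identity_and_disjoint(self):
        a = {"x", "y", "z"}
        assert overlap_score(a, set(a)) == 1.0
        assert overlap_score(a, {"u", "v"}) == 0.0

    def test_three_of_four_shared(self):
        a, b = set("ABCD"), set("ABCE")
        assert overlap_score(a, b) == pytest.approx(0.5625)

    def test_symmetric(self):
        a, b = set("ABCDEF"), set("DEFGH")
        assert overlap_score(a, b) == overlap_score(b, a)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(set(), {"A"})


class TestFractionMatched:
    def test_perfect_prediction_matches_everything(self, ref_pair):
        assert fraction_matched(ref_pair, ref_pair) == (2, 2)

    def test_disjoint_prediction_matches_nothing(self, ref_pair):
        pred = ComplexSet.from_sets([{"X", "Y", "Z"}])
        assert fraction_matched(pred, ref_pair) == (1, 0)

    def test_single_match_among_three_predictions(self):
        ref = ComplexSet.from_sets([set("ABCDE")])
        pred = ComplexSet.from_sets([
            {"A", "B", "C"},        # omega = 9/15 = 0.6 -> matched
            {"A", "x", "y", "z"},   # omega = 1/20 -> not matched
            {"u", "v", "w"},        # omega = 0
        ])
        assert fraction_matched(pred, ref) == (3, 1)

    def test_boundary_is_inclusive(self):
        ref = ComplexSet.from_sets([{f"p{i}" for i in range(10)}])
        pred = ComplexSet.from_sets([{f"p{i}" for i in range(5, 15)}])  # omega exactly 0.25
        assert fraction_matched(pred, ref, omega_min=0.25) == (1, 1)


class TestConfusionMatrix:
    def test_single_identical_complex(self):
        cs = ComplexSet.from_sets([{"A", "B", "C"}])
        cm = confusion_matrix(cs, cs)
        assert cm.T.tolist() == [[3]] and cm.N.tolist() == [3]

    def test_disjoint_sets_give_zero_matrix(self, ref_pair):
        pred = ComplexSet.from_sets([{"X", "Y"}])
        cm = confusion_matrix(ref_pair, pred)
        assert cm.T.sum() == 0

    def test_hand_counted_intersections(self, ref_pair, pred_pair):
        cm = confusion_matrix(ref_pair, pred_pair)
        assert cm.T.tolist() == [[2, 0], [1, 3]]
        assert cm.column_sums.tolist() == [3, 3]

    def test_entries_bounded_by_set_sizes(self, ref_pair, pred_pair):
        cm = confusion_matrix(ref_pair, pred_pair)
        for i, r in enumerate(ref_pair.members):
            for j, p in enumerate(pred_pair.members):
                assert cm.T[i, j] <= min(len(r), len(p))


class TestSnPpvAcc:
    def test_sn_hand_value(self, ref_pair, pred_pair):
        cm = confusion_matrix(ref_pair, pred_pair)
        assert clustering_wise_sn(cm) == pytest.approx(5 / 6)

    def test_ppv_hand_value(self, ref_pair, pred_pair):
        cm = confusion_matrix(ref_pair, pred_pair)
        assert clustering_wise_ppv(cm) == pytest.approx(5 / 6)

    def test_perfect_prediction_scores_one(self, ref_pair):
        cm = confusion_matrix(ref_pair, ref_pair)
        assert clustering_wise_sn(cm) == 1.0
        assert clustering_wise_ppv(cm) == 1.0

    def test_single_prediction_split_between_references(self):
        ref = ComplexSet.from_sets([{"A", "B"}, {"C"}])
        pred = ComplexSet.from_sets([{"A", "B", "C"}])
        cm = confusion_matrix(ref, pred)
        assert clustering_wise_ppv(cm) == pytest.approx(2 / 3)

    def test_zero_overlap_ppv_is_zero_with_warning(self, ref_pair, caplog):
        pred = ComplexSet.from_sets([{"X", "Y"}])
        cm = confusion_matrix(ref_pair, pred)
        with caplog.at_level("WARNING"):
            assert clustering_wise_ppv(cm) == 0.0
        assert any("disjoint" in r.message for r in caplog.records)

    def test_no_reference_complexes_rejected(self):
        with pytest.raises(ValueError):
            clustering_wise_sn(ConfusionMatrix(T=np.zeros((0, 0)), N=np.zeros(0)))

    @pytest.mark.parametrize(
        "sn,ppv,expected",
        [(1.0, 1.0, 1.0), (0.8333, 0.8333, 0.8333), (0.0, 0.7, 0.0), (0.5, 0.125, 0.25)],
    )
    def test_geometric_accuracy(self, sn, ppv, expected):
        assert geometric_accuracy(sn, ppv) == pytest.approx(expected, abs=1e-9)


class TestMMR:
    def test_perfect_prediction(self, ref_pair):
        assert mmr(ref_pair, ref_pair) == 1.0

    def test_one_prediction_cannot_match_two_references(self):
        # omega to ref1 = 0.9-ish, to ref2 = 0.8-ish; matching may use only one
        ref = ComplexSet.from_sets([set("ABCDEFGHIj"), set("ABCDEFGHk")])
        pred = ComplexSet.from_sets([set("ABCDEFGHI")])
        w1 = overlap_score(set("ABCDEFGHIj"), set("ABCDEFGHI"))
        w2 = overlap_score(set("ABCDEFGHk"), set("ABCDEFGHI"))
        assert mmr(pred, ref) == pytest.approx(max(w1, w2) / 2)
        assert mmr(pred, ref) == pytest.approx(brute_force_mmr(pred, ref))

    def test_no_overlap_gives_zero(self, ref_pair):
        pred = ComplexSet.from_sets([{"X", "Y", "Z"}])
        assert mmr(pred, ref_pair) == 0.0

    def test_empty_reference_rejected(self, ref_pair):
        with pytest.raises(ValueError):
            mmr(ref_pair, ComplexSet())

    def test_rowmax_upper_bounds_matching(self, ref_pair, pred_pair):
        assert mmr(pred_pair, ref_pair) <= mmr_rowmax(pred_pair, ref_pair) + 1e-12

    def test_matches_brute_force_enumeration_on_random_fixtures(self):
        """Assignment-based MMR equals exhaustive search over all one-to-one mappings."""
        rng = random.Random(20140714)
        universe = [f"P{i}" for i in range(12)]
        for trial in range(200):
            n_ref = rng.randint(1, 6)
            n_pred = rng.randint(0, 6)
            ref = ComplexSet.from_sets(
                [set(rng.sample(universe, rng.randint(1, 6))) for _ in range(n_ref)], prefix="r"
            )
            pred = ComplexSet.from_sets(
                [set(rng.sample(universe, rng.randint(1, 6))) for _ in range(n_pred)], prefix="p"
            )
            fast = mmr(pred, ref)
            slow = brute_force_mmr(pred, ref)
            assert fast == pytest.approx(slow, abs=1e-12), f"trial {trial}"
            assert fast <= mmr_rowmax(pred, ref) + 1e-12 if n_pred else True

    def test_adding_the_missing_reference_as_prediction_never_hurts(self):
        ref = ComplexSet.from_sets([set("ABC"), set("DEF"), set("GHI")])
        pred = ComplexSet.from_sets([set("ABC")])
        base = mmr(pred, ref)
        better = ComplexSet.from_sets([set("ABC"), set("DEF")])
        assert mmr(better, ref) >= base
        cm0, cm1 = confusion_matrix(ref, pred), confusion_matrix(ref, better)
        assert clustering_wise_sn(cm1) >= clustering_wise_sn(cm0)


class TestEvaluateAll:
    def test_perfect_prediction_everything_one(self, ref_pair):
        res = evaluate_all(ref_pair, ref_pair)
        assert (res.sn, res.ppv, res.acc, res.mmr) == (1.0, 1.0, 1.0, 1.0)
        assert (res.n_clusters, res.n_matched) == (2, 2)

    def test_empty_prediction_scores_zero(self, ref_pair):
        res = evaluate_all(ComplexSet(), ref_pair)
        assert (res.sn, res.ppv, res.acc, res.mmr) == (0.0, 0.0, 0.0, 0.0)
        assert (res.n_clusters, res.n_matched) == (0, 0)

    def test_composition_matches_individual_metrics(self, ref_pair, pred_pair):
        res = evaluate_all(pred_pair, ref_pair)
        assert res.sn == pytest.approx(5 / 6)
        assert res.ppv == pytest.approx(5 / 6)
        assert res.acc == pytest.approx(5 / 6)
        assert res.mmr == pytest.approx(brute_force_mmr(pred_pair, ref_pair))
        assert (res.n_clusters, res.n_matched) == (2, 2)

    def test_acc_squared_equals_sn_times_ppv(self):
        rng = random.Random(7)
        universe = [f"P{i}" for i in range(15)]
        for _ in range(50):
            ref = ComplexSet.from_sets(
                [set(rng.sample(universe, rng.randint(1, 8))) for _ in range(rng.randint(1, 5))], prefix="r"
            )
            pred = ComplexSet.from_sets(
                [set(rng.sample(universe, rng.randint(1, 8))) for _ in range(rng.randint(0, 5))], prefix="p"
            )
            res = evaluate_all(pred, ref)
            assert abs(res.acc**2 - res.sn * res.ppv) < 1e-12

    def test_invariant_under_complex_order_and_relabeling(self, ref_pair, pred_pair):
        relabel = {p: f"XX{p}" for p in ref_pair.proteins() | pred_pair.proteins()}
        ref2 = ComplexSet.from_sets([{relabel[p] for p in m} for m in reversed(ref_pair.members)])
        pred2 = ComplexSet.from_sets([{relabel[p] for p in m} for m in reversed(pred_pair.members)])
        a = evaluate_all(pred_pair, ref_pair)
        b = evaluate_all(pred2, ref2)
        assert (a.sn, a.ppv, a.acc, a.mmr) == pytest.approx((b.sn, b.ppv, b.acc, b.mmr))
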