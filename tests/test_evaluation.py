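import itertools
from math import comb

import numpy as np
import pytest

from recynh.evaluation import (
    ConfusionCounts,
    complexity,
    confusion,
    cutoff_scan,
    detect_autoactivators,
    f1_score,
    hypergeom_tail,
    mcc,
    roc_auc,
    wilcoxon_rank_sum,
)
from recynh.matrix import CountMatrix, ISMatrix


def counts(values, baits=None, preys=None, condition="RS"):
    values = np.asarray(values)
    baits = baits or [f"x{i}" for i in range(values.shape[0])]
    preys = preys or [f"y{j}" for j in range(values.shape[1])]
    return CountMatrix(baits=baits, preys=preys, values=values, condition=condition)


def scores(values, baits=None, preys=None):
    values = np.asarray(values, dtype=float)
    baits = baits or [f"x{i}" for i in range(values.shape[0])]
    preys = preys or [f"y{j}" for j in range(values.shape[1])]
    return ISMatrix(baits=baits, preys=preys, values=values)


class TestAutoactivators:
    def _matrices(self, ratios, rs_rows=100):
        n_rs = counts(np.full((len(ratios), 2), rs_rows // 2), condition="RS")
        ris = np.array([[r * rs_rows / 2, r * rs_rows / 2] for r in ratios])
        n_ris = counts(ris.astype(int), condition="RIS")
        return n_ris, n_rs

    def test_hand_example_flags_only_the_outlier(self):
        # ratios [1,1,1,10]: mean 3.25, cut-off 8.125
        n_ris, n_rs = self._matrices([1, 1, 1, 10])
        report = detect_autoactivators(n_ris, n_rs)
        assert report.mean_ratio == pytest.approx(3.25)
        assert report.flagged_baits == ["x3"]

    def test_equal_ratios_flag_nothing(self):
        n_ris, n_rs = self._matrices([2, 2, 2, 2])
        assert detect_autoactivators(n_ris, n_rs).flagged_baits == []

    def test_zero_rs_bait_flagged_with_warning(self):
        n_rs = counts([[10, 10], [0, 0]], condition="RS")
        n_ris = counts([[10, 10], [5, 5]], condition="RIS")
        with pytest.warns(UserWarning, match="no RS reads"):
            report = detect_autoactivators(n_ris, n_rs)
        assert "x1" in report.flagged_baits

    def test_flags_invariant_to_depth_rescaling(self):
        n_ris, n_rs = self._matrices([1, 2, 1, 9])
        base = detect_autoactivators(n_ris, n_rs).flagged_baits
        scaled = detect_autoactivators(
            counts(n_ris.values * 7, condition="RIS"), n_rs
        ).flagged_baits
        assert base == scaled


class TestComplexity:
    def test_enumerated_example(self):
        # 3 ORFs; observed ordered pairs (A,B), (B,A), (A,C)
        ids = ["A", "B", "C"]
        values = np.zeros((3, 3), int)
        values[0, 1] = values[1, 0] = values[0, 2] = 5
        report = complexity(counts(values, baits=ids, preys=ids))
        assert report.sample_complexity == pytest.approx(3 / 9)
        assert report.pair_complexity == pytest.approx(2 / 6)

    def test_full_and_empty_matrices(self):
        ids = ["A", "B"]
        full = complexity(counts(np.ones((2, 2), int), baits=ids, preys=ids))
        assert full.sample_complexity == 1.0
        empty = complexity(counts(np.zeros((2, 2), int), baits=ids, preys=ids))
        assert empty.sample_complexity == 0.0
        assert empty.pair_complexity == 0.0


class TestConfusion:
    def test_perfect_separation(self):
        s = scores([[5.0, 0.1], [0.2, 6.0]], baits=["a", "b"], preys=["c", "d"])
        c = confusion(s, 1.0, [("a", "c"), ("b", "d")])
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 2)

    def test_cutoff_above_all_scores(self):
        s = scores([[5.0, 0.1]], baits=["a"], preys=["c", "d"])
        c = confusion(s, 100.0, [("a", "c")])
        assert (c.tp, c.fp) == (0, 0)
        assert c.fn == 1

    def test_shared_universe_with_homodimers_excluded(self):
        # both orientations of the single reference pair are evaluated; the
        # weak reverse orientation counts as a miss, not a true negative
        s = scores([[0.0, 3.0], [1.0, 0.0]], baits=["P1", "P2"], preys=["P1", "P2"])
        c = confusion(s, 2.0, [("P1", "P2")], exclude_homodimers=True)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 0, 1)
        assert c.total == 2  # diagonal cells excluded

    def test_unknown_reference_ids_warn_and_are_skipped(self):
        s = scores([[3.0]], baits=["a"], preys=["b"])
        with pytest.warns(UserWarning, match="absent"):
            c = confusion(s, 1.0, [("a", "b"), ("ghost", "b")])
        assert c.tp == 1

    def test_counts_partition_the_cell_set(self, rng):
        baits = [f"p{i}" for i in range(5)]
        s = scores(rng.random((5, 5)) * 4, baits=baits, preys=baits)
        positives = [("p0", "p1"), ("p2", "p3")]
        c = confusion(s, 1.5, positives)
        assert c.total == 5 * 5 - 5


class TestF1Mcc:
    def test_hand_formulas(self):
        c = ConfusionCounts(tp=2, fp=1, tn=6, fn=1)
        assert f1_score(c) == pytest.approx(4 / 6)
        expected_mcc = (2 * 6 - 1 * 1) / np.sqrt(3 * 3 * 7 * 7)
        assert mcc(c) == pytest.approx(expected_mcc)

    def test_symmetric_case_has_zero_mcc(self):
        assert mcc(ConfusionCounts(tp=1, fp=1, tn=1, fn=1)) == 0.0

    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=5, fp=0, tn=5, fn=0)
        assert f1_score(c) == 1.0
        assert mcc(c) == 1.0

    def test_degenerate_denominators_warn(self):
        with pytest.warns(UserWarning):
            assert f1_score(ConfusionCounts(0, 0, 4, 0)) == 0.0
        with pytest.warns(UserWarning):
            assert mcc(ConfusionCounts(0, 0, 4, 0)) == 0.0

    def test_agree_with_label_vector_recomputation(self, rng):
        baits = [f"p{i}" for i in range(6)]
        s = scores(rng.random((6, 6)) * 3, baits=baits, preys=baits)
        positives = {("p0", "p1"), ("p2", "p5"), ("p3", "p4")}
        cutoff = 1.2
        c = confusion(s, cutoff, positives)
        # brute force over all evaluated cells
        tp = fp = tn = fn = 0
        for i, a in enumerate(baits):
            for j, b in enumerate(baits):
                if a == b:
                    continue
                truth = frozenset((a, b)) in {frozenset(p) for p in positives}
                called = s.values[i, j] >= cutoff
                tp += called and truth
                fp += called and not truth
                tn += not called and not truth
                fn += not called and truth
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert f1_score(c) == pytest.approx(
            2 * tp / (2 * tp + fp + fn) if tp else 0.0
        )


class TestCutoffScan:
    def test_unique_top_score_optimum_location(self):
        s = scores(
            [[0.0, 5.0], [2.0, 0.0]], baits=["a", "b"], preys=["c", "d"]
        )
        result = cutoff_scan(s, [("a", "d")], grid=[1.0, 3.0, 6.0])
        # the only positive has the unique top score 5: F1 is maximal for
        # cut-offs in (2, 5], here 3.0
        assert result.best_f1_cutoff == 3.0

    def test_all_zero_scores(self):
        s = scores(np.zeros((2, 2)), baits=["a", "b"], preys=["c", "d"])
        result = cutoff_scan(s, [("a", "c")], grid=[0.5, 1.0])
        assert (result.table["f1"] == 0).all()

    def test_single_value_grid(self):
        s = scores([[2.0]], baits=["a"], preys=["b"])
        result = cutoff_scan(s, [("a", "b")], grid=[1.5])
        assert result.best_f1_cutoff == 1.5

    def test_ties_resolve_to_smallest_cutoff(self):
        s = scores([[5.0, 0.0]], baits=["a"], preys=["c", "d"])
        result = cutoff_scan(s, [("a", "c")], grid=[3.0, 1.0, 2.0])
        assert result.best_f1_cutoff == 1.0

    def test_empty_grid_is_an_error(self):
        s = scores([[1.0]], baits=["a"], preys=["b"])
        with pytest.raises(ValueError):
            cutoff_scan(s, [("a", "b")], grid=[])


class TestRocAuc:
    def test_perfect_ranking(self):
        s = scores([[9.0, 0.1], [0.2, 8.0]], baits=["a", "b"], preys=["c", "d"])
        assert roc_auc(s, [("a", "c"), ("b", "d")]) == 1.0

    def test_all_tied_scores_give_half(self):
        s = scores(np.ones((2, 2)), baits=["a", "b"], preys=["c", "d"])
        assert roc_auc(s, [("a", "c")]) == 0.5

    def test_random_labels_near_half(self, rng):
        n = 40
        baits = [f"b{i}" for i in range(n)]
        preys = [f"p{j}" for j in range(n)]
        s = scores(rng.random((n, n)), baits=baits, preys=preys)
        positives = [
            (baits[i], preys[j])
            for i, j in zip(rng.integers(0, n, 200), rng.integers(0, n, 200))
        ]
        assert roc_auc(s, positives) == pytest.approx(0.5, abs=0.05)

    def test_invariant_under_monotone_transform(self, rng):
        baits = [f"b{i}" for i in range(6)]
        vals = rng.random((6, 6)) * 5
        positives = [("b0", "b1"), ("b2", "b3")]
        a1 = roc_auc(scores(vals, baits=baits, preys=baits), positives)
        a2 = roc_auc(scores(np.exp(vals), baits=baits, preys=baits), positives)
        assert a1 == pytest.approx(a2)

    def test_matches_rank_oracle(self, rng):
        """AUC equals the tie-aware pairwise-comparison probability."""
        baits = [f"b{i}" for i in range(5)]
        vals = np.round(rng.random((5, 5)) * 4) / 2  # coarse grid forces ties
        positives = {("b0", "b1"), ("b2", "b4"), ("b1", "b3")}
        s = scores(vals, baits=baits, preys=baits)
        auc = roc_auc(s, positives)
        pos, neg = [], []
        ref = {frozenset(p) for p in positives}
        for i, a in enumerate(baits):
            for j, b in enumerate(baits):
                if a == b:
                    continue
                (pos if frozenset((a, b)) in ref else neg).append(vals[i, j])
        wins = sum(
            1.0 if p > q else 0.5 if p == q else 0.0
            for p, q in itertools.product(pos, neg)
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_degenerate_class_is_an_error(self):
        s = scores([[1.0]], baits=["a"], preys=["b"])
        with pytest.raises(ValueError):
            roc_auc(s, [("a", "b")])


class TestHypergeomTail:
    def test_motif_enrichment_from_printed_counts(self):
        # 5 of 7 direct interactors carry the motif vs 4 of 25 indirect:
        # population 32 with 9 carriers, sample of 7 with >= 5
        p = hypergeom_tail(k=5, n=7, K=9, N=32)
        assert p == pytest.approx(33846 / 3365856)
        assert round(p, 2) == 0.01

    def test_zero_successes_gives_one(self):
        assert hypergeom_tail(k=0, n=5, K=3, N=10) == 1.0

    def test_exhaustive_draw_gives_one(self):
        assert hypergeom_tail(k=4, n=10, K=4, N=10) == 1.0

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            hypergeom_tail(k=5, n=4, K=3, N=10)

    def test_matches_combinatorial_enumeration(self):
        for N in (6, 9, 12):
            for K in (2, N // 2):
                for n in (2, N // 2):
                    for k in range(0, min(n, K) + 1):
                        expected = sum(
                            comb(K, i) * comb(N - K, n - i)
                            for i in range(k, min(n, K) + 1)
                        ) / comb(N, n)
                        assert hypergeom_tail(k, n, K, N) == pytest.approx(expected)


def test_wilcoxon_wrapper_matches_scipy():
    from scipy import stats

    a = [1.0, 2.0, 3.0, 10.0]
    b = [0.5, 0.7, 0.9, 1.1]
    stat, p = wilcoxon_rank_sum(a, b)
    ref = stats.ranksums(a, b)
    assert (stat, p) == (ref.statistic, ref.pvalue)
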