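"""Categorical regression of cell-mode vectors, BH adjustment, core ranking."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from tensorcell import (
    bh_adjust,
    categorical_regression_p,
    rank_l1_by_core,
    select_coincident,
)
from tensorcell.types import ClassLabels


def bh_oracle(p):
    """Step-up definition: sort ascending, cummin of p*(n/rank) from the top."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        adjusted[order[rank - 1]] = running
    return adjusted


class TestCategoricalRegression:
    def test_perfect_separation(self):
        _, _, p = categorical_regression_p(
            [1.0, 1.0, 1.0, 0.0, 0.0, 0.0], ["A", "A", "A", "B", "B", "B"]
        )
        assert p < 1e-12

    def test_constant_vector_p_one(self):
        _, _, p = categorical_regression_p(
            [2.0] * 6, ["A", "A", "A", "B", "B", "B"]
        )
        assert p == 1.0

    def test_matches_anova_oracle(self, rng):
        for _ in range(100):
            M = 60
            v = rng.standard_normal(M)
            y = rng.choice(["a", "b", "c"], size=M)
            while min((y == c).sum() for c in "abc") < 2:
                y = rng.choice(["a", "b", "c"], size=M)
            _, _, p = categorical_regression_p(v, y)
            oracle = scipy.stats.f_oneway(*(v[y == c] for c in "abc")).pvalue
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_coefficients_are_group_mean_offsets(self):
        v = np.array([1.0, 3.0, 10.0, 14.0])
        coefs, intercept, _ = categorical_regression_p(v, ["A", "A", "B", "B"])
        assert intercept == pytest.approx(2.0)
        np.testing.assert_allclose(coefs, [0.0, 10.0])

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            categorical_regression_p([1.0, 2.0, 3.0], ["A", "A", "B"])

    def test_no_residual_degrees_of_freedom_rejected(self):
        with pytest.raises(ValueError):
            categorical_regression_p([1.0, 2.0], ["A", "B"])

    def test_affine_and_relabel_invariance(self, rng):
        v = rng.standard_normal(40)
        y = np.repeat(["a", "b", "c", "d"], 10)
        _, _, p0 = categorical_regression_p(v, y)
        _, _, p1 = categorical_regression_p(3.5 * v - 2.0, y)
        relabel = {"a": "z", "b": "y", "c": "x", "d": "w"}
        _, _, p2 = categorical_regression_p(v, [relabel[c] for c in y])
        assert p1 == pytest.approx(p0, abs=1e-10)
        assert p2 == pytest.approx(p0, abs=1e-10)

    def test_null_pvalues_calibrated(self, rng):
        # under the global null the raw p-values are uniform
        y = np.repeat(["a", "b", "c"], 20)
        hits = sum(
            categorical_regression_p(rng.standard_normal(60), y)[2] < 0.05
            for _ in range(2000)
        )
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(hits / 2000 - 0.05) < 3 * se


class TestBH:
    def test_worked_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])


class TestSelectCoincident:
    def test_null_rarely_selects(self, rng):
        y = ClassLabels(
            [f"c{i}" for i in range(300)], np.repeat(["a", "b", "c"], 100)
        )
        clean = 0
        for seed in range(100):
            v = np.random.default_rng(seed).standard_normal((30, 300))
            res = select_coincident(v, y, alpha=0.01)
            clean += res.selected_.size == 0
        assert clean >= 95

    def test_planted_signal_found(self, rng):
        y = ClassLabels(
            [f"c{i}" for i in range(300)], np.repeat(["a", "b", "c"], 100)
        )
        vectors = rng.standard_normal((30, 300))
        means = {"a": -1.0, "b": 0.0, "c": 1.0}
        vectors[7] = [means[c] for c in y.labels] + 0.05 * rng.standard_normal(300)
        res = select_coincident(vectors, y, alpha=0.01)
        assert 7 in res.selected_

    def test_alpha_zero_selects_nothing(self, rng):
        y = ClassLabels([f"c{i}" for i in range(30)], np.repeat(["a", "b"], 15))
        res = select_coincident(rng.standard_normal((5, 30)), y, alpha=0.0)
        assert res.selected_.size == 0

    def test_result_frame_invariants(self, rng):
        y = ClassLabels([f"c{i}" for i in range(40)], np.repeat(["a", "b"], 20))
        res = select_coincident(rng.standard_normal((8, 40)), y)
        df = res.results_
        assert ((df.pvalue >= 0) & (df.pvalue <= 1)).all()
        assert (df.adjusted_pvalue >= df.pvalue - 1e-15).all()
        assert (df.adjusted_pvalue <= 1).all()
        assert (df.selected == (df.adjusted_pvalue < 0.01)).all()


class TestCoreRanking:
    def test_single_entry_core(self):
        G = np.zeros((5, 6, 3))
        G[2, 4, 0] = 5.0
        order, scores = rank_l1_by_core(G, selected_l2=[4])
        assert order[0] == 2
        assert scores[2] == pytest.approx(25.0)
        assert scores.sum() == pytest.approx(25.0)

    def test_all_selected_follows_mode_energy(self, rng):
        from tensorcell import hosvd

        model = hosvd(rng.standard_normal((6, 10, 3)))
        order, scores = rank_l1_by_core(model.core_, range(model.core_.shape[1]))
        assert (np.diff(scores) <= 1e-8 * scores[0]).all()
        assert list(order) == list(range(6))

    def test_brute_force_oracle(self, rng):
        G = rng.standard_normal((4, 7, 3))
        sel = [1, 3, 6]
        _, scores = rank_l1_by_core(G, sel)
        expected = [
            sum(G[l1, l2, l3] ** 2 for l2 in sel for l3 in range(3))
            for l1 in range(4)
        ]
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="no coincident"):
            rank_l1_by_core(rng.standard_normal((3, 4, 2)), [])

    def test_tie_broken_by_smaller_index(self):
        G = np.zeros((3, 2, 1))
        G[0, 0, 0] = 2.0
        G[2, 0, 0] = 2.0
        order, _ = rank_l1_by_core(G, [0])
        assert list(order) == [0, 2, 1]
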