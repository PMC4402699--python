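"""Discretization, symmetrical uncertainty, CFS, Gain Ratio, ReliefF."""

import numpy as np
import pandas as pd
import pytest

from epidex.selection import (
    cfs_select,
    gain_ratio_rank,
    match_top_n,
    mdl_discretize,
    relieff_rank,
    symmetrical_uncertainty,
)


def entropy(counts):
    p = np.asarray(counts, dtype=float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


class TestMDLDiscretize:
    def test_perfect_separation_single_cut(self):
        values = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        labels = np.array([0] * 10 + [1] * 10)
        cuts = mdl_discretize(values, labels)
        assert len(cuts) == 1
        assert 1 < cuts[0] < 5

    def test_permuted_labels_mostly_no_cuts(self, rng):
        values = rng.normal(size=100)
        hits = 0
        for _ in range(30):
            labels = rng.permutation([0] * 50 + [1] * 50)
            if mdl_discretize(values, labels):
                hits += 1
        assert hits <= 6  # cuts accepted in at most a small minority

    def test_constant_feature_empty(self):
        assert mdl_discretize(np.ones(50), np.arange(50) % 2) == []

    def test_missing_values_ignored(self):
        values = np.array([0.0, 0.1, np.nan, 5.0, 5.1, np.nan] * 5)
        labels = np.array([0, 0, 0, 1, 1, 1] * 5)
        cuts = mdl_discretize(values, labels)
        assert len(cuts) == 1


class TestSymmetricalUncertainty:
    def test_identical_variables(self):
        x = np.array([0, 1, 0, 1, 1, 0])
        assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)

    def test_exact_independence(self):
        # product table: every (x, y) combination equally often
        x = np.repeat([0, 0, 1, 1], 5)
        y = np.tile([0, 1], 10)
        assert symmetrical_uncertainty(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_printed_2x2_table_matches_plugin_entropy(self):
        # table [[30, 10], [10, 30]]
        x = np.array([0] * 40 + [1] * 40)
        y = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 30)
        hx = entropy([40, 40])
        hy = entropy([40, 40])
        hxy = entropy([30, 10, 10, 30])
        expected = 2 * (hx + hy - hxy) / (hx + hy)
        assert symmetrical_uncertainty(x, y) == pytest.approx(expected)

    def test_constant_variable_zero(self):
        assert symmetrical_uncertainty(np.zeros(10, int), np.arange(10) % 2) == 0.0


class TestCFS:
    def make_planted(self, rng, n=200, noise=10):
        y = np.array(["down", "up"])[rng.integers(0, 2, n)]
        signal = np.where(y == "up", 1.0, 0.0) + rng.normal(0, 0.05, n)
        cols = {"signal": signal}
        for j in range(noise):
            cols[f"noise{j}"] = rng.normal(size=n)
        return pd.DataFrame(cols), pd.Series(y, index=pd.RangeIndex(n))

    def test_planted_predictor_selected(self, rng):
        m, y = self.make_planted(rng)
        res = cfs_select(m, y)
        assert "signal" in res.selected

    def test_duplicate_signal_not_both_selected(self, rng):
        m, y = self.make_planted(rng)
        m["signal_copy"] = m["signal"]
        res = cfs_select(m, y)
        assert len({"signal", "signal_copy"} & set(res.selected)) == 1

    def test_redundancy_penalty_two_feature_merit(self):
        # hand computation: duplicated feature has SU(f,f')=1, so the
        # 2-subset merit 2*rcf/sqrt(2+2) = rcf equals the 1-subset merit
        # rcf/sqrt(1) and best-first keeps the singleton
        x = np.array([0.0, 0.0, 1.0, 1.0] * 10)
        m = pd.DataFrame({"a": x, "b": x})
        y = pd.Series(np.array(["down", "down", "up", "up"] * 10))
        res = cfs_select(m, y)
        assert res.n_selected == 1
        assert res.merit == pytest.approx(1.0)

    def test_permuted_labels_small_selection(self, rng):
        m, y = self.make_planted(rng, noise=20)
        sizes = []
        for seed in range(3):
            perm = pd.Series(
                rng.permutation(y.to_numpy()), index=y.index
            )
            sizes.append(cfs_select(m, perm).n_selected)
        assert max(sizes) <= 5

    def test_column_order_invariance(self, rng):
        m, y = self.make_planted(rng, noise=6)
        a = cfs_select(m, y)
        b = cfs_select(m[list(m.columns[::-1])], y)
        assert set(a.selected) == set(b.selected)


class TestGainRatio:
    def test_perfect_binary_feature(self):
        x = np.array([0.0, 1.0] * 20)
        y = pd.Series(np.where(x > 0.5, "up", "down"))
        res = gain_ratio_rank(pd.DataFrame({"f": x}), y)
        assert res.scores["f"] == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        y = pd.Series(["up", "down"] * 10)
        res = gain_ratio_rank(pd.DataFrame({"f": np.ones(20)}), y)
        assert res.scores["f"] == 0.0

    def test_three_category_toy_matches_hand_arithmetic(self):
        # three perfectly class-pure value clusters: MDL keeps both cuts,
        # so GR = H(class) / H(feature) exactly
        x = np.concatenate([np.full(20, 0.0), np.full(20, 5.0), np.full(20, 9.0)])
        y = np.array(["u"] * 20 + ["d"] * 20 + ["u"] * 20)
        res = gain_ratio_rank(pd.DataFrame({"f": x}), pd.Series(y))
        expected = entropy([40, 20]) / entropy([20, 20, 20])
        assert res.scores["f"] == pytest.approx(expected)

    def test_uneven_binary_table_matches_hand_arithmetic(self):
        # 2x2 table with class counts (25, 5) and (10, 20)
        x = np.array([0.0] * 30 + [1.0] * 30)
        y = np.array(["u"] * 25 + ["d"] * 5 + ["u"] * 10 + ["d"] * 20)
        res = gain_ratio_rank(pd.DataFrame({"f": x}), pd.Series(y))
        hy = entropy([35, 25])
        cond = 0.5 * entropy([25, 5]) + 0.5 * entropy([10, 20])
        expected = (hy - cond) / entropy([30, 30])
        assert res.scores["f"] == pytest.approx(expected)

    def test_ranking_descends(self, rng):
        m = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = pd.Series(np.where(m["c"] > 0, "up", "down"))
        res = gain_ratio_rank(m, y)
        assert res.selected[0] == "c"
        ordered = [res.scores[f] for f in res.selected]
        assert all(x >= y_ for x, y_ in zip(ordered, ordered[1:]))


class TestReliefF:
    def test_planted_indicator_ranks_first(self, rng):
        n = 300
        y = np.array(["down", "up"])[rng.integers(0, 2, n)]
        m = pd.DataFrame(rng.normal(size=(n, 12)),
                         columns=[f"n{j}" for j in range(12)])
        m["signal"] = (y == "up").astype(float)
        res = relieff_rank(m, pd.Series(y), seed=0)
        assert res.selected[0] == "signal"

    def test_constant_feature_weight_zero(self, rng):
        y = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, 60)])
        m = pd.DataFrame({"c": np.ones(60), "r": rng.normal(size=60)})
        res = relieff_rank(m, y, seed=0)
        assert res.scores["c"] == pytest.approx(0.0)

    def test_xor_pair_beats_univariate_noise(self, rng):
        # class = f1 XOR f2; each feature alone is class-balanced
        n = 500
        f1 = rng.integers(0, 2, n)
        f2 = rng.integers(0, 2, n)
        y = np.where(f1 ^ f2, "up", "down")
        m = pd.DataFrame({
            "x1": f1 + rng.normal(0, 0.1, n),
            "x2": f2 + rng.normal(0, 0.1, n),
        })
        for j in range(10):
            m[f"noise{j}"] = rng.normal(size=n)
        res = relieff_rank(m, pd.Series(y), seed=0)
        noise_scores = [res.scores[f"noise{j}"] for j in range(10)]
        assert res.scores["x1"] > np.median(noise_scores)
        assert res.scores["x2"] > np.median(noise_scores)
        assert {"x1", "x2"} <= set(res.selected[:4])

    def test_affine_rescaling_invariance(self, rng):
        n = 120
        y = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, n)])
        m = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        res1 = relieff_rank(m, y, seed=3)
        m2 = m.copy()
        m2["b"] = 100.0 * m2["b"] - 7.0
        res2 = relieff_rank(m2, y, seed=3)
        assert np.allclose(res1.scores.to_numpy(), res2.scores.to_numpy())

    def test_weights_bounded(self, rng):
        y = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, 80)])
        m = pd.DataFrame(rng.normal(size=(80, 6)))
        m.columns = [f"f{j}" for j in range(6)]
        res = relieff_rank(m, y, seed=0)
        assert res.scores.between(-1, 1).all()

    def test_small_class_reduces_k_with_warning(self, rng):
        y = pd.Series(["up"] * 5 + ["down"] * 40)
        m = pd.DataFrame(rng.normal(size=(45, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="k reduced"):
            relieff_rank(m, y, k=10, seed=0)


class TestMatchTopN:
    def make_result(self):
        m = pd.DataFrame({
            "a": [0.0, 1.0] * 10, "b": [0.0, 0.5] * 10, "c": [0.1] * 20,
        })
        y = pd.Series(np.array(["down", "up"] * 10))
        return gain_ratio_rank(m, y)

    def test_full_n_is_identity(self):
        r = self.make_result()
        assert match_top_n(r, 3).selected == r.selected

    def test_top_one(self):
        r = self.make_result()
        assert match_top_n(r, 1).selected == [r.selected[0]]

    def test_tie_broken_by_column_order(self, rng):
        scores = pd.Series({"z_first": 0.5, "a_second": 0.5, "m_third": 0.2})
        from epidex.selection import SelectionResult

        r = SelectionResult("GainRatio", [], scores)
        top = match_top_n(r, 1)
        assert top.selected == ["z_first"]  # column order, not alphabetical

    def test_invalid_n(self):
        r = self.make_result()
        with pytest.raises(ValueError):
            match_top_n(r, 0)
        with pytest.raises(ValueError):
            match_top_n(r, 99)
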