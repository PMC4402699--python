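"""Splits, cross-validation, metrics, classifiers, and feature analyses."""

import numpy as np
import pandas as pd
import pytest

from epidex.evaluation import (
    CLASSIFIERS,
    classifier_train,
    compute_metrics,
    cross_validate,
    feature_correlation_clusters,
    rank_by_class_correlation,
    stratified_split,
)


def labeled_matrix(rng, n=200, p=4, signal=True):
    y = np.array(["down", "up"])[rng.integers(0, 2, n)]
    m = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{j}" for j in range(p)],
                     index=[f"g{i}" for i in range(n)])
    if signal:
        m["f0"] += np.where(y == "up", 2.0, 0.0)
    return m, pd.Series(y, index=m.index)


class TestStratifiedSplit:
    def test_exact_division(self):
        labels = pd.Series(["up"] * 100 + ["down"] * 100,
                           index=[f"g{i}" for i in range(200)])
        tr, te = stratified_split(labels, 0.8, seed=0)
        assert len(tr) == 160 and len(te) == 40
        assert (labels[te] == "up").sum() == 20

    def test_partition_and_determinism(self, rng):
        m, labels = labeled_matrix(rng, n=97)
        tr1, te1 = stratified_split(labels, 0.8, seed=5)
        tr2, te2 = stratified_split(labels, 0.8, seed=5)
        assert list(tr1) == list(tr2) and list(te1) == list(te2)
        assert set(tr1) | set(te1) == set(labels.index)
        assert not (set(tr1) & set(te1))
        tr3, _ = stratified_split(labels, 0.8, seed=6)
        assert list(tr3) != list(tr1)

    def test_per_class_floor_for_test(self):
        labels = pd.Series(["up"] * 13 + ["down"] * 9)
        tr, te = stratified_split(labels, 0.8, seed=0)
        assert (labels[te] == "up").sum() == 2   # floor(13 * .2)
        assert (labels[te] == "down").sum() == 1  # floor(9 * .2)

    def test_degenerate_class_rejected(self):
        labels = pd.Series(["up"] * 3 + ["down"] * 50)
        with pytest.raises(ValueError):
            stratified_split(labels, 0.8, seed=0)


class TestMetrics:
    def test_perfect_confusion(self):
        scores = pd.Series([0.9] * 5 + [0.1] * 5)
        labels = pd.Series(["up"] * 5 + ["down"] * 5)
        m = compute_metrics(scores, labels)
        assert m == {"auc": 1.0, "accuracy": 1.0, "f_measure": 1.0, "mcc": 1.0}

    def test_hand_confusion_matrix(self):
        # TP=4, FN=1, FP=2, TN=3
        labels = pd.Series(["up"] * 5 + ["down"] * 5)
        scores = pd.Series([0.9, 0.9, 0.9, 0.9, 0.1, 0.9, 0.9, 0.1, 0.1, 0.1])
        m = compute_metrics(scores, labels)
        prec, rec = 4 / 6, 4 / 5
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f_measure"] == pytest.approx(2 * prec * rec / (prec + rec))
        mcc = (4 * 3 - 2 * 1) / np.sqrt(6 * 4 * 5 * 5)
        assert m["mcc"] == pytest.approx(mcc)

    def test_constant_scores_auc_half_mcc_zero(self):
        labels = pd.Series(["up", "down"] * 10)
        m = compute_metrics(pd.Series([0.7] * 20), labels)
        assert m["auc"] == pytest.approx(0.5)
        # all predictions positive -> a zero marginal -> MCC defined as 0
        assert m["mcc"] == 0.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, 50)])
        s = pd.Series(rng.normal(size=50))
        a1 = compute_metrics(1 / (1 + np.exp(-s)), labels)["auc"]
        a2 = compute_metrics(1 / (1 + np.exp(-(3 * s + 2))), labels)["auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(pd.Series([0.1, 0.9]), pd.Series(["up", "up"]))

    def test_mcc_symmetric_under_joint_swap(self, rng):
        labels = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, 40)])
        scores = pd.Series(rng.uniform(size=40))
        m1 = compute_metrics(scores, labels)
        swapped = labels.map({"up": "down", "down": "up"})
        m2 = compute_metrics(1 - scores, pd.Series(swapped))
        assert m1["mcc"] == pytest.approx(m2["mcc"])
        assert m1["accuracy"] == pytest.approx(m2["accuracy"])


class TestClassifiers:
    @pytest.mark.parametrize("clf", CLASSIFIERS)
    def test_separable_data_perfect_training_accuracy(self, clf, rng):
        m, y = labeled_matrix(rng, n=80, p=2, signal=False)
        m["f0"] = np.where(y == "up", 5.0, -5.0) + rng.normal(0, 0.1, 80)
        scorer = classifier_train(clf, m, y, seed=0)
        metrics = compute_metrics(scorer(m), y)
        assert metrics["accuracy"] == 1.0

    @pytest.mark.parametrize("clf", ["random_forest", "gaussian_svm"])
    def test_training_reproducible_under_seed(self, clf, rng):
        m, y = labeled_matrix(rng)
        s1 = classifier_train(clf, m, y, seed=7)(m)
        s2 = classifier_train(clf, m, y, seed=7)(m)
        assert np.allclose(s1, s2)

    def test_unknown_classifier(self, rng):
        m, y = labeled_matrix(rng)
        with pytest.raises(ValueError):
            classifier_train("perceptron", m, y)

    def test_nonfinite_matrix_rejected(self, rng):
        m, y = labeled_matrix(rng)
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            classifier_train("logistic", m, y)

    def test_forest_beats_linear_on_xor_interaction(self, rng):
        # planted interaction: class = sign agreement of two features
        n = 400
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = pd.Series(np.where((a > 0) == (b > 0), "up", "down"),
                      index=[f"g{i}" for i in range(n)])
        m = pd.DataFrame({"a": a, "b": b}, index=y.index)
        rep_rf = cross_validate(m, y, "random_forest", folds=5, seed=0)
        rep_lin = cross_validate(m, y, "logistic", folds=5, seed=0)
        assert rep_rf.auc > rep_lin.auc + 0.2


class TestCrossValidation:
    def test_perfect_scorer_auc_one(self, rng):
        m, y = labeled_matrix(rng, n=100)
        m["f0"] = np.where(y == "up", 1.0, 0.0)
        rep = cross_validate(m[["f0"]], y, "logistic", folds=5, seed=0)
        assert rep.auc == 1.0

    def test_label_permutation_null_auc(self, rng):
        n = 2000
        m = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{j}" for j in range(10)],
                         index=[f"g{i}" for i in range(n)])
        y = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, n)], index=m.index)
        rep = cross_validate(m, y, "logistic", folds=10, seed=0)
        assert 0.45 <= rep.auc <= 0.55

    def test_pooled_metrics_of_deterministic_scorer_match_single_pass(self, rng):
        # a classifier that learns an exact deterministic rule gives the
        # same pooled out-of-fold metrics as scoring the full set at once
        m, y = labeled_matrix(rng, n=120)
        m["f0"] = np.where(y == "up", 1.0, 0.0)
        rep = cross_validate(m[["f0"]], y, "naive_bayes", folds=6, seed=1)
        direct = compute_metrics((m["f0"] > 0.5).astype(float), y)
        assert rep.auc == pytest.approx(direct["auc"])
        assert rep.accuracy == pytest.approx(direct["accuracy"])

    def test_class_smaller_than_folds_rejected(self, rng):
        m, y = labeled_matrix(rng, n=30)
        y.iloc[:] = "down"
        y.iloc[:5] = "up"
        with pytest.raises(ValueError):
            cross_validate(m, y, "logistic", folds=10, seed=0)


class TestFeatureAnalyses:
    def test_duplicated_feature_merges_first(self, rng):
        m = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        m["a_copy"] = m["a"]
        z, corr, names = feature_correlation_clusters(m)
        assert corr.loc["a", "a_copy"] == pytest.approx(1.0)
        # the first linkage row joins the duplicated pair at distance ~0
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        _, corr, _ = feature_correlation_clusters(m)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_blocks_separate(self, rng):
        n = 1000
        base1, base2 = rng.normal(size=n), rng.normal(size=n)
        m = pd.DataFrame({
            "a1": base1 + rng.normal(0, 0.3, n),
            "a2": base1 + rng.normal(0, 0.3, n),
            "b1": base2 + rng.normal(0, 0.3, n),
            "b2": base2 + rng.normal(0, 0.3, n),
        })
        _, corr, _ = feature_correlation_clusters(m)
        within = (corr.loc["a1", "a2"] + corr.loc["b1", "b2"]) / 2
        between = corr.loc[["a1", "a2"], ["b1", "b2"]].to_numpy().mean()
        assert between < within

    def test_zero_variance_feature_excluded(self, rng):
        m = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30),
                          "const": np.ones(30)})
        _, corr, names = feature_correlation_clusters(m)
        assert "const" not in names

    def test_rank_by_class_correlation(self, rng):
        n = 2000
        y = pd.Series(np.array(["down", "up"])[rng.integers(0, 2, n)],
                      index=[f"g{i}" for i in range(n)])
        enc = np.where(y == "up", 1.0, -1.0)
        m = pd.DataFrame({"exact": enc,
                          "noise": rng.normal(size=n)}, index=y.index)
        top = rank_by_class_correlation(m, y, top_k=2)
        assert top.index[0] == "exact"
        assert top.iloc[0] == pytest.approx(1.0)
        assert abs(top["noise"]) < 0.1
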