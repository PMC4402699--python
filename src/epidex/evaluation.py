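"""Classifier training, cross-validation, metrics and selected-feature analyses.

Five classifier families (Gaussian SVM, linear SVM, logistic regression,
naive Bayes, random forest) are evaluated under a stratified 80/20 split
and stratified 10-fold cross-validation, reporting AUC, accuracy,
F-measure (positive class = up-regulated) and Matthews correlation.
All classifiers emit scores on a probability scale so a common 0.5
threshold applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .catalog import impute_median

POSITIVE_CLASS = "up"
CLASSIFIERS = ("gaussian_svm", "linear_svm", "logistic", "naive_bayes", "random_forest")

#: default hyperparameters, mirroring common toolkit defaults
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "gaussian_svm": {"C": 1.0, "gamma": "scale"},
    "linear_svm": {"C": 1.0},
    "logistic": {"C": 1.0, "max_iter": 2000},
    "naive_bayes": {},
    "random_forest": {"n_estimators": 100},
}


@dataclass
class EvaluationReport:
    """Metrics of one (selector, classifier) model on one evaluation split."""

    model_id: str
    auc: float                     # pooled out-of-fold (or single-pass) AUC
    accuracy: float
    f_measure: float
    mcc: float
    fold_metrics: pd.DataFrame | None = None   # per-fold AUC/acc/F/MCC
    scores: pd.Series | None = None            # per-gene out-of-fold scores
    extras: dict = field(default_factory=dict)

    @property
    def fold_mean_auc(self) -> float | None:
        if self.fold_metrics is None:
            return None
        return float(self.fold_metrics["auc"].mean())

    def to_json_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
        }
        if self.fold_metrics is not None:
            d["fold_mean_auc"] = self.fold_mean_auc
        d.update(self.extras)
        return d


def _binary(labels: pd.Series) -> np.ndarray:
    return (labels.to_numpy() == POSITIVE_CLASS).astype(int)


def stratified_split(
    labels: pd.Series, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Per-class proportional train/test split of gene ids.

    The per-class test count is ``floor(n_class * (1 - train_fraction))``;
    remaining genes train.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) < 5:
            raise ValueError(f"class {cls!r} has fewer than 5 members")
        perm = rng.permutation(len(ids))
        n_test = int(np.floor(round(len(ids) * (1.0 - train_fraction), 9)))
        test_ids.extend(ids[perm[:n_test]])
        train_ids.extend(ids[perm[n_test:]])
    return pd.Index(sorted(train_ids)), pd.Index(sorted(test_ids))


def classifier_train(
    classifier_id: str,
    train: pd.DataFrame,
    labels: pd.Series,
    hyperparameters: dict | None = None,
    seed: int = 0,
):
    """Fit one classifier; returns ``score(frame) -> P(up)`` per row.

    The matrix must already be imputed/finite.  Features are standardized
    inside the returned scorer for the scale-sensitive learners; SVM
    scores are Platt-calibrated probabilities so every classifier scores
    on the same [0, 1] scale.
    """
    if classifier_id not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier_id!r}")
    x = train.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("training matrix contains non-finite values")
    y = _binary(labels.reindex(train.index))
    hp = dict(DEFAULT_HYPERPARAMETERS[classifier_id])
    hp.update(hyperparameters or {})

    scaler = None
    if classifier_id in ("gaussian_svm", "linear_svm", "logistic"):
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)

    if classifier_id == "gaussian_svm":
        model = SVC(kernel="rbf", probability=True, random_state=seed, **hp)
    elif classifier_id == "linear_svm":
        model = SVC(kernel="linear", probability=True, random_state=seed, **hp)
    elif classifier_id == "logistic":
        model = LogisticRegression(**hp)
    elif classifier_id == "naive_bayes":
        model = GaussianNB(**hp)
    else:
        model = RandomForestClassifier(random_state=seed, **hp)
    model.fit(x, y)
    pos_col = int(np.nonzero(model.classes_ == 1)[0][0])

    def score(frame: pd.DataFrame) -> pd.Series:
        z = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("scoring matrix contains non-finite values")
        if scaler is not None:
            z = scaler.transform(z)
        return pd.Series(model.predict_proba(z)[:, pos_col], index=frame.index)

    return score


def compute_metrics(
    scores: pd.Series, labels: pd.Series, threshold: float = 0.5
) -> dict[str, float]:
    """AUC (rank statistic, ties 1/2), accuracy, F (positive class), MCC."""
    y = _binary(labels.reindex(scores.index))
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    s = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    pred = (s >= threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y, s)),
        "accuracy": float(accuracy_score(y, pred)),
        "f_measure": float(f1_score(y, pred, zero_division=0.0)),
        "mcc": float(matthews_corrcoef(y, pred)),
    }


def cross_validate(
    m: pd.DataFrame,
    labels: pd.Series,
    classifier_id: str,
    folds: int = 10,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold CV with per-fold imputation; pooled + per-fold metrics."""
    labels = labels.reindex(m.index)
    y = _binary(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = pd.Series(np.nan, index=m.index, dtype=float)
    fold_rows = []
    for fold, (tr, te) in enumerate(skf.split(m, y)):
        tr_x, te_x = impute_median(m.iloc[tr], m.iloc[te])
        scorer = classifier_train(
            classifier_id, tr_x, labels.iloc[tr], hyperparameters, seed=seed
        )
        sc = scorer(te_x)
        oof.iloc[te] = sc.to_numpy()
        fm = compute_metrics(sc, labels.iloc[te])
        fm["fold"] = fold
        fold_rows.append(fm)
    pooled = compute_metrics(oof, labels)
    return EvaluationReport(
        model_id=classifier_id,
        auc=pooled["auc"],
        accuracy=pooled["accuracy"],
        f_measure=pooled["f_measure"],
        mcc=pooled["mcc"],
        fold_metrics=pd.DataFrame(fold_rows).set_index("fold"),
        scores=oof,
    )


def feature_correlation_clusters(
    m: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Average-linkage clustering of features on distance 1 - |Pearson r|.

    Pearson correlations use pairwise-complete observations; zero-variance
    features are excluded.  Returns (scipy linkage matrix, |r| matrix
    ordered by the dendrogram leaves, ordered feature names).
    """
    keep = [c for c in m.columns if m[c].std(skipna=True) > 0]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant features")
    corr = m[keep].corr(method="pearson").abs()
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    dist = squareform((1.0 - corr).to_numpy(), checks=False)
    z = linkage(dist, method="average")
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(z)
    names = [keep[i] for i in order]
    return z, corr.iloc[order, order], names


def rank_by_class_correlation(
    m: pd.DataFrame, labels: pd.Series, top_k: int = 15
) -> pd.Series:
    """Top features by |point-biserial correlation| with the +/-1 class code."""
    enc = np.where(_binary(labels.reindex(m.index)) == 1, 1.0, -1.0)
    rs = {}
    for c in m.columns:
        v = m[c].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(enc[ok]) == 0:
            continue
        rs[c] = float(np.corrcoef(v[ok], enc[ok])[0, 1])
    s = pd.Series(rs)
    order = sorted(s.index, key=lambda c: (-abs(s[c]), list(m.columns).index(c)))
    return s.loc[order[:top_k]]
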