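"""Feature selection: CFS, Gain Ratio, and ReliefF.

CFS (correlation-based feature selection) searches for a feature subset
maximizing ``merit = k * mean SU(f, class) / sqrt(k + k(k-1) * mean
SU(f, f'))`` where SU is the symmetrical uncertainty; it is the only
method with a built-in subset size.  Gain Ratio and ReliefF are rankers;
their selections are size-matched to the CFS subset.  The
information-theoretic methods run on Fayyad–Irani MDL-discretized
features; ReliefF runs on range-normalized continuous values with k
nearest hits/misses under Manhattan distance.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionResult:
    method: str                     # CFS | GainRatio | ReliefF
    selected: list[str]             # ordered feature names
    scores: pd.Series               # per-feature score (rankers: all features)
    n_selected: int = field(init=False)
    merit: float | None = None      # CFS subset merit

    def __post_init__(self):
        self.n_selected = len(self.selected)

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": list(self.selected),
            "scores": {k: float(v) for k, v in self.scores.items()},
            "n_selected": self.n_selected,
            "merit": self.merit,
        }


# ---------------------------------------------------------------------------
# entropy helpers (natural log; ratios are base-invariant)
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _joint_counts(x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> np.ndarray:
    return np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny)


def symmetrical_uncertainty(x, y) -> float:
    """SU(x, y) = 2 I(x; y) / (H(x) + H(y)); 0 when either entropy is 0.

    ``x`` and ``y`` are integer category codes (missing entries coded as a
    category of their own upstream, or pre-filtered).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    nx, ny = int(x.max()) + 1, int(y.max()) + 1
    joint = _joint_counts(x, y, nx, ny)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _entropy_from_counts(joint.ravel())
    mi = hx + hy - hxy
    return max(0.0, 2.0 * mi / (hx + hy))


# ---------------------------------------------------------------------------
# Fayyad–Irani MDL discretization
# ---------------------------------------------------------------------------

def _class_entropy(counts: np.ndarray) -> float:
    return _entropy_from_counts(counts)


def mdl_discretize(values, labels) -> list[float]:
    """Entropy-based recursive binary splitting with the MDL stop rule.

    Returns the sorted list of cut points (possibly empty: the feature is
    uninformative).  Missing values are ignored during boundary search.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    ok = np.isfinite(v)
    v, y = v[ok], y[ok]
    if v.size < 2 or np.unique(v).size < 2:
        return []
    classes, y = np.unique(y, return_inverse=True)
    k = len(classes)
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    cuts: list[float] = []
    _mdl_split(v, y, k, 0, v.size, cuts)
    return sorted(cuts)


def _mdl_split(v, y, n_classes, lo, hi, cuts) -> None:
    n = hi - lo
    if n < 4:  # cannot produce two non-trivial halves worth testing
        return
    seg_v, seg_y = v[lo:hi], y[lo:hi]
    # cumulative class counts: cum[i, c] = count of class c in first i items
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), seg_y] = 1
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    ent_s = _class_entropy(total)
    # candidate cuts: between adjacent distinct values
    distinct = np.nonzero(seg_v[1:] > seg_v[:-1])[0]  # cut after index i
    if distinct.size == 0:
        return
    left = cum[distinct]
    right = total - left
    n_left = left.sum(axis=1).astype(float)
    n_right = right.sum(axis=1).astype(float)

    def ent_rows(counts, totals):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / totals[:, None]
            t = np.where(counts > 0, -p * np.log(p), 0.0)
        return t.sum(axis=1)

    e_left = ent_rows(left, n_left)
    e_right = ent_rows(right, n_right)
    went = (n_left * e_left + n_right * e_right) / n
    best = int(np.argmin(went))
    gain = ent_s - went[best]

    k = np.count_nonzero(total)
    k1 = np.count_nonzero(left[best])
    k2 = np.count_nonzero(right[best])
    e1 = _class_entropy(left[best])
    e2 = _class_entropy(right[best])
    delta = np.log(3**k - 2) - (k * ent_s - k1 * e1 - k2 * e2)
    threshold = (np.log(n - 1) + delta) / n
    if gain <= threshold:
        return
    cut_idx = distinct[best]
    cuts.append(float((seg_v[cut_idx] + seg_v[cut_idx + 1]) / 2.0))
    _mdl_split(v, y, n_classes, lo, lo + cut_idx + 1, cuts)
    _mdl_split(v, y, n_classes, lo + cut_idx + 1, hi, cuts)


def discretize_matrix(
    m: pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MDL-discretize every column; missing values get their own category.

    Returns (codes matrix int64 n x p, number of categories per column).
    Code 0 is reserved for missing; real bins start at 1.
    """
    n, p = m.shape
    codes = np.zeros((n, p), dtype=np.int64)
    ncat = np.ones(p, dtype=np.int64)
    x = m.to_numpy(dtype=float)
    for j in range(p):
        col = x[:, j]
        cuts = mdl_discretize(col, labels)
        ok = np.isfinite(col)
        binned = np.searchsorted(np.asarray(cuts), col[ok], side="right") + 1
        codes[ok, j] = binned
        ncat[j] = len(cuts) + 2  # missing + bins
    return codes, ncat


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def _merit(sum_rcf: float, sum_rff: float, k: int) -> float:
    if k == 0:
        return 0.0
    denom = np.sqrt(k + 2.0 * sum_rff)
    return float(k * (sum_rcf / k) / denom) if denom > 0 else 0.0


def cfs_select(
    m: pd.DataFrame,
    labels,
    *,
    max_stale: int = 5,
) -> SelectionResult:
    """Correlation-based feature selection via best-first forward search.

    Search starts from the empty set; each expansion adds one feature;
    the search stops after ``max_stale`` consecutive expansions that do
    not improve the best merit found so far.
    """
    y = _encode_labels(labels, m.index)
    names = list(m.columns)
    codes, _ = discretize_matrix(m, y)
    p = len(names)
    su_class = np.array([symmetrical_uncertainty(codes[:, j], y) for j in range(p)])

    su_cache: dict[int, np.ndarray] = {}

    def su_row(j: int) -> np.ndarray:
        if j not in su_cache:
            su_cache[j] = np.array(
                [symmetrical_uncertainty(codes[:, j], codes[:, i]) for i in range(p)]
            )
        return su_cache[j]

    # best-first over subsets; priority = -merit, tie-break = insertion order
    start = frozenset()
    heap: list[tuple[float, int, frozenset]] = [(0.0, 0, start)]
    visited = {start}
    best_subset, best_merit = start, 0.0
    stale, counter = 0, 1

    while heap and stale < max_stale:
        _, _, subset = heapq.heappop(heap)
        idx = list(subset)
        k = len(idx)
        sum_rcf = float(su_class[idx].sum()) if k else 0.0
        sum_rff = 0.0
        if k > 1:
            sum_rff = sum(
                su_row(a)[b] for i, a in enumerate(idx) for b in idx[i + 1 :]
            )
        # vectorized merit of every one-feature extension (SU is symmetric,
        # so only rows for current members are materialized)
        rff_to_subset = np.zeros(p)
        for a in idx:
            rff_to_subset += su_row(a)
        child_rcf = sum_rcf + su_class
        child_rff = sum_rff + rff_to_subset
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt((k + 1) + 2.0 * child_rff)
            merits = np.where(denom > 0, child_rcf / denom, 0.0)
        improved = False
        for j in np.argsort(-merits, kind="stable"):
            j = int(j)
            if j in subset:
                continue
            child = subset | {j}
            if child in visited:
                continue
            visited.add(child)
            heapq.heappush(heap, (-float(merits[j]), counter, child))
            counter += 1
            if merits[j] > best_merit + 1e-12:
                best_merit, best_subset = float(merits[j]), child
                improved = True
        stale = 0 if improved else stale + 1

    # order selected features by class relevance, tie-break catalog order
    sel_idx = sorted(best_subset, key=lambda j: (-su_class[j], j))
    return SelectionResult(
        "CFS",
        [names[j] for j in sel_idx],
        pd.Series(su_class, index=names),
        merit=best_merit,
    )


# ---------------------------------------------------------------------------
# Gain Ratio
# ---------------------------------------------------------------------------

def gain_ratio_rank(m: pd.DataFrame, labels) -> SelectionResult:
    """Gain Ratio = information gain / split information, per feature.

    Computed on MDL-discretized values; constant features (zero split
    information) score 0.  Returns the full descending ranking.
    """
    y = _encode_labels(labels, m.index)
    codes, ncat = discretize_matrix(m, y)
    names = list(m.columns)
    hy = _entropy_from_counts(np.bincount(y))
    scores = np.zeros(len(names))
    for j in range(len(names)):
        x = codes[:, j]
        joint = _joint_counts(x, y, int(ncat[j]), int(y.max()) + 1)
        hx = _entropy_from_counts(joint.sum(axis=1))
        if hx == 0.0:
            continue
        hxy = _entropy_from_counts(joint.ravel())
        ig = hy + hx - hxy
        scores[j] = max(0.0, ig / hx)
    s = pd.Series(scores, index=names)
    order = _rank_order(s)
    return SelectionResult("GainRatio", [names[j] for j in order], s)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_rank(
    m: pd.DataFrame,
    labels,
    *,
    k: int = 10,
    m_samples: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """ReliefF feature weights with k nearest hits and misses.

    Features are range-normalized to [0, 1]; distances are Manhattan.
    For each sampled instance the weight of feature f is decreased by the
    mean |diff| to its k nearest same-class neighbours (hits) and
    increased by the class-prior-weighted mean |diff| to the k nearest
    neighbours of each other class (misses).  Missing entries contribute
    through a neutral feature-mean fill.  Weights lie
    in [-1, 1]; by default all instances are used (m = n).
    """
    y = _encode_labels(labels, m.index)
    x = m.to_numpy(dtype=float).copy()
    n, p = x.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs at least two classes")
    k_eff = {}
    for c, cnt in zip(classes, counts):
        k_eff[c] = min(k, cnt - 1)
        if cnt - 1 < k:
            import warnings

            warnings.warn(
                f"class {c} has only {cnt} members; k reduced to {cnt - 1}"
            )

    # neutral mean fill for missing values: a missing entry contributes the
    # feature's average diff, and identical fills cannot fabricate
    # between-class contrast for mostly-missing noise features
    col_mean = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nanmask = ~np.isfinite(x)
    x[nanmask] = np.broadcast_to(col_mean, x.shape)[nanmask]

    # range normalization
    rng_ = x.max(axis=0) - x.min(axis=0)
    rng_[rng_ == 0] = 1.0
    x = (x - x.min(axis=0)) / rng_

    rng = np.random.default_rng(seed)
    if m_samples is None or m_samples >= n:
        sample = np.arange(n)
    else:
        sample = rng.choice(n, size=m_samples, replace=False)

    priors = counts / n
    prior_of = dict(zip(classes, priors))
    w = np.zeros(p)
    class_rows = {c: np.nonzero(y == c)[0] for c in classes}
    for i in sample:
        d = np.abs(x - x[i]).sum(axis=1)
        ci = y[i]
        hits_pool = class_rows[ci]
        hp = hits_pool[hits_pool != i]
        kh = k_eff[ci]
        if kh > 0 and hp.size:
            nearest = hp[np.argpartition(d[hp], min(kh, hp.size) - 1)[:kh]]
            w -= np.abs(x[nearest] - x[i]).mean(axis=0) / len(sample)
        denom = 1.0 - prior_of[ci]
        for c in classes:
            if c == ci:
                continue
            pool = class_rows[c]
            km = min(k, pool.size)
            nearest = pool[np.argpartition(d[pool], km - 1)[:km]]
            w += (
                (prior_of[c] / denom)
                * np.abs(x[nearest] - x[i]).mean(axis=0)
                / len(sample)
            )
    s = pd.Series(w, index=m.columns)
    order = _rank_order(s)
    return SelectionResult("ReliefF", [m.columns[j] for j in order], s)


def match_top_n(r: SelectionResult, n: int) -> SelectionResult:
    """Top-n features of a ranker, ties broken by catalog (column) order."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(r.scores):
        raise ValueError("n exceeds number of ranked features")
    order = _rank_order(r.scores)
    names = list(r.scores.index)
    return SelectionResult(r.method, [names[j] for j in order[:n]], r.scores)


def _rank_order(scores: pd.Series) -> list[int]:
    """Indices sorted by descending score, ties broken by position."""
    arr = scores.to_numpy()
    return sorted(range(len(arr)), key=lambda j: (-arr[j], j))


def _encode_labels(labels, index) -> np.ndarray:
    """Encode an up/down label vector (Series or array) as int codes.

    ``up`` is coded 1 and ``down`` 0 when present; other label sets get
    sorted-order codes.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(index)
        if labels.isna().any():
            raise ValueError("labels missing for some genes in the matrix")
        vals = labels.to_numpy()
    else:
        vals = np.asarray(labels)
    uniq = sorted(set(vals.tolist()))
    if set(uniq) <= {"up", "down"}:
        mapping = {"down": 0, "up": 1}
    else:
        mapping = {v: i for i, v in enumerate(uniq)}
    return np.array([mapping[v] for v in vals], dtype=np.int64)
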