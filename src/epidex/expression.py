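"""Gene-level differential-expression labels.

Transcript-level differential-expression results (per-condition mean
counts, log2 fold change, p-value from any upstream DE tool) are
aggregated per gene by a shifted geometric mean, the gene log2FC is
recomputed from the aggregated condition means, p-values are combined
(minimum raw p per gene) and adjusted by Holm's step-down procedure, and
a gene is labeled ``up`` / ``down`` when adj_p < 0.05 and |log2FC| > 1
(strict); everything else is ``excluded``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ADJ_P_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 1.0


@dataclass
class DEResult:
    gene_id: str
    log2FC: float
    p_value: float
    adj_p: float
    label: str  # up | down | excluded


def geometric_mean_aggregate(values) -> float:
    """Geometric mean with a +1/-1 shift when any value is zero.

    If any value is 0, every value is increased by one before the
    geometric mean and one is subtracted from the result; otherwise the
    plain geometric mean is returned.  A singleton returns itself under
    both branches.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    if np.any(v == 0):
        return float(np.exp(np.mean(np.log(v + 1.0))) - 1.0)
    return float(np.exp(np.mean(np.log(v))))


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def label_genes(
    de: pd.DataFrame,
    *,
    aggregate: str = "condition_means",
    alpha: float = ADJ_P_THRESHOLD,
    lfc_threshold: float = LOG2FC_THRESHOLD,
) -> list[DEResult]:
    """Aggregate a transcript-level DE table to labeled genes.

    Parameters
    ----------
    de : DataFrame
        Columns ``transcript_id, gene_id, mean_count_A, mean_count_B,
        log2FC, p_value`` (A = cancer, B = normal).
    aggregate : str
        ``"condition_means"`` (default): geometric-mean-aggregate the
        per-condition mean counts per gene and recompute log2FC from the
        aggregated means.  ``"fold_changes"``: geometric-mean-aggregate
        the per-transcript fold changes ``2**log2FC`` directly.

    The gene p-value is the minimum raw transcript p, Holm-adjusted
    across genes.  Genes whose aggregated means are zero in both
    conditions are excluded with a warning.
    """
    if aggregate not in ("condition_means", "fold_changes"):
        raise ValueError(f"unknown aggregation rule {aggregate!r}")
    results: dict[str, dict] = {}
    for gene_id, g in de.groupby("gene_id", sort=True):
        rec: dict = {"p": float(g["p_value"].min())}
        if aggregate == "condition_means":
            a = geometric_mean_aggregate(g["mean_count_A"].to_numpy())
            b = geometric_mean_aggregate(g["mean_count_B"].to_numpy())
            if a == 0 and b == 0:
                logger.warning("gene %s: zero counts in both conditions", gene_id)
                rec["lfc"] = np.nan
            elif a == 0 or b == 0:
                # zero in one condition: fall back to the shifted ratio
                rec["lfc"] = float(np.log2((a + 1.0) / (b + 1.0)))
            else:
                rec["lfc"] = float(np.log2(a / b))
        else:
            fc = geometric_mean_aggregate(np.exp2(g["log2FC"].to_numpy()))
            rec["lfc"] = float(np.log2(fc)) if fc > 0 else np.nan
        results[gene_id] = rec

    genes = sorted(results)
    adj = holm_adjust([results[g]["p"] for g in genes])
    out = []
    for g, ap in zip(genes, adj):
        lfc = results[g]["lfc"]
        label = "excluded"
        if np.isfinite(lfc) and ap < alpha:
            if lfc > lfc_threshold:
                label = "up"
            elif lfc < -lfc_threshold:
                label = "down"
        out.append(DEResult(g, lfc, results[g]["p"], float(ap), label))
    return out


def labels_to_series(results: list[DEResult]) -> pd.Series:
    """Binary up/down label vector (excluded genes dropped)."""
    kept = {r.gene_id: r.label for r in results if r.label in ("up", "down")}
    return pd.Series(kept, name="label", dtype="object")
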