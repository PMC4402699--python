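"""CpG methylation features.

Per-probe differential methylation between paired cancer and normal
tissues (logFC = mean M-value difference, cancer − normal), segment-level
aggregates (avgMval, avglogFC, numHyper, numHypo) and transcript-level
distances of differentially methylated probes to exon–exon junctions.

M-values are the logit-transformed methylation fraction,
``M = log2(beta / (1 - beta))``; positive logFC means hypermethylation
in cancer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segments import SegmentSet, TranscriptModel

#: per-segment methylation measures, in catalog order
METHYLATION_MEASURES = ("avgMval", "avglogFC", "numHyper", "numHypo")

#: the 12 junction-distance feature names
JUNCTION_FEATURES = tuple(
    f"{stat}{call}To{side}"
    for call in ("Hyper", "Hypo")
    for side in ("5", "3")
    for stat in ("max", "min", "avg")
)


def beta_to_m(beta):
    """Convert methylation fractions (beta) to M-values, M = log2(b/(1-b))."""
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta / (1.0 - beta))


@dataclass
class ProbeStats:
    """Differential-methylation summary of one CpG probe."""

    probe_id: str
    chromosome: str
    position: int
    logFC: float
    avgMval: float
    p_value: float
    adj_p: float
    call: str  # hyper | hypo | none


def probe_differential_stats(
    m_matrix: pd.DataFrame,
    pairing: pd.DataFrame,
    manifest: pd.DataFrame,
    *,
    alpha: float = 0.05,
    paired: bool = True,
) -> list[ProbeStats]:
    """Per-probe differential methylation between cancer and normal samples.

    Parameters
    ----------
    m_matrix : DataFrame
        Probes (rows) x samples (columns) of M-values.
    pairing : DataFrame
        Columns ``sample_id``, ``pair_id``, ``group`` (cancer/normal).
    manifest : DataFrame
        Columns ``probe_id``, ``chrom``, ``pos`` giving probe coordinates.
    alpha : float
        BH-adjusted significance threshold of the hyper/hypo call.
    paired : bool
        Paired t-test on per-pair differences (default) or Welch unpaired.

    logFC is the mean over pairs of (M_cancer - M_normal); avgMval the grand
    mean over both groups; p-values from a two-sided t-test, adjusted across
    probes by Benjamini-Hochberg.  Probes with fewer than 3 complete pairs
    get missing statistics (``call='none'``, NaN stats).
    """
    pairing = pairing.set_index("sample_id") if "sample_id" in pairing.columns else pairing
    cancer_cols, normal_cols = {}, {}
    for sample_id, row in pairing.iterrows():
        d = cancer_cols if str(row["group"]).lower() in ("cancer", "tumor", "a") else normal_cols
        d[row["pair_id"]] = sample_id
    common_pairs = sorted(set(cancer_cols) & set(normal_cols))
    if len(common_pairs) < 3:
        raise ValueError("need at least 3 complete cancer/normal pairs")
    ca = m_matrix[[cancer_cols[p] for p in common_pairs]].to_numpy(dtype=float)
    no = m_matrix[[normal_cols[p] for p in common_pairs]].to_numpy(dtype=float)

    if paired:
        diffs = ca - no  # probes x pairs; NaN where either member missing
        n = np.sum(np.isfinite(diffs), axis=1)
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            logfc = np.nanmean(diffs, axis=1)
            sd = np.nanstd(diffs, axis=1, ddof=1)
            t = logfc / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    else:
        res = stats.ttest_ind(ca, no, axis=1, equal_var=False, nan_policy="omit")
        logfc = np.nanmean(ca, axis=1) - np.nanmean(no, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        n = np.minimum(
            np.sum(np.isfinite(ca), axis=1), np.sum(np.isfinite(no), axis=1)
        )
    with np.errstate(invalid="ignore"):
        avgm = np.nanmean(np.concatenate([ca, no], axis=1), axis=1)

    enough = n >= 3
    testable = enough & np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if testable.any():
        adj[testable] = multipletests(p[testable], method="fdr_bh")[1]

    coords = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    out = []
    for i, probe_id in enumerate(m_matrix.index):
        row = coords.loc[probe_id]
        # effect estimates need >=3 complete pairs; the call additionally
        # needs a defined (non-degenerate) p-value
        lf = float(logfc[i]) if enough[i] else float("nan")
        am = float(avgm[i]) if enough[i] else float("nan")
        pv = float(p[i]) if testable[i] else float("nan")
        ap = float(adj[i]) if testable[i] else float("nan")
        call = "none"
        if testable[i] and ap < alpha:
            if lf > 0:
                call = "hyper"
            elif lf < 0:
                call = "hypo"
        out.append(
            ProbeStats(str(probe_id), str(row["chrom"]), int(row["pos"]),
                       lf, am, pv, ap, call)
        )
    return out


def segment_methylation_features(
    probes: list[ProbeStats], s: SegmentSet
) -> dict[str, float]:
    """avgMval / avglogFC / numHyper / numHypo per segment category.

    A probe contributes to a segment iff its position falls in any of the
    segment's intervals (a probe may contribute to several overlapping
    categories, e.g. UTR5 and first_exon).  Segments with no probe yield
    missing values (NaN for averages; counts are only defined where a
    probe maps, matching the source platform's missingness).
    """
    out: dict[str, float] = {}
    on_chrom = [p for p in probes if p.chromosome == s.chromosome]
    for cat, intervals in s.segments.items():
        hits = [
            p
            for p in on_chrom
            if any(lo <= p.position < hi for lo, hi in intervals)
        ]
        if not hits:
            continue
        mvals = [p.avgMval for p in hits if np.isfinite(p.avgMval)]
        fcs = [p.logFC for p in hits if np.isfinite(p.logFC)]
        out[f"{cat}_avgMval"] = float(np.mean(mvals)) if mvals else np.nan
        out[f"{cat}_avglogFC"] = float(np.mean(fcs)) if fcs else np.nan
        out[f"{cat}_numHyper"] = float(sum(p.call == "hyper" for p in hits))
        out[f"{cat}_numHypo"] = float(sum(p.call == "hypo" for p in hits))
    return out


def _transcript_coordinate(t: TranscriptModel, pos: int) -> int | None:
    """Map a genomic position on an exon to 0-based transcript coordinate."""
    exons = t.exon_intervals
    off = 0
    if t.strand == "+":
        for s, e in exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
    else:
        for s, e in reversed(exons):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
    return None


def _junction_positions(t: TranscriptModel) -> list[int]:
    """Exon-exon junction coordinates in transcript space.

    Junction ``J`` sits between transcript bases ``J-1`` and ``J``.
    """
    lengths = [e - s for s, e in t.exon_intervals]
    if t.strand == "-":
        lengths = lengths[::-1]
    out, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        out.append(acc)
    return out


def junction_distance_features(
    probes: list[ProbeStats], t: TranscriptModel
) -> dict[str, float]:
    """max/min/avg distance of hyper/hypo probes to nearest 5'/3' junctions.

    Distances are in transcript coordinates (introns excised).  A probe on
    the first base 3' of a junction is at distance 0 from that (5') junction;
    symmetrically the last base 5' of a junction is at distance 0 from that
    (3') junction.  Only exonic probes qualify; values are missing when no
    junction lies on the required side or no called probe exists.
    """
    out = {name: np.nan for name in JUNCTION_FEATURES}
    junctions = _junction_positions(t)
    if not junctions:
        return out
    dists: dict[tuple[str, str], list[float]] = {
        (c, s): [] for c in ("Hyper", "Hypo") for s in ("5", "3")
    }
    for p in probes:
        if p.call not in ("hyper", "hypo") or p.chromosome != t.chromosome:
            continue
        tc = _transcript_coordinate(t, p.position)
        if tc is None:
            continue
        call = p.call.capitalize()
        up = [j for j in junctions if j <= tc]
        down = [j for j in junctions if j > tc]
        if up:
            dists[(call, "5")].append(tc - max(up))
        if down:
            dists[(call, "3")].append(min(down) - 1 - tc)
    for (call, side), vals in dists.items():
        if vals:
            out[f"max{call}To{side}"] = float(max(vals))
            out[f"min{call}To{side}"] = float(min(vals))
            out[f"avg{call}To{side}"] = float(np.mean(vals))
    return out
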