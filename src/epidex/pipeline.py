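"""End-to-end orchestration: bundle -> features -> selection -> evaluation.

``extract_features`` turns an input bundle (annotation, genome, CpG
M-values, histone read sets, conservation tracks) into the per-gene
catalog feature matrix; ``run_study`` performs the stratified 80/20
split, feature selection on the training split (CFS fixes the subset
size; rankers are size-matched), 10-fold cross-validation on the
training split and a held-out evaluation on the test split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import histone as hst
from . import methylation as meth
from . import sequence_features as seqf
from .catalog import (
    FeatureCatalog,
    assemble_matrix,
    build_catalog,
    gene_level_reduce,
    impute_median,
)
from .evaluation import (
    EvaluationReport,
    classifier_train,
    compute_metrics,
    cross_validate,
    stratified_split,
)
from .expression import label_genes, labels_to_series
from .segments import read_annotation, segment_transcript
from .selection import (
    SelectionResult,
    cfs_select,
    gain_ratio_rank,
    match_top_n,
    relieff_rank,
)

logger = logging.getLogger(__name__)

SELECTORS = ("CFS", "GainRatio", "ReliefF")


@dataclass
class Bundle:
    """Paths of one input data bundle."""

    root: Path

    @property
    def genome(self): return self.root / "genome.fa"
    @property
    def annotation(self): return self.root / "annotation.refflat.tsv"
    @property
    def probes(self): return self.root / "probes.tsv"
    @property
    def mvalues(self): return self.root / "mvalues.tsv"
    @property
    def pairing(self): return self.root / "pairing.tsv"
    @property
    def de_table(self): return self.root / "de_table.tsv"

    def reads(self, cell_line: str, marker: str) -> Path:
        return self.root / f"reads_{cell_line}{marker}.bed"

    def conservation(self, species_set: str) -> Path:
        return self.root / f"conservation_{species_set}.bedgraph"


def extract_features(
    bundle: Bundle | str | Path,
    catalog: FeatureCatalog | None = None,
) -> tuple[pd.DataFrame, FeatureCatalog]:
    """Compute the per-gene feature matrix of a bundle.

    Transcript-level features are reduced to gene level by the arithmetic
    mean over each gene's transcripts.
    """
    if not isinstance(bundle, Bundle):
        bundle = Bundle(Path(bundle))
    catalog = catalog or build_catalog()

    transcripts = read_annotation(bundle.annotation, dialect="refflat")
    seg_sets = [segment_transcript(t) for t in transcripts]
    tx_index = pd.Index([t.transcript_id for t in transcripts], name="transcript_id")
    gene_map = pd.Series(
        {t.transcript_id: t.gene_id for t in transcripts}, name="gene_id"
    )

    # ---- methylation ------------------------------------------------------
    manifest = pd.read_csv(bundle.probes, sep="\t", dtype={"chrom": str})
    mvals = pd.read_csv(bundle.mvalues, sep="\t", index_col=0)
    pairing = pd.read_csv(bundle.pairing, sep="\t")
    probe_stats = meth.probe_differential_stats(mvals, pairing, manifest)

    by_chrom: dict[str, tuple[np.ndarray, list]] = {}
    for chrom in manifest["chrom"].unique():
        ps = sorted(
            (p for p in probe_stats if p.chromosome == chrom),
            key=lambda p: p.position,
        )
        by_chrom[chrom] = (np.array([p.position for p in ps]), ps)

    meth_rows, junction_rows = {}, {}
    for t, ss in zip(transcripts, seg_sets):
        pos, ps = by_chrom.get(t.chromosome, (np.array([]), []))
        lo = min(iv[0] for ivs in ss.segments.values() for iv in ivs)
        hi = max(iv[1] for ivs in ss.segments.values() for iv in ivs)
        i, j = np.searchsorted(pos, [lo, hi])
        local = ps[i:j]
        meth_rows[t.transcript_id] = meth.segment_methylation_features(local, ss)
        junction_rows[t.transcript_id] = meth.junction_distance_features(local, t)
    meth_tx = pd.DataFrame.from_dict(meth_rows, orient="index").reindex(tx_index)
    junc_tx = pd.DataFrame.from_dict(junction_rows, orient="index").reindex(tx_index)

    # ---- histone ----------------------------------------------------------
    hist_cols: dict[str, dict[str, float]] = {}
    densities: dict[str, dict[tuple[str, str], float]] = {}
    lengths = {
        (ss.transcript_id, cat): hst.segment_length_for_density(ss, cat)
        for ss in seg_sets
        for cat in ss.segments
    }
    for line in hst.CELL_LINES:
        for marker in hst.MARKERS:
            rs = hst.ReadSet.from_bed(bundle.reads(line, marker), line, marker)
            counts = hst.count_reads_bulk(rs, seg_sets)
            dens = {
                key: hst.normalize_density(c, lengths[key], rs.library_size)
                for key, c in counts.items()
            }
            densities[f"{line}{marker}"] = dens
            for (tx, cat), d in dens.items():
                hist_cols.setdefault(tx, {})[f"{cat}_{line}{marker}"] = d
    for marker in hst.MARKERS:
        da, ds = densities[f"A{marker}"], densities[f"S{marker}"]
        for key in da:
            tx, cat = key
            hist_cols.setdefault(tx, {})[
                f"{cat}_A{marker}_minus_S{marker}_divavg"
            ] = hst.compare_cell_lines(da[key], ds[key])
    hist_tx = pd.DataFrame.from_dict(hist_cols, orient="index").reindex(tx_index)

    # ---- nucleotide + conservation ---------------------------------------
    genome = Fasta(str(bundle.genome))
    seq_rows = {
        ss.transcript_id: seqf.segment_nucleotide_features(genome, ss)
        for ss in seg_sets
    }
    seq_tx = pd.DataFrame.from_dict(seq_rows, orient="index").reindex(tx_index)

    cons_rows: dict[str, dict[str, float]] = {tx: {} for tx in tx_index}
    for sp in seqf.SPECIES_SETS:
        track = seqf.ConservationTrack.from_bedgraph(bundle.conservation(sp))
        for ss in seg_sets:
            cons_rows[ss.transcript_id].update(seqf.segment_conservation(track, ss, sp))
    cons_tx = pd.DataFrame.from_dict(cons_rows, orient="index").reindex(tx_index)

    blocks = []
    for tx_frame in (meth_tx, junc_tx, hist_tx, seq_tx, cons_tx):
        blocks.append(gene_level_reduce(tx_frame, gene_map))
    matrix = assemble_matrix(blocks, catalog)
    logger.info(
        "feature matrix: %d genes x %d features (%.1f%% missing)",
        *matrix.shape, 100 * matrix.isna().to_numpy().mean(),
    )
    return matrix, catalog


def load_labels(bundle: Bundle | str | Path) -> pd.Series:
    """Binary up/down gene labels from the bundle's transcript DE table."""
    if not isinstance(bundle, Bundle):
        bundle = Bundle(Path(bundle))
    de = pd.read_csv(bundle.de_table, sep="\t")
    return labels_to_series(label_genes(de))


def select_features(
    m: pd.DataFrame,
    labels: pd.Series,
    selector: str,
    *,
    seed: int = 0,
    n_features: int | None = None,
) -> tuple[SelectionResult, SelectionResult]:
    """Run CFS (for its subset size) and the requested selector.

    Returns ``(cfs_result, chosen_result)``; for the rankers the chosen
    result is size-matched to the CFS subset (or to ``n_features``).
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    cfs = cfs_select(m, labels)
    n = n_features or max(cfs.n_selected, 1)
    if selector == "CFS":
        return cfs, cfs
    rank = gain_ratio_rank(m, labels) if selector == "GainRatio" else relieff_rank(
        m, labels, seed=seed
    )
    return cfs, match_top_n(rank, min(n, len(rank.scores)))


@dataclass
class StudyResult:
    """Everything one modeling run produced."""

    selector: str
    classifier: str
    selection: SelectionResult
    cfs_size: int
    train_report: EvaluationReport
    test_report: EvaluationReport
    train_ids: pd.Index
    test_ids: pd.Index

    def summary(self) -> pd.DataFrame:
        rows = []
        for split, rep in (("train_cv", self.train_report), ("test", self.test_report)):
            rows.append(
                {
                    "split": split,
                    "auc": rep.auc,
                    "accuracy": rep.accuracy,
                    "f_measure": rep.f_measure,
                    "mcc": rep.mcc,
                }
            )
        return pd.DataFrame(rows).set_index("split")


def run_study(
    m: pd.DataFrame,
    labels: pd.Series,
    *,
    selector: str = "ReliefF",
    classifier: str = "random_forest",
    train_fraction: float = 0.8,
    folds: int = 10,
    seed: int = 0,
    n_features: int | None = None,
    hyperparameters: dict | None = None,
    preselected: tuple[SelectionResult, SelectionResult] | None = None,
) -> StudyResult:
    """Split, select on the training split, cross-validate, evaluate held-out.

    Selection sees only the training split; the information-theoretic
    selectors use MDL discretization (missing values form their own
    category) and ReliefF its native incomplete-data handling, so
    selection runs on the unimputed matrix.  Classifiers train on
    median-imputed data (medians from the training side only).
    """
    labels = labels.reindex(m.index).dropna()
    m = m.loc[labels.index]
    train_ids, test_ids = stratified_split(labels, train_fraction, seed)
    m_train, m_test = m.loc[train_ids], m.loc[test_ids]
    y_train, y_test = labels.loc[train_ids], labels.loc[test_ids]

    if preselected is not None:
        cfs, chosen = preselected
    else:
        cfs, chosen = select_features(
            m_train, y_train, selector, seed=seed, n_features=n_features
        )
    cols = chosen.selected
    if not cols:
        raise ValueError("selection returned no features")

    train_report = cross_validate(
        m_train[cols], y_train, classifier, folds=folds, seed=seed,
        hyperparameters=hyperparameters,
    )
    tr_x, te_x = impute_median(m_train[cols], m_test[cols])
    scorer = classifier_train(classifier, tr_x, y_train, hyperparameters, seed=seed)
    test_scores = scorer(te_x)
    test_metrics = compute_metrics(test_scores, y_test)
    test_report = EvaluationReport(
        model_id=f"{selector}+{classifier}",
        scores=test_scores,
        **test_metrics,
    )
    return StudyResult(
        selector, classifier, chosen, cfs.n_selected,
        train_report, test_report, train_ids, test_ids,
    )


def run_grid(
    m: pd.DataFrame,
    labels: pd.Series,
    *,
    selectors: tuple[str, ...] = SELECTORS,
    classifiers: tuple[str, ...] = None,
    seed: int = 0,
    folds: int = 10,
) -> pd.DataFrame:
    """The selector x classifier benchmark grid (15 models by default)."""
    from .evaluation import CLASSIFIERS

    classifiers = classifiers or CLASSIFIERS
    rows = []
    labels_ = labels.reindex(m.index).dropna()
    m_ = m.loc[labels_.index]
    train_ids, _ = stratified_split(labels_, 0.8, seed)
    for sel in selectors:
        pre = select_features(
            m_.loc[train_ids], labels_.loc[train_ids], sel, seed=seed
        )
        for clf in classifiers:
            study = run_study(
                m, labels, selector=sel, classifier=clf, seed=seed, folds=folds,
                preselected=pre,
            )
            rows.append(
                {
                    "selector": sel,
                    "classifier": clf,
                    "n_selected": study.selection.n_selected,
                    "train_cv_auc": study.train_report.auc,
                    "test_auc": study.test_report.auc,
                    "train_cv_mcc": study.train_report.mcc,
                    "test_mcc": study.test_report.mcc,
                }
            )
    return pd.DataFrame(rows)
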