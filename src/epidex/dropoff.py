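"""Drop-off (ablation) experiment designs.

Two designs: (1) data-type drop-off — remove one feature family
(nucleotide, histone, methylation, or nucleotide+histone) from the full
catalog; (2) sequential segment drop-off — within the methylation-only
sub-model, progressively remove first exon/intron features, then all
gene-body features, then TSS1500, leaving only the TSS200 aggregates.
For every condition, feature selection and classification are re-run on
the surviving columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import FeatureCatalog, parse_feature_name
from .evaluation import EvaluationReport
from .pipeline import run_study

GENE_BODY_SEGMENTS = (
    "UTR5", "first_exon", "first_intron", "exon", "intron", "CDS",
    "last_intron", "last_exon", "UTR3", "fullTranscript",
    "single_exon", "single_intron",
)


@dataclass
class DropoffCondition:
    name: str
    removed: list[str]  # feature names removed from the catalog


@dataclass
class DropoffPlan:
    name: str
    conditions: list[DropoffCondition]

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "conditions": [
                {"name": c.name, "n_removed": len(c.removed), "removed": c.removed}
                for c in self.conditions
            ],
        }


def datatype_dropoff_plan(catalog: FeatureCatalog) -> DropoffPlan:
    """Full model plus removal of each data-type family.

    Families: nucleotide = composition + length; histone = densities +
    comparisons; methylation = segment aggregates + junction distances.
    Conservation is never dropped.
    """
    nucleotide = catalog.by_data_type("nucleotide", "length")
    histone = catalog.by_data_type("histone", "histone_cmp")
    methylation = catalog.by_data_type("methylation", "junction")
    return DropoffPlan(
        "datatype",
        [
            DropoffCondition("full_model", []),
            DropoffCondition("minus_nucleotide", nucleotide),
            DropoffCondition("minus_histone", histone),
            DropoffCondition("minus_methylation", methylation),
            DropoffCondition("minus_nucleotide_histone", nucleotide + histone),
        ],
    )


def segment_dropoff_plan(catalog: FeatureCatalog) -> DropoffPlan:
    """Sequential segment-wise drop-off on the methylation-only sub-model.

    Step 0 keeps all methylation features (segment aggregates + junction
    distances); step 1 additionally removes first exon/intron features;
    step 2 removes all gene-body features (exons, introns, UTRs, CDS,
    full transcript, and the exon-defined junction distances); step 3
    removes TSS1500 so only the four TSS200 aggregates remain.  Removed
    sets are strictly nested.
    """
    non_methylation = [
        d.name
        for d in catalog.descriptors
        if d.data_type not in ("methylation", "junction")
    ]

    def meth_of(segments: tuple[str, ...]) -> list[str]:
        return [
            d.name
            for d in catalog.descriptors
            if d.data_type == "methylation" and d.segment in segments
        ]

    junction = catalog.by_data_type("junction")
    step1 = meth_of(("first_exon", "first_intron"))
    body_segs = tuple(s for s in GENE_BODY_SEGMENTS if s not in ("first_exon", "first_intron"))
    step2 = meth_of(body_segs) + junction
    step3 = meth_of(("TSS1500",))

    removed0 = list(non_methylation)
    removed1 = removed0 + step1
    removed2 = removed1 + step2
    removed3 = removed2 + step3
    return DropoffPlan(
        "segment",
        [
            DropoffCondition("all_methylation", removed0),
            DropoffCondition("minus_first_exon_intron", removed1),
            DropoffCondition("minus_gene_body", removed2),
            DropoffCondition("TSS200_only", removed3),
        ],
    )


def run_dropoff(
    plan: DropoffPlan,
    m: pd.DataFrame,
    labels: pd.Series,
    *,
    selector: str = "ReliefF",
    classifier: str = "random_forest",
    train_fraction: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run selection + classification per condition; tabulate metrics.

    Returns a tidy frame with one row per (condition, split) carrying the
    four metrics, the number of removed/surviving columns and the number
    of selected features.
    """
    rows = []
    for cond in plan.conditions:
        removed = set(cond.removed)
        unknown = removed - set(m.columns)
        if unknown:
            raise ValueError(
                f"{cond.name}: removed features not in matrix: {sorted(unknown)[:5]}"
            )
        keep = [c for c in m.columns if c not in removed]
        if not keep:
            raise ValueError(f"condition {cond.name!r} removes every feature")
        study = run_study(
            m[keep], labels,
            selector=selector, classifier=classifier,
            train_fraction=train_fraction, folds=folds, seed=seed,
        )
        overlap = set(study.selection.selected) & removed
        assert not overlap, f"{cond.name}: selected removed features {overlap}"
        for split, rep in (("train_cv", study.train_report), ("test", study.test_report)):
            rows.append(
                {
                    "condition": cond.name,
                    "split": split,
                    "auc": rep.auc,
                    "accuracy": rep.accuracy,
                    "f_measure": rep.f_measure,
                    "mcc": rep.mcc,
                    "n_removed": len(cond.removed),
                    "n_features": len(keep),
                    "n_selected": study.selection.n_selected,
                }
            )
    return pd.DataFrame(rows)
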