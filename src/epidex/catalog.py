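"""The canonical named feature schema and feature-matrix assembly.

The default catalog enumerates 1424 features over the 14 segment
categories: 4 methylation aggregates (56), mono/di/tri-nucleotide
composition (56 + 224 + 896), 12 segment lengths (the fixed-width
promoter windows have none), 6 histone read densities (84), 3 histone
cancer-vs-normal comparisons (42), 3 conservation scores (42), and the
12 transcript-level junction-distance features.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .histone import COMPARISON_SUFFIXES, DENSITY_SUFFIXES
from .methylation import JUNCTION_FEATURES, METHYLATION_MEASURES
from .segments import SEGMENT_CATEGORIES
from .sequence_features import KMERS, SPECIES_SETS

#: segments that carry a length feature (all but the fixed promoter windows)
LENGTH_SEGMENTS = tuple(c for c in SEGMENT_CATEGORIES if c not in ("TSS1500", "TSS200"))

DATA_TYPES = (
    "methylation", "nucleotide", "length", "histone", "histone_cmp",
    "conservation", "junction",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    data_type: str   # methylation | nucleotide | length | histone | histone_cmp | conservation | junction
    segment: str     # a segment category, or "transcript" for junction features
    measure: str     # e.g. avgMval, AA, length, A4, A4_minus_S4_divavg, vertebrate


@dataclass(frozen=True)
class FeatureCatalog:
    descriptors: tuple[FeatureDescriptor, ...]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def subset(self, predicate) -> list[str]:
        return [d.name for d in self.descriptors if predicate(d)]

    def by_data_type(self, *data_types: str) -> list[str]:
        return self.subset(lambda d: d.data_type in data_types)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(d) for d in self.descriptors], fh, indent=1)


def build_catalog(
    data_types: tuple[str, ...] = DATA_TYPES,
    segments: tuple[str, ...] = SEGMENT_CATEGORIES,
) -> FeatureCatalog:
    """Build the ordered feature catalog (default: all 1424 features).

    The order is family-major (methylation aggregates, mono, di, tri,
    length, histone densities, histone comparisons, conservation,
    junction), with segments in canonical order inside each family.
    """
    for dt in data_types:
        if dt not in DATA_TYPES:
            raise ValueError(f"unknown data type {dt!r}")
    for seg in segments:
        if seg not in SEGMENT_CATEGORIES:
            raise ValueError(f"unknown segment category {seg!r}")
    segs = tuple(c for c in SEGMENT_CATEGORIES if c in segments)
    desc: list[FeatureDescriptor] = []

    def add(name, dt, seg, measure):
        desc.append(FeatureDescriptor(name, dt, seg, measure))

    if "methylation" in data_types:
        for m in METHYLATION_MEASURES:
            for s in segs:
                add(f"{s}_{m}", "methylation", s, m)
    if "nucleotide" in data_types:
        for k in (1, 2, 3):
            for mer in KMERS[k]:
                for s in segs:
                    add(f"{s}_{mer}", "nucleotide", s, mer)
    if "length" in data_types:
        for s in segs:
            if s in LENGTH_SEGMENTS:
                add(f"{s}_length", "length", s, "length")
    if "histone" in data_types:
        for suf in DENSITY_SUFFIXES:
            for s in segs:
                add(f"{s}_{suf}", "histone", s, suf)
    if "histone_cmp" in data_types:
        for suf in COMPARISON_SUFFIXES:
            for s in segs:
                add(f"{s}_{suf}", "histone_cmp", s, suf)
    if "conservation" in data_types:
        for sp in SPECIES_SETS:
            for s in segs:
                add(f"{s}_{sp}", "conservation", s, sp)
    if "junction" in data_types:
        for name in JUNCTION_FEATURES:
            add(name, "junction", "transcript", name)

    names = [d.name for d in desc]
    assert len(names) == len(set(names)), "duplicate feature names"
    return FeatureCatalog(tuple(desc))


_KMER_RE = re.compile(r"^[ACGT]{1,3}$")


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """(data_type, segment, measure) recovered from a feature name."""
    if name in JUNCTION_FEATURES:
        return "junction", "transcript", name
    for seg in sorted(SEGMENT_CATEGORIES, key=len, reverse=True):
        if name.startswith(seg + "_"):
            measure = name[len(seg) + 1 :]
            if measure in METHYLATION_MEASURES:
                return "methylation", seg, measure
            if _KMER_RE.match(measure):
                return "nucleotide", seg, measure
            if measure == "length":
                return "length", seg, measure
            if measure in DENSITY_SUFFIXES:
                return "histone", seg, measure
            if measure in COMPARISON_SUFFIXES:
                return "histone_cmp", seg, measure
            if measure in SPECIES_SETS:
                return "conservation", seg, measure
    raise ValueError(f"unparsable feature name {name!r}")


def gene_level_reduce(
    transcript_features: pd.DataFrame, gene_map: pd.Series
) -> pd.DataFrame:
    """Arithmetic mean of per-transcript feature vectors per gene.

    ``gene_map`` maps transcript_id -> gene_id.  NaNs are ignored in the
    mean; a feature missing for every transcript of a gene stays missing.
    """
    genes = transcript_features.index.map(gene_map)
    if genes.isna().any():
        missing = transcript_features.index[genes.isna()].tolist()
        raise ValueError(f"transcripts without gene mapping: {missing[:5]}")
    return transcript_features.groupby(genes).mean()


def assemble_matrix(
    sources: list[pd.DataFrame], catalog: FeatureCatalog
) -> pd.DataFrame:
    """Join per-gene feature blocks into one catalog-conformant matrix.

    Each source is a genes x features frame.  The gene universe is the
    intersection across sources; catalog columns absent from every source
    are created as missing.
    """
    if not sources:
        raise ValueError("no feature sources")
    genes = sources[0].index
    for src in sources[1:]:
        genes = genes.intersection(src.index)
    blocks = [src.reindex(genes) for src in sources]
    wide = pd.concat(blocks, axis=1)
    dup = wide.columns[wide.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature columns across sources: {list(dup)[:5]}")
    extra = set(wide.columns) - set(catalog.names)
    if extra:
        raise ValueError(f"columns not in catalog: {sorted(extra)[:5]}")
    out = wide.reindex(columns=catalog.names)
    out.index.name = "gene_id"
    return out.astype(float)


def impute_median(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Median-impute missing values; medians fitted on the training frame only.

    Columns that are entirely missing in the training frame are filled
    with 0 (no information available).
    """
    med = train.median(axis=0, skipna=True).fillna(0.0)
    return tuple(df.fillna(med).fillna(0.0) for df in (train, *others))
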