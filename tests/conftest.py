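"""Shared fixtures: toy transcripts and a small synthetic bundle."""

import numpy as np
import pandas as pd
import pytest

from epidex.segments import TranscriptModel, segment_transcript
from epidex.simulate import SimulationConfig, generate_bundle


@pytest.fixture
def three_exon_plus():
    """Plus-strand 3-exon coding transcript with room for both TSS windows."""
    return TranscriptModel(
        "tx1", "g1", "chr1", "+",
        exon_intervals=((10000, 10200), (10500, 10700), (11000, 11300)),
        cds_interval=(10100, 11150),
    )


@pytest.fixture
def three_exon_minus():
    return TranscriptModel(
        "tx2", "g2", "chr1", "-",
        exon_intervals=((10000, 10200), (10500, 10700), (11000, 11300)),
        cds_interval=(10100, 11150),
    )


@pytest.fixture
def single_exon():
    return TranscriptModel(
        "tx3", "g3", "chr1", "+", exon_intervals=((5000, 5400),),
        cds_interval=(5100, 5300),
    )


@pytest.fixture
def two_exon():
    return TranscriptModel(
        "tx4", "g4", "chr1", "+",
        exon_intervals=((20000, 20300), (20800, 21100)),
        cds_interval=(20100, 21000),
    )


@pytest.fixture
def segset(three_exon_plus):
    return segment_transcript(three_exon_plus)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic bundle (150 labeled genes, 6 pairs)."""
    root = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(
        n_genes=150, n_background=20, n_pairs=6, seed=11, read_depth=30000,
        n_chromosomes=2,
    )
    return generate_bundle(cfg, root)


@pytest.fixture(scope="session")
def small_features(small_bundle):
    from epidex.pipeline import extract_features, load_labels

    matrix, catalog = extract_features(small_bundle.root)
    labels = load_labels(small_bundle.root)
    return matrix, catalog, labels


def brute_force_overlap_counts(reads, intervals):
    """Count reads overlapping any interval by >=1 base (each read once)."""
    n = 0
    for rs, re in reads:
        if any(rs < hi and re > lo for lo, hi in intervals):
            n += 1
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
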