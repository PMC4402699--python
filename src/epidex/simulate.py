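"""Synthetic multi-omic data bundles with planted epigenetic effects.

The generator emits a complete, internally consistent input bundle —
random genome FASTA, refFlat transcript annotation, CpG probe manifest
with a paired tumor/normal M-value matrix, six histone ChIP-seq read
sets (2 cell lines x 3 marks), three conservation tracks and a
transcript-level differential-expression table — with configurable
associations between epigenetic state and the up/down expression label:

* down-regulated genes carry promoter hypermethylation in the cancer
  samples (M-value shift ``+meth_delta`` on TSS200/TSS1500 probes);
* up-regulated genes carry promoter H3K4me3 and gene-body H3K36me3 read
  enrichment in the cancer (A) cell line;
* an optional interaction mode replaces the marginal histone effects
  with an XOR pattern of the two marks, so that only the joint state is
  informative about the label.

Effects are planted at the data-generating level (probe M-values, read
placements), never at the feature-table level, so the whole extraction
stack is exercised.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segments import TranscriptModel, segment_transcript, write_refflat


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Default scale: 2000 labeled genes plus 200 non-DE background genes,
    20 tumor/normal pairs, 3 marks x 2 cell lines at 100k reads each.
    """

    n_genes: int = 2000
    n_background: int = 200
    n_pairs: int = 20
    seed: int = 0
    frac_up: float = 0.5
    n_chromosomes: int = 4

    # planted effect sizes
    meth_delta: float = 1.0          # promoter M shift (down genes, cancer samples)
    k4_promoter_fold: float = 3.0    # H3K4me3 promoter enrichment (up genes, A line)
    k36_body_fold: float = 2.0       # H3K36me3 body enrichment (up genes, A line)
    interaction: bool = False        # XOR histone pattern instead of marginal effects

    # noise scales
    probe_noise_sd: float = 0.5      # within-sample M noise
    pair_effect_sd: float = 0.3      # shared per-pair probe effect
    gene_meth_sd: float = 0.5        # between-gene spread of the promoter shift
    gene_activity_sd: float = 0.4    # lognormal sd of per-gene histone activity

    # probe placement intensities
    probes_tss200: float = 2.0       # expected probes in the TSS200 window
    probes_tss1500: float = 3.0      # expected probes in the TSS1500 window
    probes_per_kb_body: float = 3.0  # expected probes per kb of transcript span

    # histone libraries
    read_depth: int = 100_000        # aligned reads per library
    read_length: int = 75
    signal_fraction: float = 0.7     # reads placed on genes vs uniform background

    # expression table
    lfc_base: float = 1.2            # minimum |log2FC| of DE genes
    lfc_scale: float = 0.6           # exponential tail of |log2FC|

    def scaled(self, effect_scale: float) -> "SimulationConfig":
        """Copy with every planted effect scaled by ``effect_scale``.

        Fold effects scale on the log scale (fold**s), the M shift linearly.
        """
        return dataclasses.replace(
            self,
            meth_delta=self.meth_delta * effect_scale,
            k4_promoter_fold=float(self.k4_promoter_fold**effect_scale),
            k36_body_fold=float(self.k36_body_fold**effect_scale),
        )


@dataclass
class SyntheticBundle:
    root: Path
    config: SimulationConfig
    transcripts: list[TranscriptModel]
    labels: pd.Series  # gene -> up/down (background genes absent)


# baseline histone densities (reads per kb, arbitrary units before scaling)
_BASE_RATES = {
    "4": {"promoter": 8.0, "body": 1.0},
    "27": {"promoter": 2.0, "body": 2.0},
    "36": {"promoter": 1.0, "body": 4.0},
}

_CONS_BLOCK = 200  # bases per conservation run


def _make_gene(rng, chrom, cursor, gene_idx) -> tuple[TranscriptModel, int]:
    n_exons = 1 if rng.random() < 0.10 else int(rng.integers(2, 11))
    exon_lens = rng.integers(80, 300, size=n_exons)
    intron_lens = rng.integers(150, 600, size=max(n_exons - 1, 0))
    start = cursor
    exons, pos = [], start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    end = pos
    strand = "+" if rng.random() < 0.5 else "-"
    cds = None
    if sum(exon_lens) >= 120:
        cds = (exons[0][0] + int(exon_lens[0] // 2), exons[-1][1] - int(exon_lens[-1] // 2))
        if cds[0] >= cds[1]:
            cds = None
    gid = f"G{gene_idx:05d}"
    t = TranscriptModel(f"T{gene_idx:05d}", gid, chrom, strand, tuple(exons), cds)
    return t, end


def generate_genome_annotation(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[TranscriptModel]]:
    """Random chromosome sequences and gene models (not yet written out)."""
    n_total = cfg.n_genes + cfg.n_background
    per_chrom = int(np.ceil(n_total / cfg.n_chromosomes))
    transcripts: list[TranscriptModel] = []
    chrom_seqs: dict[str, np.ndarray] = {}
    gene_idx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 1700 + int(rng.integers(0, 500))
        for _ in range(per_chrom):
            if gene_idx >= n_total:
                break
            t, end = _make_gene(rng, chrom, cursor, gene_idx)
            transcripts.append(t)
            cursor = end + 1700 + int(rng.integers(500, 1500))
            gene_idx += 1
        length = cursor + 2000
        chrom_seqs[chrom] = rng.integers(0, 4, size=length).astype(np.uint8)
    return chrom_seqs, transcripts


def generate_labels(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """i.i.d. up/down labels for the first ``n_genes`` genes."""
    draws = rng.random(cfg.n_genes) < cfg.frac_up
    return pd.Series(
        np.where(draws, "up", "down"),
        index=[f"G{i:05d}" for i in range(cfg.n_genes)],
        name="label",
    )


def _promoter_windows(t: TranscriptModel) -> list[tuple[int, int]]:
    seg = segment_transcript(t).segments
    return seg.get("TSS200", []) + seg.get("TSS1500", [])


def _write_fasta(chrom_seqs: dict[str, np.ndarray], path: Path) -> None:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, codes in chrom_seqs.items():
            fh.write(f">{chrom}\n")
            ascii_seq = lut[codes].tobytes().decode("ascii")
            for i in range(0, len(ascii_seq), 80):
                fh.write(ascii_seq[i : i + 80] + "\n")


def generate_bundle(cfg: SimulationConfig, out_dir) -> SyntheticBundle:
    """Generate and write a complete bundle under ``out_dir``."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    chrom_seqs, transcripts = generate_genome_annotation(cfg, rng)
    labels = generate_labels(cfg, rng)
    _write_fasta(chrom_seqs, root / "genome.fa")
    write_refflat(transcripts, root / "annotation.refflat.tsv")

    label_of = labels.to_dict()  # background genes absent -> None

    # ---- CpG probes and M-values -----------------------------------------
    # every gene's promoter carries a random cancer-vs-normal methylation
    # change; down-regulated genes get the systematic +meth_delta on top,
    # so at meth_delta=0 the two classes are exchangeable
    probe_rows = []
    gene_shift = {
        t.gene_id: float(rng.normal(0.0, cfg.gene_meth_sd))
        + (cfg.meth_delta if label_of.get(t.gene_id) == "down" else 0.0)
        for t in transcripts
    }
    pid = 0
    for t in transcripts:
        lab = label_of.get(t.gene_id)
        windows = _promoter_windows(t)
        span = t.span
        n200 = rng.poisson(cfg.probes_tss200)
        n1500 = rng.poisson(cfg.probes_tss1500)
        nbody = rng.poisson(cfg.probes_per_kb_body * (span[1] - span[0]) / 1000.0)
        seg = segment_transcript(t).segments
        placements = []
        if "TSS200" in seg:
            lo, hi = seg["TSS200"][0]
            placements += [(int(p), True) for p in rng.integers(lo, hi, size=n200)]
        if "TSS1500" in seg:
            lo, hi = seg["TSS1500"][0]
            placements += [(int(p), True) for p in rng.integers(lo, hi, size=n1500)]
        placements += [
            (int(p), False) for p in rng.integers(span[0], span[1], size=nbody)
        ]
        for pos, in_promoter in placements:
            shift = gene_shift[t.gene_id] if in_promoter else 0.0
            probe_rows.append((f"cg{pid:08d}", t.chromosome, pos, shift))
            pid += 1

    manifest = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "_shift"]
    )
    n_probes = len(manifest)
    shifts = manifest.pop("_shift").to_numpy()
    manifest.to_csv(root / "probes.tsv", sep="\t", index=False)

    baseline = rng.normal(0.0, 2.0, size=n_probes)
    normal_cols, cancer_cols, pair_ids = [], [], []
    m = np.empty((n_probes, 2 * cfg.n_pairs))
    for i in range(cfg.n_pairs):
        pair_fx = rng.normal(0.0, cfg.pair_effect_sd, size=n_probes)
        m[:, 2 * i] = baseline + pair_fx + rng.normal(0, cfg.probe_noise_sd, n_probes)
        m[:, 2 * i + 1] = (
            baseline + pair_fx + shifts + rng.normal(0, cfg.probe_noise_sd, n_probes)
        )
        normal_cols.append(f"N{i:02d}")
        cancer_cols.append(f"T{i:02d}")
        pair_ids.append(f"P{i:02d}")
    cols = [c for pair in zip(normal_cols, cancer_cols) for c in pair]
    mdf = pd.DataFrame(m, index=manifest["probe_id"], columns=cols)
    mdf.to_csv(root / "mvalues.tsv", sep="\t", float_format="%.5f")
    pairing = pd.DataFrame(
        {
            "sample_id": cols,
            "pair_id": [p for p in pair_ids for _ in range(2)],
            "group": ["normal", "cancer"] * cfg.n_pairs,
        }
    )
    pairing.to_csv(root / "pairing.tsv", sep="\t", index=False)

    # ---- histone read sets ------------------------------------------------
    activity = np.exp(rng.normal(0.0, cfg.gene_activity_sd, size=len(transcripts)))
    z1 = rng.random(len(transcripts)) < 0.5
    z2 = np.empty_like(z1)
    for i, t in enumerate(transcripts):
        lab = label_of.get(t.gene_id)
        if cfg.interaction and lab is not None:
            z2[i] = z1[i] if lab == "up" else not z1[i]
        else:
            z2[i] = rng.random() < 0.5

    chrom_len = {c: len(s) for c, s in chrom_seqs.items()}
    for line in ("A", "S"):
        for marker in ("4", "27", "36"):
            regions, rates = [], []
            for i, t in enumerate(transcripts):
                lab = label_of.get(t.gene_id)
                prom_rate = _BASE_RATES[marker]["promoter"] * activity[i]
                body_rate = _BASE_RATES[marker]["body"] * activity[i]
                if line == "A" and lab == "up":
                    if cfg.interaction:
                        if marker == "4" and z1[i]:
                            prom_rate *= cfg.k4_promoter_fold
                        if marker == "36" and z2[i]:
                            body_rate *= cfg.k36_body_fold
                    else:
                        if marker == "4":
                            prom_rate *= cfg.k4_promoter_fold
                        if marker == "36":
                            body_rate *= cfg.k36_body_fold
                elif line == "A" and cfg.interaction and lab == "down":
                    # XOR pattern: down genes show the complementary state
                    if marker == "4" and z1[i]:
                        prom_rate *= cfg.k4_promoter_fold
                    if marker == "36" and z2[i]:
                        body_rate *= cfg.k36_body_fold
                for lo, hi in _promoter_windows(t):
                    regions.append((t.chromosome, lo, hi))
                    rates.append(prom_rate)
                span = t.span
                regions.append((t.chromosome, span[0], span[1]))
                rates.append(body_rate)
            lens = np.array([hi - lo for _, lo, hi in regions], dtype=float)
            weights = np.asarray(rates) * lens / 1000.0
            n_signal = int(round(cfg.read_depth * cfg.signal_fraction))
            n_bg = cfg.read_depth - n_signal
            counts = rng.poisson(weights / weights.sum() * n_signal)
            rows = []
            for (chrom, lo, hi), c in zip(regions, counts):
                if c == 0:
                    continue
                starts = rng.integers(
                    max(lo - cfg.read_length + 1, 0), hi, size=c
                )
                for s in starts:
                    rows.append((chrom, int(s), int(s) + cfg.read_length))
            chroms = list(chrom_len)
            probs = np.array([chrom_len[c] for c in chroms], dtype=float)
            bg_chrom = rng.choice(len(chroms), size=n_bg, p=probs / probs.sum())
            for ci in bg_chrom:
                c = chroms[ci]
                s = int(rng.integers(0, chrom_len[c] - cfg.read_length))
                rows.append((c, s, s + cfg.read_length))
            bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            bed = bed.sort_values(["chrom", "start"], kind="stable")
            bed.to_csv(root / f"reads_{line}{marker}.bed", sep="\t",
                       index=False, header=False)

    # ---- conservation tracks ---------------------------------------------
    # the three species sets share a base landscape plus small offsets
    cons_base = {
        chrom: rng.normal(0.5, 0.2, size=len(seq) // _CONS_BLOCK)
        for chrom, seq in chrom_seqs.items()
    }
    cons_cov = {
        chrom: rng.random(len(base)) >= 0.10 for chrom, base in cons_base.items()
    }
    for sp_i, sp in enumerate(("vertebrate", "primate", "placental")):
        with open(root / f"conservation_{sp}.bedgraph", "w") as fh:
            for chrom, base in cons_base.items():
                offs = 0.0 if sp_i == 0 else rng.normal(0, 0.05, size=len(base))
                vals = np.clip(base + offs, 0.0, 1.0)
                for b in np.nonzero(cons_cov[chrom])[0]:
                    fh.write(
                        f"{chrom}\t{b * _CONS_BLOCK}\t{(b + 1) * _CONS_BLOCK}"
                        f"\t{vals[b]:.4f}\n"
                    )

    # ---- DE table ---------------------------------------------------------
    de_rows = []
    for t in transcripts:
        lab = label_of.get(t.gene_id)
        base_b = float(np.exp(rng.normal(5.0, 1.0)))
        if lab is None:
            lfc = float(rng.normal(0.0, 0.3))
            p = float(rng.uniform(0.05, 1.0))
            if rng.random() < 0.05:
                base_b = 0.0
        else:
            mag = cfg.lfc_base + float(rng.exponential(cfg.lfc_scale))
            lfc = mag if lab == "up" else -mag
            p = float(10 ** (-rng.uniform(6.0, 10.0)))
        mean_a = base_b * (2.0**lfc)
        de_rows.append(
            (t.transcript_id, t.gene_id, mean_a, base_b, lfc, p)
        )
    de = pd.DataFrame(
        de_rows,
        columns=["transcript_id", "gene_id", "mean_count_A", "mean_count_B",
                 "log2FC", "p_value"],
    )
    de.to_csv(root / "de_table.tsv", sep="\t", index=False, float_format="%.6g")

    with open(root / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(cfg),
                "files": sorted(p.name for p in root.iterdir() if p.is_file()),
            },
            fh,
            indent=1,
        )
    return SyntheticBundle(root, cfg, transcripts, labels)
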