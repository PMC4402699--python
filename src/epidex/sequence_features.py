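"""Nucleotide composition, segment length, and conservation features.

Composition is the fraction of overlapping k-mer windows (k = 1, 2, 3)
over the strand-oriented segment sequence; windows containing an
ambiguous base are excluded from numerator and denominator.  Conservation
features are the arithmetic mean of per-base phastCons-style scores
(in [0, 1]) over the bases of a segment that the track covers, for the
vertebrate / primate / placental species sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .segments import SegmentSet

BASES = "ACGT"
SPECIES_SETS = ("vertebrate", "primate", "placental")

#: canonical k-mer orderings (lexicographic)
KMERS = {
    k: ["".join(p) for p in itertools.product(BASES, repeat=k)] for k in (1, 2, 3)
}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_composition(sequence: str, k: int) -> dict[str, float]:
    """Fractions of the 4**k k-mers over overlapping windows.

    Returns all-NaN fractions when the sequence is shorter than ``k`` or
    no window is free of ambiguous bases.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    kmers = KMERS[k]
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return {m: float("nan") for m in kmers}
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c < 4
        idx = idx * 4 + c
    idx = idx[valid]
    if idx.size == 0:
        return {m: float("nan") for m in kmers}
    counts = np.bincount(idx, minlength=4**k)
    fr = counts / idx.size
    return {m: float(fr[i]) for i, m in enumerate(kmers)}


def segment_sequence(genome, s: SegmentSet, category: str) -> str | None:
    """Strand-oriented sequence of one segment (5'->3' concatenation).

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name to
    sliceable sequence).  Multi-interval segments are concatenated in
    transcript order; minus-strand segments are reverse-complemented.
    """
    intervals = s.segments.get(category)
    if not intervals:
        return None
    chrom = genome[s.chromosome]
    chrom_len = len(chrom)
    parts = []
    for lo, hi in intervals:
        if lo < 0 or hi > chrom_len:
            raise ValueError(
                f"{s.transcript_id}/{category}: interval ({lo},{hi}) outside "
                f"{s.chromosome} (length {chrom_len})"
            )
        parts.append(str(chrom[lo:hi]))
    seq = "".join(parts).upper()
    return reverse_complement(seq) if s.strand == "-" else seq


def segment_nucleotide_features(
    genome, s: SegmentSet, *, with_length: bool = True
) -> dict[str, float]:
    """Mono/di/tri-nucleotide fractions and lengths for every segment.

    The promoter windows (TSS200/TSS1500) have no length feature — their
    lengths are fixed by construction.
    """
    out: dict[str, float] = {}
    for cat in s.segments:
        seq = segment_sequence(genome, s, cat)
        if seq is None:
            continue
        for k in (1, 2, 3):
            out.update({f"{cat}_{m}": v for m, v in kmer_composition(seq, k).items()})
        if with_length and cat not in ("TSS200", "TSS1500"):
            out[f"{cat}_length"] = float(s.length(cat))
    return out


class ConservationTrack:
    """Per-base conservation scores as sorted non-overlapping runs.

    Holds, per chromosome, arrays (starts, ends, values); bases not covered
    by any run have no score and are excluded from means.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.runs = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping conservation runs")
            # prefix sums for O(log) interval means
            lens = (e - s).astype(float)
            self.runs[chrom] = (s, e, v, np.concatenate([[0.0], np.cumsum(v * lens)]),
                                np.concatenate([[0.0], np.cumsum(lens)]))

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="#", dtype={"chrom": str},
        )
        runs = {
            chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=False)
        }
        return cls(runs)

    @classmethod
    def from_wig(cls, path) -> "ConservationTrack":
        """Fixed-step WIG reader (``fixedStep chrom=... start=... step=1``)."""
        chroms: dict[str, list] = {}
        chrom, pos, step, span = None, None, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # WIG is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    chroms.setdefault(chrom, [])
                else:
                    chroms[chrom].append((pos, pos + span, float(line)))
                    pos += step
        runs = {}
        for c, triples in chroms.items():
            a = np.array(triples, dtype=float)
            runs[c] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
        return cls(runs)

    def interval_sums(self, chrom: str, lo: int, hi: int) -> tuple[float, float]:
        """(sum of scores, number of covered bases) over [lo, hi)."""
        if chrom not in self.runs:
            return 0.0, 0.0
        s, e, v, cum_sv, cum_len = self.runs[chrom]
        i = np.searchsorted(e, lo, side="right")
        j = np.searchsorted(s, hi, side="left")
        if i >= j:
            return 0.0, 0.0
        total = cum_sv[j] - cum_sv[i]
        nbase = cum_len[j] - cum_len[i]
        # trim partial overlap at both ends
        left_clip = max(0, lo - s[i])
        right_clip = max(0, e[j - 1] - hi)
        total -= left_clip * v[i] + right_clip * v[j - 1]
        nbase -= left_clip + right_clip
        return float(total), float(nbase)


def segment_conservation(
    track: ConservationTrack, s: SegmentSet, species_set: str
) -> dict[str, float]:
    """Mean per-base conservation per segment for one species set.

    Segments with no covered base are missing.
    """
    if species_set not in SPECIES_SETS:
        raise ValueError(f"unknown species set {species_set!r}")
    out: dict[str, float] = {}
    for cat, intervals in s.segments.items():
        total = nbase = 0.0
        for lo, hi in intervals:
            t, n = track.interval_sums(s.chromosome, max(lo, 0), hi)
            total += t
            nbase += n
        out[f"{cat}_{species_set}"] = total / nbase if nbase > 0 else float("nan")
    return out
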