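"""Transcript models and segment decomposition.

A protein-coding transcript is decomposed into up to 14 named genomic
segment categories: the two Illumina-style promoter windows (TSS200,
TSS1500), the 5'/3' untranslated regions, first/last/body exons and
introns (with ``single_exon`` / ``single_intron`` designations for
transcripts that have only one of either), the coding region (CDS) and
the full transcript (the union of its exons).

Coordinates are 0-based half-open throughout, as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)

#: The 14 segment categories, in canonical (catalog) order.
SEGMENT_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "UTR5",
    "first_exon",
    "first_intron",
    "exon",
    "intron",
    "CDS",
    "last_intron",
    "last_exon",
    "UTR3",
    "fullTranscript",
    "single_exon",
    "single_intron",
)

TSS200_SPAN = 200
TSS1500_SPAN = 1300  # the (200, 1500] upstream window


class AnnotationError(ValueError):
    """A malformed annotation record."""


@dataclass(frozen=True)
class TranscriptModel:
    """One protein-coding transcript's exon structure.

    ``exon_intervals`` are non-overlapping ``(start, end)`` pairs sorted
    by genomic coordinate; ``cds_interval`` is ``None`` for non-coding
    records (BED12 thickStart == thickEnd convention).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exon_intervals: tuple[tuple[int, int], ...]
    cds_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exon_intervals))
        object.__setattr__(self, "exon_intervals", exons)
        for (s, e) in exons:
            if not s < e:
                raise AnnotationError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.cds_interval is not None:
            cs, ce = self.cds_interval
            if not (exons[0][0] <= cs < ce <= exons[-1][1]):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS outside exon span"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_intervals[0][0], self.exon_intervals[-1][1]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1]

    @property
    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        exons = self.exon_intervals
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:]) if s1 > e0
        )


@dataclass
class SegmentSet:
    """The named segments of one transcript: category -> interval list."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def length(self, category: str) -> int | None:
        ivs = self.segments.get(category)
        if not ivs:
            return None
        return sum(e - s for s, e in ivs)


# ---------------------------------------------------------------------------
# annotation readers / writers
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AnnotationError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationError(f"line {lineno}: blockCount mismatch")
    exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
    if exons[-1][1] != end:
        raise AnnotationError(f"line {lineno}: blocks do not reach chromEnd")
    cds = None if thick_start >= thick_end else (thick_start, thick_end)
    gene_id = name.split("|")[0] if "|" in name else name
    tx_id = name.split("|")[1] if "|" in name else name
    return TranscriptModel(tx_id, gene_id, chrom, strand, exons, cds)


def _parse_refflat_line(line: str, lineno: int) -> TranscriptModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 11:
        raise AnnotationError(f"line {lineno}: refFlat needs 11 fields, got {len(f)}")
    try:
        gene_id, tx_id, chrom, strand = f[0], f[1], f[2], f[3]
        cds_start, cds_end = int(f[6]), int(f[7])
        n_exons = int(f[8])
        starts = [int(x) for x in f[9].rstrip(",").split(",")]
        ends = [int(x) for x in f[10].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    if len(starts) != n_exons or len(ends) != n_exons:
        raise AnnotationError(f"line {lineno}: exonCount mismatch")
    exons = tuple(zip(starts, ends))
    cds = None if cds_start >= cds_end else (cds_start, cds_end)
    return TranscriptModel(tx_id, gene_id, chrom, strand, exons, cds)


def read_annotation(path, dialect: str = "refflat") -> list[TranscriptModel]:
    """Read a transcript annotation file.

    ``dialect`` is ``"bed12"`` or ``"refflat"`` (gene, transcript, chrom,
    strand, txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts,
    exonEnds). BED12 names may be ``gene|transcript``.
    """
    parsers = {"bed12": _parse_bed12_line, "refflat": _parse_refflat_line}
    if dialect not in parsers:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    parse = parsers[dialect]
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            out.append(parse(line, lineno))
    return out


def write_refflat(transcripts: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            exons = t.exon_intervals
            cds = t.cds_interval or (t.span[1], t.span[1])
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.transcript_id,
                        t.chromosome,
                        t.strand,
                        str(t.span[0]),
                        str(t.span[1]),
                        str(cds[0]),
                        str(cds[1]),
                        str(len(exons)),
                        ",".join(str(s) for s, _ in exons) + ",",
                        ",".join(str(e) for _, e in exons) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _clip_to_exons(
    exons: Iterable[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Exonic bases within genomic window [lo, hi)."""
    out = []
    for s, e in exons:
        cs, ce = max(s, lo), min(e, hi)
        if cs < ce:
            out.append((cs, ce))
    return out


def segment_transcript(t: TranscriptModel) -> SegmentSet:
    """Decompose a transcript into its named segment categories.

    First/last exons and introns are 5'-most / 3'-most on the transcript
    strand and are removed from the body categories.  A single-exon
    transcript gets ``single_exon`` instead of any exon category; a
    transcript with exactly one intron gets ``single_intron`` instead of
    any intron category.  UTRs are exonic bases outside the CDS,
    strand-aware; they may overlap the first/last exon segments.
    """
    seg: dict[str, list[tuple[int, int]]] = {}
    exons = list(t.exon_intervals)
    introns = list(t.intron_intervals)
    plus = t.strand == "+"

    # promoter windows, upstream of the TSS on the transcript strand
    if plus:
        tss = t.tss
        tss200 = (tss - TSS200_SPAN, tss)
        tss1500 = (tss - TSS200_SPAN - TSS1500_SPAN, tss - TSS200_SPAN)
    else:
        tss = t.tss
        tss200 = (tss, tss + TSS200_SPAN)
        tss1500 = (tss + TSS200_SPAN, tss + TSS200_SPAN + TSS1500_SPAN)
    for name, (s, e) in (("TSS200", tss200), ("TSS1500", tss1500)):
        if s < 0:
            logger.warning(
                "%s: %s window truncated at chromosome start", t.transcript_id, name
            )
            s = max(s, 0)
        if s < e:
            seg[name] = [(s, e)]

    # exon categories
    if len(exons) == 1:
        seg["single_exon"] = [exons[0]]
    else:
        first = exons[0] if plus else exons[-1]
        last = exons[-1] if plus else exons[0]
        seg["first_exon"] = [first]
        seg["last_exon"] = [last]
        body = [e for e in exons if e != first and e != last]
        if body:
            seg["exon"] = body

    # intron categories
    if len(introns) == 1:
        seg["single_intron"] = [introns[0]]
    elif len(introns) >= 2:
        first = introns[0] if plus else introns[-1]
        last = introns[-1] if plus else introns[0]
        seg["first_intron"] = [first]
        seg["last_intron"] = [last]
        body = [i for i in introns if i != first and i != last]
        if body:
            seg["intron"] = body

    seg["fullTranscript"] = exons[:]

    # CDS and UTRs
    if t.cds_interval is not None:
        cs, ce = t.cds_interval
        cds = _clip_to_exons(exons, cs, ce)
        if cds:
            seg["CDS"] = cds
        up = _clip_to_exons(exons, 0, cs)     # genomically left of CDS
        down = _clip_to_exons(exons, ce, 2**62)
        utr5, utr3 = (up, down) if plus else (down, up)
        if utr5:
            seg["UTR5"] = utr5
        if utr3:
            seg["UTR3"] = utr3

    return SegmentSet(t.transcript_id, t.gene_id, t.chromosome, t.strand, seg)


def write_segments_bed(segment_sets: Iterable[SegmentSet], path) -> None:
    """Export segments as BED6 with ``transcript|category`` in the name column."""
    with open(path, "w") as fh:
        for ss in segment_sets:
            for cat in SEGMENT_CATEGORIES:
                for s, e in ss.segments.get(cat, ()):
                    fh.write(
                        f"{ss.chromosome}\t{s}\t{e}\t"
                        f"{ss.transcript_id}|{cat}\t0\t{ss.strand}\n"
                    )
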