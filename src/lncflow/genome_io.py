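"""Annotation and sequence I/O plus the interval algebra used throughout.

Coordinates are 0-based, half-open internally.  GTF (1-based, inclusive)
is converted on read and write.  Transcript *spans* (first exon start to
last exon end) are the unit of every positional comparison downstream:
overlap, gap distance, positional classification and the cis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("known_coding", "known_lncRNA", "assembled")

#: Sentinel for the distance between features on different chromosomes.
INFINITE_GAP = math.inf


class AnnotationParseError(ValueError):
    """A malformed annotation record; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Non-strict containment of ``other``'s bases within self (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on a single chromosome and strand.

    ``category`` distinguishes annotated coding genes, annotated lncRNAs
    and newly assembled transcripts awaiting the discovery cascade.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)
    category: str = "assembled"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.transcript_id}: unknown category {self.category!r}"
            )
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Transcript length: the sum of exon lengths (not the span)."""
        return sum(len(e) for e in self.exons)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Bases strictly between two intervals on one chromosome.

    Overlapping or book-ended intervals have gap 0.  Intervals on
    different chromosomes are infinitely far apart (``INFINITE_GAP``).
    """
    if a.chrom != b.chrom:
        return INFINITE_GAP
    return max(0, max(a.start, b.start) - min(a.end, b.end))


# ---------------------------------------------------------------------------
# GTF / GFF3 reading and writing
# ---------------------------------------------------------------------------

def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return None


def read_annotation(
    path: str | Path,
    category_key: str = "category",
    default_category: str = "assembled",
) -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 file.

    Exon records are grouped by their ``transcript_id`` (GTF) or
    ``Parent``/``ID`` (GFF3) attribute.  The transcript category is read
    from ``category_key`` when present, falling back to
    ``default_category``.  Chromosome names are taken verbatim; no
    reference genome is consulted.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    categories: dict[str, str] = {}
    order: list[str] = []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationParseError(
                    f"{path}: malformed record at line {lineno}: "
                    f"expected 9 tab-separated fields, got {line.count(chr(9)) + 1}"
                )
            try:
                feature = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise AnnotationParseError(
                    f"{path}: malformed record at line {lineno}: {exc}"
                ) from exc
            if feature.featuretype != "exon":
                continue
            tid = _first_attr(feature, "transcript_id", "Parent", "ID")
            if tid is None:
                raise AnnotationParseError(
                    f"{path}: exon without transcript identifier at line {lineno}"
                )
            # GTF is 1-based inclusive; convert to 0-based half-open.
            start, end = feature.start - 1, feature.end
            if end <= start:
                raise AnnotationParseError(
                    f"{path}: exon with end <= start at line {lineno}"
                )
            strand = feature.strand if feature.strand in ("+", "-") else "+"
            try:
                interval = GenomicInterval(feature.seqid, start, end, strand)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: invalid exon at line {lineno}: {exc}"
                ) from exc
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(interval)
            gid = _first_attr(feature, "gene_id") or tid
            genes.setdefault(tid, gid)
            cat = _first_attr(feature, category_key)
            if cat is not None:
                categories.setdefault(tid, cat)

    models = []
    for tid in order:
        cat = categories.get(tid, default_category)
        if cat not in CATEGORIES:
            cat = default_category
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                exons=tuple(exons[tid]),
                category=cat,
            )
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF 2.2 (transcript + exon records)."""
    with open(path, "w") as handle:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'category "{tx.category}";'
            )
            span = tx.span
            handle.write(
                "\t".join(
                    [
                        span.chrom,
                        "lncflow",
                        "transcript",
                        str(span.start + 1),
                        str(span.end),
                        ".",
                        span.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in tx.exons:
                handle.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "lncflow",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; record ids must match transcript ids."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def index_by_chrom(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    """Group transcripts per chromosome, sorted by span start."""
    index: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        index.setdefault(tx.chrom, []).append(tx)
    for chrom in index:
        index[chrom].sort(key=lambda t: (t.span.start, t.span.end, t.transcript_id))
    return index
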