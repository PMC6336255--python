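"""Positional classification of lncRNAs relative to a partner gene.

Each lncRNA is paired with a partner transcript (the gene it overlaps
most, or failing that the nearest gene within a search window) and then
assigned one of six positional classes:

genic (spans share bases)
    ``containing``  — the partner lies inside the lncRNA span,
    ``nested``      — the lncRNA lies inside the partner span,
    ``overlapping`` — partial span overlap;

intergenic (disjoint spans)
    ``same_strand`` — both transcribed in the same direction,
    ``convergent``  — opposite strands transcribing toward the gap,
    ``divergent``   — opposite strands transcribing away from the gap.

Genic subtypes are purely geometric (strand is ignored: an antisense
overlap is still overlapping/containing/nested); exact span equality
classifies as ``containing`` (containment is read non-strictly, with the
tie against ``nested`` resolved deterministically in favour of
``containing``).  All comparisons use transcript spans, not exon unions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import TranscriptModel, gap_distance, index_by_chrom, overlap_bp

GENIC_CLASSES = ("overlapping", "containing", "nested")
INTERGENIC_CLASSES = ("same_strand", "convergent", "divergent")
ALL_CLASSES = GENIC_CLASSES + INTERGENIC_CLASSES
UNCLASSIFIED = "unclassified"

#: Default partner search window: the cis-regulation window (100 kb).
DEFAULT_MAX_GAP = 100_000


@dataclass(frozen=True)
class PartnerAssignment:
    lnc_id: str
    partner_gene_id: str | None
    positional_class: str  # one of ALL_CLASSES or UNCLASSIFIED
    overlap_bp: int
    gap_bp: float  # 0 when overlapping, inf when unclassified


def classify(lnc: TranscriptModel, partner: TranscriptModel) -> str:
    """Assign the six-way positional class for an (lncRNA, partner) pair."""
    a, b = lnc.span, partner.span
    if a.chrom != b.chrom:
        raise ValueError(
            f"{lnc.transcript_id} and {partner.transcript_id} are on "
            "different chromosomes"
        )
    if overlap_bp(a, b) > 0:
        if a.contains(b):
            return "containing"
        if b.contains(a):
            return "nested"
        return "overlapping"
    if a.strand == b.strand:
        return "same_strand"
    # Opposite strands, disjoint spans: orient by genomic position.  The
    # pair is convergent when the left feature is on '+' and the right on
    # '-' (both transcribe toward the gap between them); otherwise the two
    # transcribe away from the gap (divergent).
    left, right = (a, b) if a.start <= b.start else (b, a)
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    return "divergent"


def assign_partner(
    lnc: TranscriptModel,
    genes: Sequence[TranscriptModel] | Mapping[str, Sequence[TranscriptModel]],
    max_gap: float = DEFAULT_MAX_GAP,
) -> PartnerAssignment:
    """Choose the partner gene of an lncRNA and classify the pair.

    The partner is the gene with maximal span overlap; if no gene
    overlaps, the nearest gene within ``max_gap`` bases.  Ties are broken
    by smaller gene start coordinate, then gene id.
    """
    if isinstance(genes, Mapping):
        candidates = genes.get(lnc.chrom, [])
    else:
        candidates = [g for g in genes if g.chrom == lnc.chrom]
    candidates = [g for g in candidates if g.transcript_id != lnc.transcript_id]

    span = lnc.span
    best = None
    best_key = None
    for gene in candidates:
        ov = overlap_bp(span, gene.span)
        gap = gap_distance(span, gene.span)
        if ov > 0:
            key = (0, -ov, gene.span.start, gene.transcript_id)
        elif gap <= max_gap:
            key = (1, gap, gene.span.start, gene.transcript_id)
        else:
            continue
        if best_key is None or key < best_key:
            best, best_key = gene, key

    if best is None:
        return PartnerAssignment(lnc.transcript_id, None, UNCLASSIFIED, 0, math.inf)
    return PartnerAssignment(
        lnc_id=lnc.transcript_id,
        partner_gene_id=best.gene_id,
        positional_class=classify(lnc, best),
        overlap_bp=overlap_bp(span, best.span),
        gap_bp=gap_distance(span, best.span),
    )


def classify_all(
    lncs: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    max_gap: float = DEFAULT_MAX_GAP,
) -> list[PartnerAssignment]:
    index = index_by_chrom(genes)
    return [assign_partner(lnc, index, max_gap=max_gap) for lnc in lncs]


def assignments_to_frame(assignments: Sequence[PartnerAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [a.lnc_id for a in assignments],
            "partner_gene_id": [a.partner_gene_id or "" for a in assignments],
            "class": [a.positional_class for a in assignments],
            "overlap_bp": [a.overlap_bp for a in assignments],
            "gap_bp": [a.gap_bp for a in assignments],
        }
    )


def class_summaries(
    assignments: Sequence[PartnerAssignment],
    lncs: Sequence[TranscriptModel],
    length_bins: Sequence[int] = (0, 500, 1000, 1500, 2000, 3000, 5000, np.inf),
) -> dict[str, pd.DataFrame]:
    """Class composition tables: proportions, class x length bin, per-chrom.

    Only classified lncRNAs contribute.  Proportions sum to 1 and counts
    are conserved (each classified lncRNA appears in exactly one cell).
    """
    by_id = {t.transcript_id: t for t in lncs}
    classified = [a for a in assignments if a.positional_class != UNCLASSIFIED]
    if not classified:
        empty = pd.DataFrame()
        return {"proportions": empty, "length_bins": empty, "per_chrom": empty}

    df = pd.DataFrame(
        {
            "lnc_id": [a.lnc_id for a in classified],
            "class": [a.positional_class for a in classified],
            "length": [by_id[a.lnc_id].length for a in classified],
            "chrom": [by_id[a.lnc_id].chrom for a in classified],
        }
    )
    counts = df["class"].value_counts().reindex(list(ALL_CLASSES), fill_value=0)
    proportions = pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    ).rename_axis("class")

    df["length_bin"] = pd.cut(df["length"], bins=list(length_bins), right=False)
    length_table = (
        df.groupby(["length_bin", "class"], observed=False).size().unstack(fill_value=0)
    )
    chrom_table = (
        df.groupby(["chrom", "class"], observed=False).size().unstack(fill_value=0)
    )
    return {
        "proportions": proportions,
        "length_bins": length_table,
        "per_chrom": chrom_table,
    }
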