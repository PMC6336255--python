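"""Novel-lncRNA discovery: the five-step filtering cascade and transcript
characterization (length, exon count, longest ORF).

Assembled transcripts are screened in a fixed cascade order; a transcript
is a novel lncRNA only if it survives every step, i.e. the survivor set is
the intersection of the per-step pass sets:

0. deduplication of identical transcript structures,
1. transcript length >= 200 bp,
2. read coverage >= 3,
3. no overlap with known coding genes and <= 90% identity to known
   lncRNAs,
4. coding-potential score < 0 and no protein-domain (Pfam-style) hit.

Coding-potential scores, domain hits, read coverage and percent identity
are consumed as an evidence table produced by external scorers; only the
decision logic lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import TranscriptModel

#: Cascade steps in application order, plus the "passed" sentinel.
CASCADE_STEPS = (
    "length",
    "coverage",
    "known_overlap",
    "known_lnc_similarity",
    "coding_potential",
)
PASSED = "none"

EVIDENCE_COLUMNS = (
    "transcript_id",
    "cpc_score",
    "pfam_hit",
    "read_coverage",
    "known_lnc_identity",
    "overlaps_known_coding",
)


@dataclass(frozen=True)
class CodingEvidence:
    """Per-transcript filter inputs from external scorers.

    ``known_lnc_identity`` is a percent in [0, 100] or ``None`` when the
    transcript had no alignment to any known lncRNA.
    """

    transcript_id: str
    cpc_score: float
    pfam_hit: bool
    read_coverage: float
    known_lnc_identity: float | None = None
    overlaps_known_coding: bool = False

    def __post_init__(self) -> None:
        if self.read_coverage < 0:
            raise ValueError(
                f"{self.transcript_id}: read coverage must be >= 0, "
                f"got {self.read_coverage}"
            )
        ident = self.known_lnc_identity
        if ident is not None and not (0.0 <= ident <= 100.0):
            raise ValueError(
                f"{self.transcript_id}: identity must be a percent in [0, 100]"
            )


@dataclass(frozen=True)
class FilterOutcome:
    transcript_id: str
    passed: bool
    failed_step: str  # first violated cascade step, or "none"


def deduplicate_transcripts(
    transcripts: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Collapse transcripts with identical chrom, strand and exon coordinates.

    The first-seen transcript id is kept per structure.
    """
    seen: set[tuple] = set()
    unique = []
    for tx in transcripts:
        key = (tx.chrom, tx.strand, tuple((e.start, e.end) for e in tx.exons))
        if key in seen:
            continue
        seen.add(key)
        unique.append(tx)
    return unique


def _first_failed_step(
    tx: TranscriptModel,
    ev: CodingEvidence,
    min_length: int,
    min_coverage: float,
    max_known_identity: float,
    cpc_cutoff: float,
) -> str:
    # Boundary semantics follow the printed inequalities literally:
    # length exactly `min_length` is kept ("shorter than" removed),
    # coverage exactly `min_coverage` is kept (">= selected"),
    # identity exactly `max_known_identity` is kept (strictly greater removed),
    # cpc_score exactly `cpc_cutoff` is removed (strictly negative kept).
    if tx.length < min_length:
        return "length"
    if ev.read_coverage < min_coverage:
        return "coverage"
    if ev.overlaps_known_coding:
        return "known_overlap"
    if ev.known_lnc_identity is not None and ev.known_lnc_identity > max_known_identity:
        return "known_lnc_similarity"
    if ev.cpc_score >= cpc_cutoff or ev.pfam_hit:
        return "coding_potential"
    return PASSED


def run_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    evidence: Iterable[CodingEvidence] | Mapping[str, CodingEvidence],
    min_length: int = 200,
    min_coverage: float = 3.0,
    max_known_identity: float = 90.0,
    cpc_cutoff: float = 0.0,
) -> list[FilterOutcome]:
    """Apply the discovery cascade; attribute each failure to its first step.

    Every transcript must have exactly one evidence record; a missing
    record is an error naming the transcript.
    """
    if isinstance(evidence, Mapping):
        ev_map = dict(evidence)
    else:
        ev_map = {}
        for ev in evidence:
            if ev.transcript_id in ev_map:
                raise ValueError(f"duplicate evidence for {ev.transcript_id}")
            ev_map[ev.transcript_id] = ev

    outcomes = []
    for tx in transcripts:
        ev = ev_map.get(tx.transcript_id)
        if ev is None:
            raise KeyError(f"no coding evidence for transcript {tx.transcript_id}")
        step = _first_failed_step(
            tx, ev, min_length, min_coverage, max_known_identity, cpc_cutoff
        )
        outcomes.append(
            FilterOutcome(tx.transcript_id, passed=(step == PASSED), failed_step=step)
        )
    return outcomes


def read_evidence(path) -> dict[str, CodingEvidence]:
    """Read the evidence TSV (see :data:`EVIDENCE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    records = {}
    for row in df.itertuples(index=False):
        ident = row.known_lnc_identity
        if ident is None or (isinstance(ident, float) and math.isnan(ident)):
            ident = None
        records[row.transcript_id] = CodingEvidence(
            transcript_id=row.transcript_id,
            cpc_score=float(row.cpc_score),
            pfam_hit=bool(row.pfam_hit),
            read_coverage=float(row.read_coverage),
            known_lnc_identity=ident,
            overlaps_known_coding=bool(row.overlaps_known_coding),
        )
    return records


def write_evidence(records: Iterable[CodingEvidence], path) -> None:
    rows = [
        {
            "transcript_id": ev.transcript_id,
            "cpc_score": ev.cpc_score,
            "pfam_hit": int(ev.pfam_hit),
            "read_coverage": ev.read_coverage,
            "known_lnc_identity": (
                "" if ev.known_lnc_identity is None else ev.known_lnc_identity
            ),
            "overlaps_known_coding": int(ev.overlaps_known_coding),
        }
        for ev in records
    ]
    pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def outcomes_to_frame(outcomes: Sequence[FilterOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [o.transcript_id for o in outcomes],
            "passed": [int(o.passed) for o in outcomes],
            "failed_step": [o.failed_step for o in outcomes],
        }
    )


# ---------------------------------------------------------------------------
# ORF search and characterization
# ---------------------------------------------------------------------------

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")


def find_longest_orf(sequence: str) -> int:
    """Length (bp, including the stop codon) of the longest complete ORF.

    ORFs are ATG-initiated and in-frame stop-terminated, searched on the
    sense strand only (transcripts from a strand-specific library are
    already oriented).  Returns 0 when no complete ORF exists.
    """
    seq = sequence.upper()
    if set(seq) - _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    best = 0
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if open_start is not None:
                    best = max(best, pos + 3 - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
    return best


def characterize(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-transcript length, exon count and longest-ORF length.

    The ORF column is NaN for transcripts without a sequence; binning for
    histograms is left to the caller.
    """
    rows = []
    for tx in transcripts:
        orf = np.nan
        if sequences is not None and tx.transcript_id in sequences:
            orf = find_longest_orf(sequences[tx.transcript_id])
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "length": tx.length,
                "n_exons": len(tx.exons),
                "orf_length": orf,
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "length", "n_exons", "orf_length"]
    )
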