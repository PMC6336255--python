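"""Cis-target prediction for DE lncRNAs and hypergeometric term enrichment.

A gene is a cis-target candidate of an lncRNA when both are
differentially expressed, their transcript spans overlap or lie within a
100-kb window of each other, and their expression profiles correlate
(two-sided Pearson p < 0.01 across all samples).

Term enrichment of a DE gene set against a background uses the exact
hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

with N background genes, n DE genes, M genes annotated to the term and m
DE genes among them.  The sum is evaluated in exact integer arithmetic
for small backgrounds, with a log-space survival-function fallback for
large N; BH adjustment across terms yields the reported Q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .genome_io import TranscriptModel, gap_distance, overlap_bp

#: Largest background size for which the tail is summed in exact integers.
EXACT_N_LIMIT = 500


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-based p-value.

    Requires equal-length vectors of at least 3 points; constant vectors
    have no defined correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class CisCandidate:
    lnc_id: str
    gene_id: str
    r: float
    p: float
    relation: str  # "overlap" | "within_window"
    gap_bp: int


def predict_cis_targets(
    de_lnc: Collection[str],
    de_genes: Collection[str],
    expr: pd.DataFrame,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    window: int = 100_000,
    alpha: float = 0.01,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Emit (lncRNA, gene) cis pairs passing proximity and co-expression.

    ``expr`` is an RPKM matrix indexed by feature id; ``transcripts``
    supplies the genomic spans.  Features with constant expression are
    skipped (their correlation is undefined).
    """
    if isinstance(transcripts, Mapping):
        by_id = dict(transcripts)
    else:
        by_id = {t.transcript_id: t for t in transcripts}

    rows = []
    for lnc_id in sorted(de_lnc):
        lnc = by_id.get(lnc_id)
        if lnc is None or lnc_id not in expr.index:
            continue
        x = expr.loc[lnc_id].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        for gene_id in sorted(de_genes):
            if gene_id == lnc_id:
                continue
            gene = by_id.get(gene_id)
            if gene is None or gene_id not in expr.index:
                continue
            if gene.chrom != lnc.chrom:
                continue
            ov = overlap_bp(lnc.span, gene.span)
            gap = gap_distance(lnc.span, gene.span)
            if ov == 0 and gap > window:
                continue
            y = expr.loc[gene_id].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            r, p = pearson_with_p(x, y)
            if p >= alpha or (positive_only and r <= 0):
                continue
            rows.append(
                {
                    "lnc_id": lnc_id,
                    "gene_id": gene_id,
                    "r": r,
                    "p": p,
                    "relation": "overlap" if ov > 0 else "within_window",
                    "gap_bp": 0 if ov > 0 else int(gap),
                }
            )
    return pd.DataFrame(
        rows, columns=["lnc_id", "gene_id", "r", "p", "relation", "gap_bp"]
    )


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X hypergeometric(N, M, n), via the complement sum.

    Exact integer arithmetic up to ``EXACT_N_LIMIT`` background genes;
    beyond that the SciPy survival function (log-space stable) is used.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N; got N={N}, M={M}, n={n}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"require 0 <= m <= min(n, M); got m={m}")
    if m == 0:
        return 1.0
    if N <= EXACT_N_LIMIT:
        denom = math.comb(N, n)
        below = sum(math.comb(M, i) * math.comb(N - M, n - i) for i in range(m))
        return float((denom - below) / denom)
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def enrich(
    term_map: pd.DataFrame,
    de_set: Collection[str],
    background: Collection[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a DE gene set per annotation term.

    ``term_map`` needs columns ``gene_id`` and ``term_id`` (optionally
    ``term_name`` and ``namespace``).  Genes outside the background are
    ignored; the DE set must be a subset of the background.  Output rows
    are sorted by P then term id, with BH Q-values across terms.
    """
    background = set(background)
    de_set = set(de_set)
    if not de_set <= background:
        extra = sorted(de_set - background)[:5]
        raise ValueError(f"DE genes outside the background: {extra}")
    required = {"gene_id", "term_id"}
    if not required <= set(term_map.columns):
        raise ValueError(f"term_map needs columns {sorted(required)}")

    term_map = term_map[term_map["gene_id"].isin(background)]
    N, n = len(background), len(de_set)
    names = (
        term_map.drop_duplicates("term_id").set_index("term_id")
        if "term_name" in term_map.columns
        else None
    )

    rows = []
    for term_id, group in term_map.groupby("term_id"):
        genes = set(group["gene_id"])
        M = len(genes)
        m = len(genes & de_set)
        rows.append(
            {
                "term_id": term_id,
                "term_name": (
                    names.loc[term_id, "term_name"] if names is not None else ""
                ),
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "P": hypergeom_tail(N, M, n, m),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "n", "M", "m", "P"]
    )
    if len(result):
        result["q"] = bh_adjust(result["P"].to_numpy())
        result = result.sort_values(["P", "term_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        result["q"] = []
    return result
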