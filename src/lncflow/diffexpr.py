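"""Differential-expression screening between tissue pairs.

The screen reproduced here is the joint rule: fold change >= 2 and
BH-adjusted Q-value <= 0.01.  The test statistic is pluggable; the
default ``pooled_z`` statistic pools replicate counts per tissue and
tests the split of the pooled total against the library-size expectation
with a two-sided normal approximation (the classic MA-plot-style test for
count data, which models counting noise as Poisson and is therefore
anti-conservative under strong biological overdispersion).  An exact
binomial alternative (``binomial_exact``) is provided.

Fold changes are computed on library-size-normalized counts (counts per
million) with a pseudo-count of one normalized count, so features with
zeros have finite, shrunk log-ratios.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .expression import tissue_groups

METHODS = ("pooled_z", "binomial_exact")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_label(tissue_a: str, tissue_b: str) -> str:
    return f"{tissue_a}-vs-{tissue_b}"


def de_test(
    counts: pd.DataFrame,
    contrast: tuple[str, str],
    method: str = "pooled_z",
    pseudo: float = 1.0,
    min_fold_change: float = 2.0,
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Screen all features for differential expression between two tissues.

    Returns one row per feature with ``log2fc`` (tissue A over tissue B),
    ``pvalue``, BH ``qvalue``, ``direction`` (up/down/none relative to A)
    and the joint ``significant`` verdict
    (|log2fc| >= log2(min_fold_change) and qvalue <= q_cutoff).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; available: {METHODS}")
    tissue_a, tissue_b = contrast
    groups = tissue_groups(counts.columns)
    for tissue in contrast:
        if tissue not in groups or not groups[tissue]:
            raise ValueError(f"no samples for tissue {tissue!r}")
    cols_a, cols_b = groups[tissue_a], groups[tissue_b]

    lib = counts.sum(axis=0).astype(float)
    cpm = 1e6 * counts.div(lib, axis=1)
    mean_a = cpm[cols_a].mean(axis=1).to_numpy()
    mean_b = cpm[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))

    k_a = counts[cols_a].sum(axis=1).to_numpy(dtype=float)
    k_b = counts[cols_b].sum(axis=1).to_numpy(dtype=float)
    n_a, n_b = lib[cols_a].sum(), lib[cols_b].sum()
    p0 = n_a / (n_a + n_b)
    total = k_a + k_b

    if method == "pooled_z":
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(total * p0 * (1.0 - p0))
            z = np.where(total > 0, (k_a - total * p0) / np.where(se > 0, se, 1.0), 0.0)
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
        pvalue = np.where(total > 0, np.minimum(pvalue, 1.0), 1.0)
    else:  # binomial_exact
        pvalue = np.array(
            [
                stats.binomtest(int(ka), int(t), p0).pvalue if t > 0 else 1.0
                for ka, t in zip(k_a.astype(int), total.astype(int))
            ]
        )

    qvalue = bh_adjust(pvalue)
    fc_floor = np.log2(min_fold_change)
    significant = (np.abs(log2fc) >= fc_floor) & (qvalue <= q_cutoff)
    direction = np.where(
        significant & (log2fc > 0), "up", np.where(significant, "down", "none")
    )
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "contrast": contrast_label(tissue_a, tissue_b),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "qvalue": qvalue,
            "direction": direction,
            "significant": significant,
        }
    ).reset_index(drop=True)


def de_all_contrasts(
    counts: pd.DataFrame,
    tissues: Sequence[str],
    **kwargs,
) -> pd.DataFrame:
    """Concatenated DE results for every ordered tissue pair (A before B)."""
    frames = [
        de_test(counts, (a, b), **kwargs)
        for i, a in enumerate(tissues)
        for b in tissues[i + 1 :]
    ]
    return pd.concat(frames, ignore_index=True)


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distances; rows with zero variance get
    distance 1 to everything (correlation there is undefined)."""
    x = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    corr = (x @ x.T) / np.outer(safe, safe)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of matrix rows for heatmap ordering.

    Returns the leaf order (row labels) and the SciPy linkage matrix.
    ``distance`` is ``correlation`` (1 - Pearson across samples, with
    constant rows at distance 1) or ``euclidean``.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    values = matrix.to_numpy(dtype=float)
    if distance == "correlation":
        dist = squareform(_correlation_distance(values), checks=False)
    elif distance == "euclidean":
        dist = squareform(
            np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(-1)),
            checks=False,
        )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    tree = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(tree)
    return [matrix.index[i] for i in order], tree
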