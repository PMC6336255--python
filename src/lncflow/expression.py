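"""RPKM quantification, the low-expression filter, and tissue presence sets.

Count and RPKM matrices are plain pandas DataFrames with feature ids as
the index and sample columns named ``<tissue>_<replicate>`` (for example
``flower_1``).  RPKM for feature A in one sample is

    RPKM(A) = 1e9 * C / (N * L)

with C the reads assigned to A, N the sample's total assigned reads
(column sum) and L the feature length in bases.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

DEFAULT_TISSUES = ("flower", "leaf", "root")


def sample_tissue(sample: str) -> str:
    """Tissue label of a ``<tissue>_<replicate>`` sample column name."""
    tissue, _, rep = sample.rpartition("_")
    if not tissue or not rep.isdigit():
        raise ValueError(
            f"sample name {sample!r} is not of the form '<tissue>_<replicate>'"
        )
    return tissue


def tissue_groups(columns: Iterable[str]) -> dict[str, list[str]]:
    """Map tissue -> sample columns, preserving column order."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        groups.setdefault(sample_tissue(col), []).append(col)
    return groups


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads-per-kilobase-per-million matrix from raw counts.

    ``lengths`` gives per-feature transcript length in bases; every
    feature needs a positive length and every sample a positive total.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for features: {list(missing[:5])}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()[:5]
        raise ValueError(f"non-positive feature lengths: {bad}")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total count in samples {bad}: RPKM undefined")
    return 1e9 * counts.div(totals, axis=1).div(lengths, axis=0)


def expressed_sets(
    rpkm: pd.DataFrame,
    threshold: float = 1.0,
    agg: str = "mean",
) -> dict[str, set[str]]:
    """Features expressed per tissue: replicate-aggregate RPKM >= threshold.

    The aggregate across a tissue's replicates is the mean by default
    (``agg='max'`` calls a feature expressed if any replicate reaches the
    threshold).  The threshold is inclusive.
    """
    if agg not in ("mean", "max"):
        raise ValueError(f"agg must be 'mean' or 'max', got {agg!r}")
    sets: dict[str, set[str]] = {}
    for tissue, cols in tissue_groups(rpkm.columns).items():
        summary = rpkm[cols].mean(axis=1) if agg == "mean" else rpkm[cols].max(axis=1)
        sets[tissue] = set(summary.index[summary >= threshold])
    return sets


def venn_partition(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Disjoint Venn regions of 2-4 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection
    the region is; with three tissues there are 7 non-empty signatures.
    Single-name regions are the tissue-specific feature lists.
    """
    names = sorted(sets)
    if not (2 <= len(names) <= 4):
        raise ValueError(f"venn_partition supports 2-4 sets, got {len(names)}")
    regions: dict[tuple[str, ...], set[str]] = {}
    universe = set().union(*sets.values())
    for feature in universe:
        signature = tuple(n for n in names if feature in sets[n])
        regions.setdefault(signature, set()).add(feature)
    return regions


def venn_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    regions = venn_partition(sets)
    rows = [
        {"region": "&".join(sig), "n": len(members)}
        for sig, members in sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "n"])


def tissue_specific(sets: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Features expressed in exactly one tissue."""
    regions = venn_partition(sets)
    return {name: regions.get((name,), set()) for name in sorted(sets)}
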