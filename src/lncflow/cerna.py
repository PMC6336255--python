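"""Competing-endogenous-RNA (ceRNA) network construction.

A candidate triplet is an (lncRNA, miRNA, mRNA) trio in which the miRNA
has a predicted binding site (MRE) on both the lncRNA and the mRNA.  A
candidate is accepted when the expression trends are consistent with
sponging in at least one tissue contrast: the lncRNA is differentially
expressed there, the mRNA moves in the same direction, and the miRNA
moves in the opposite direction.  Requiring the opposite miRNA trend
removes shared-MRE false positives whose expression does not behave like
a sponge.

Trend profiles are signed per-contrast vectors derived from the DE
screen: +1/-1 where the feature is significantly up/down, 0 elsewhere.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ("mirna_id", "target_id", "target_type", "source", "score")


def build_trends(de: pd.DataFrame, contrasts: Sequence[str] | None = None) -> pd.DataFrame:
    """Signed per-contrast trend profiles from a DE result table.

    ``de`` holds rows for every feature in every contrast (columns
    ``feature_id``, ``contrast``, ``log2fc``, ``significant``).  The sign
    is that of the fold change where significant, else 0.  Every feature
    must be tested in every requested contrast.
    """
    if contrasts is None:
        contrasts = sorted(de["contrast"].unique())
    sign = de["significant"].astype(int) * de["log2fc"].apply(
        lambda v: 1 if v > 0 else (-1 if v < 0 else 0)
    )
    table = (
        de.assign(sign=sign)
        .pivot_table(index="feature_id", columns="contrast", values="sign", dropna=False)
        .reindex(columns=list(contrasts))
    )
    if table.isna().any().any():
        missing = table.columns[table.isna().any()].tolist()
        raise ValueError(f"features missing DE results for contrasts: {missing}")
    return table.astype(int)


def build_cerna_network(
    lnc_targets: pd.DataFrame,
    mrna_targets: pd.DataFrame,
    trends: pd.DataFrame,
    mode: str = "any",
    combine: str = "union",
) -> pd.DataFrame:
    """Enumerate shared-miRNA triplets and apply the trend-consistency rule.

    ``lnc_targets`` / ``mrna_targets`` are miRNA-target tables (columns
    ``mirna_id``, ``target_id``; multiple predictor ``source`` rows are
    combined by union or intersection).  ``trends`` is the per-contrast
    sign table from :func:`build_trends`, covering lncRNAs, mRNAs and
    miRNAs; targets without a trend profile are skipped (counted in the
    log).

    ``mode='any'`` accepts a triplet when at least one contrast
    qualifies; ``mode='strict'`` requires every contrast where the lncRNA
    is DE to qualify.
    """
    if mode not in ("any", "strict"):
        raise ValueError(f"mode must be 'any' or 'strict', got {mode!r}")
    if combine not in ("union", "intersect"):
        raise ValueError(f"combine must be 'union' or 'intersect', got {combine!r}")

    def pairs(table: pd.DataFrame) -> set[tuple[str, str]]:
        if combine == "union" or "source" not in table.columns:
            return set(zip(table["mirna_id"], table["target_id"]))
        by_source = [
            set(zip(g["mirna_id"], g["target_id"]))
            for _, g in table.groupby("source")
        ]
        return set.intersection(*by_source) if by_source else set()

    lnc_pairs = pairs(lnc_targets)
    mrna_pairs = pairs(mrna_targets)

    known = set(trends.index)
    skipped = {
        f
        for pair_set in (lnc_pairs, mrna_pairs)
        for pair in pair_set
        for f in pair
        if f not in known
    }
    if skipped:
        logger.info("ceRNA: %d features lack trend profiles; skipped", len(skipped))

    lnc_by_mir: dict[str, list[str]] = {}
    for mir, lnc in sorted(lnc_pairs):
        if mir in known and lnc in known:
            lnc_by_mir.setdefault(mir, []).append(lnc)
    mrna_by_mir: dict[str, list[str]] = {}
    for mir, mrna in sorted(mrna_pairs):
        if mir in known and mrna in known:
            mrna_by_mir.setdefault(mir, []).append(mrna)

    contrasts = list(trends.columns)
    rows = []
    for mir in sorted(set(lnc_by_mir) & set(mrna_by_mir)):
        mir_sign = trends.loc[mir]
        for lnc in lnc_by_mir[mir]:
            lnc_sign = trends.loc[lnc]
            for mrna in mrna_by_mir[mir]:
                mrna_sign = trends.loc[mrna]
                qualifying = [
                    c
                    for c in contrasts
                    if lnc_sign[c] != 0
                    and lnc_sign[c] == mrna_sign[c]
                    and mir_sign[c] == -lnc_sign[c]
                ]
                lnc_de = [c for c in contrasts if lnc_sign[c] != 0]
                if mode == "any":
                    accepted = len(qualifying) > 0
                else:
                    accepted = bool(lnc_de) and len(qualifying) == len(lnc_de)
                rows.append(
                    {
                        "lnc_id": lnc,
                        "mirna_id": mir,
                        "mrna_id": mrna,
                        "shared_contrasts": ";".join(qualifying),
                        "accepted": accepted,
                    }
                )
    return pd.DataFrame(
        rows, columns=["lnc_id", "mirna_id", "mrna_id", "shared_contrasts", "accepted"]
    )


def export_network(
    triplets: pd.DataFrame,
    sif_path: str | Path,
    nodes_path: str | Path,
) -> None:
    """Write the accepted network as SIF plus a node-attribute table.

    Each accepted triplet contributes a miRNA->lncRNA and a miRNA->mRNA
    ``targets`` edge; edges are deduplicated and both files are sorted,
    so re-export is byte-identical.
    """
    accepted = triplets[triplets["accepted"]] if len(triplets) else triplets
    edges: set[tuple[str, str]] = set()
    nodes: dict[str, str] = {}
    for row in accepted.itertuples(index=False):
        edges.add((row.mirna_id, row.lnc_id))
        edges.add((row.mirna_id, row.mrna_id))
        nodes[row.lnc_id] = "lncRNA"
        nodes[row.mirna_id] = "miRNA"
        nodes[row.mrna_id] = "mRNA"
    with open(sif_path, "w") as handle:
        for source, target in sorted(edges):
            handle.write(f"{source}\ttargets\t{target}\n")
    with open(nodes_path, "w") as handle:
        handle.write("id\ttype\n")
        for node, kind in sorted(nodes.items()):
            handle.write(f"{node}\t{kind}\n")
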