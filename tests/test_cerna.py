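"""ceRNA trend profiles, network construction and SIF export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncflow.cerna import build_cerna_network, build_trends, export_network

CONTRASTS = ["flower-vs-leaf", "flower-vs-root", "leaf-vs-root"]


def de_frame(rows):
    """rows: {feature: [sign per contrast]}; sign !=0 implies significant."""
    records = []
    for feature, signs in rows.items():
        for contrast, sign in zip(CONTRASTS, signs):
            records.append(
                {
                    "feature_id": feature,
                    "contrast": contrast,
                    "log2fc": 2.0 * sign if sign else 0.1,
                    "significant": bool(sign),
                }
            )
    return pd.DataFrame(records)


def trends_of(rows):
    return build_trends(de_frame(rows), CONTRASTS)


def targets(pairs, target_type):
    return pd.DataFrame(
        [
            {
                "mirna_id": mir,
                "target_id": tgt,
                "target_type": target_type,
                "source": "pred",
                "score": 150.0,
            }
            for mir, tgt in pairs
        ]
    )


def test_build_trends_signs():
    trends = trends_of(
        {"up2": [1, 1, 0], "flat": [0, 0, 0], "down": [-1, 0, 1]}
    )
    assert trends.loc["up2"].tolist() == [1, 1, 0]
    assert trends.loc["flat"].tolist() == [0, 0, 0]
    assert trends.loc["down"].tolist() == [-1, 0, 1]


def test_build_trends_missing_contrast_errors():
    de = de_frame({"a": [1, 1, 0]})
    de = de[de["contrast"] != "leaf-vs-root"]
    with pytest.raises(ValueError, match="leaf-vs-root"):
        build_trends(de, CONTRASTS)


def test_triplet_accepted_on_opposite_mirna_trend():
    trends = trends_of(
        {"lnc": [1, 1, 0], "mrna": [1, 1, 0], "mir": [-1, -1, 0]}
    )
    out = build_cerna_network(
        targets([("mir", "lnc")], "lncRNA"), targets([("mir", "mrna")], "mRNA"), trends
    )
    assert len(out) == 1 and bool(out.iloc[0]["accepted"])
    assert out.iloc[0]["shared_contrasts"] == "flower-vs-leaf;flower-vs-root"


def test_triplet_rejected_on_concordant_mirna_trend():
    trends = trends_of({"lnc": [1, 1, 0], "mrna": [1, 1, 0], "mir": [1, 1, 0]})
    out = build_cerna_network(
        targets([("mir", "lnc")], "lncRNA"), targets([("mir", "mrna")], "mRNA"), trends
    )
    assert len(out) == 1 and not bool(out.iloc[0]["accepted"])


def test_no_shared_mirna_no_triplet():
    trends = trends_of({"lnc": [1, 0, 0], "mrna": [1, 0, 0],
                        "mirA": [-1, 0, 0], "mirB": [-1, 0, 0]})
    out = build_cerna_network(
        targets([("mirA", "lnc")], "lncRNA"),
        targets([("mirB", "mrna")], "mRNA"),
        trends,
    )
    assert out.empty


def test_strict_mode_requires_all_lnc_de_contrasts():
    # lncRNA DE in two contrasts, miRNA opposite in only one
    trends = trends_of({"lnc": [1, 1, 0], "mrna": [1, 1, 0], "mir": [-1, 0, 0]})
    lt, mt = targets([("mir", "lnc")], "lncRNA"), targets([("mir", "mrna")], "mRNA")
    assert bool(build_cerna_network(lt, mt, trends, mode="any").iloc[0]["accepted"])
    assert not bool(
        build_cerna_network(lt, mt, trends, mode="strict").iloc[0]["accepted"]
    )


def brute_force_triplets(lnc_pairs, mrna_pairs, trends):
    accepted = set()
    mirs = {m for m, _ in lnc_pairs} | {m for m, _ in mrna_pairs}
    lncs = {l for _, l in lnc_pairs}
    mrnas = {m for _, m in mrna_pairs}
    for mir, lnc, mrna in itertools.product(sorted(mirs), sorted(lncs), sorted(mrnas)):
        if (mir, lnc) not in lnc_pairs or (mir, mrna) not in mrna_pairs:
            continue
        for c in trends.columns:
            ls, ms, gs = trends.at[lnc, c], trends.at[mir, c], trends.at[mrna, c]
            if ls != 0 and ls == gs and ms == -ls:
                accepted.add((lnc, mir, mrna))
                break
    return accepted


def test_network_equals_brute_force_enumeration():
    rng = np.random.default_rng(23)
    for _ in range(20):
        lncs = [f"l{i}" for i in range(5)]
        mrnas = [f"g{i}" for i in range(5)]
        mirs = [f"m{i}" for i in range(3)]
        features = lncs + mrnas + mirs
        trends = trends_of(
            {f: list(rng.integers(-1, 2, size=3)) for f in features}
        )
        lnc_pairs = {
            (m, l) for m in mirs for l in lncs if rng.random() < 0.5
        }
        mrna_pairs = {
            (m, g) for m in mirs for g in mrnas if rng.random() < 0.5
        }
        out = build_cerna_network(
            targets(sorted(lnc_pairs), "lncRNA"),
            targets(sorted(mrna_pairs), "mRNA"),
            trends,
        )
        got = {
            (r.lnc_id, r.mirna_id, r.mrna_id)
            for r in out.itertuples()
            if r.accepted
        }
        assert got == brute_force_triplets(lnc_pairs, mrna_pairs, trends)


def test_global_sign_flip_leaves_accepted_set_unchanged():
    rng = np.random.default_rng(29)
    features = [f"l{i}" for i in range(4)] + [f"g{i}" for i in range(4)] + ["m0", "m1"]
    signs = {f: list(rng.integers(-1, 2, size=3)) for f in features}
    flipped = {f: [-s for s in v] for f, v in signs.items()}
    lt = targets([("m0", "l0"), ("m1", "l1"), ("m0", "l2")], "lncRNA")
    mt = targets([("m0", "g0"), ("m1", "g1"), ("m0", "g3")], "mRNA")
    a = build_cerna_network(lt, mt, trends_of(signs))
    b = build_cerna_network(lt, mt, trends_of(flipped))
    key = ["lnc_id", "mirna_id", "mrna_id", "accepted"]
    pd.testing.assert_frame_equal(a[key], b[key])


def test_targets_without_trend_profile_are_skipped():
    trends = trends_of({"lnc": [1, 0, 0], "mrna": [1, 0, 0], "mir": [-1, 0, 0]})
    lt = targets([("mir", "lnc"), ("mir", "lnc_unknown")], "lncRNA")
    mt = targets([("mir", "mrna")], "mRNA")
    out = build_cerna_network(lt, mt, trends)
    assert set(out["lnc_id"]) == {"lnc"}


def test_intersect_combine_mode():
    trends = trends_of(
        {"lncA": [1, 0, 0], "lncB": [1, 0, 0], "mrna": [1, 0, 0], "mir": [-1, 0, 0]}
    )
    # lncA supported by both predictors, lncB by only one
    lt = pd.concat(
        [
            targets([("mir", "lncA"), ("mir", "lncB")], "lncRNA"),
            targets([("mir", "lncA")], "lncRNA").assign(source="other"),
        ],
        ignore_index=True,
    )
    mt = targets([("mir", "mrna")], "mRNA")
    union = build_cerna_network(lt, mt, trends, combine="union")
    strict = build_cerna_network(lt, mt, trends, combine="intersect")
    assert set(union["lnc_id"]) == {"lncA", "lncB"}
    assert set(strict["lnc_id"]) == {"lncA"}


def test_export_network_dedup_and_determinism(tmp_path):
    triplets = pd.DataFrame(
        [
            {"lnc_id": "l1", "mirna_id": "m1", "mrna_id": "g1",
             "shared_contrasts": "c", "accepted": True},
            {"lnc_id": "l2", "mirna_id": "m1", "mrna_id": "g1",
             "shared_contrasts": "c", "accepted": True},
            {"lnc_id": "l3", "mirna_id": "m2", "mrna_id": "g2",
             "shared_contrasts": "", "accepted": False},
        ]
    )
    sif, nodes = tmp_path / "n.sif", tmp_path / "n_nodes.tsv"
    export_network(triplets, sif, nodes)
    lines = sif.read_text().splitlines()
    # shared m1->g1 edge written once; rejected triplet absent
    assert lines == sorted(lines)
    assert len(lines) == 3
    assert "m1\ttargets\tg1" in lines
    node_rows = nodes.read_text().splitlines()[1:]
    assert len(node_rows) == 4  # l1, l2, m1, g1
    first = sif.read_bytes()
    export_network(triplets, sif, nodes)
    assert sif.read_bytes() == first
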