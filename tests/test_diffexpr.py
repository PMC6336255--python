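"""DE screen, BH adjustment and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from lncflow.diffexpr import bh_adjust, de_test, hierarchical_cluster


def bh_oracle(p):
    """Definitional step-up: q_(i) = min_{j >= i} p_(j) * n / j, capped."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = min(running, 1.0)
    return q


def test_bh_small_example():
    got = bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(got, [0.03, 0.03, 0.03])


def test_bh_trivial_cases():
    assert np.allclose(bh_adjust([0.2]), [0.2])
    assert np.allclose(bh_adjust([0.5, 0.5, 0.5, 0.5]), 0.5)
    assert bh_adjust([]).size == 0


def test_bh_validation():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([np.nan])


def test_bh_matches_definitional_oracle():
    rng = np.random.default_rng(13)
    for _ in range(2000):
        p = rng.random(rng.integers(1, 9))
        got = bh_adjust(p)
        assert np.allclose(got, bh_oracle(p), atol=1e-12)
        # monotone non-decreasing along the p-ranked list
        order = np.argsort(p, kind="stable")
        assert (np.diff(got[order]) >= -1e-12).all()


def simulate_counts(rng, mu, dispersion, n_reps=3):
    """features x (2 tissues x n_reps) count matrix around per-group means."""
    cols = [f"flower_{i+1}" for i in range(n_reps)] + [
        f"leaf_{i+1}" for i in range(n_reps)
    ]
    mu_mat = np.repeat(mu, n_reps, axis=1)
    if dispersion == 0:
        data = rng.poisson(mu_mat)
    else:
        size = 1.0 / dispersion
        data = rng.negative_binomial(size, size / (size + mu_mat))
    return pd.DataFrame(
        data, index=[f"f{i}" for i in range(len(mu))], columns=cols, dtype=float
    )


def test_de_noiseless_planted_fold_change():
    """Planted 4-fold change with exact counts gives |log2fc| ~ 2 and a
    significant call; identical groups give log2fc 0 and direction none."""
    # the large flat feature anchors the library size so the per-million
    # normalization does not distort the planted ratio
    mu = np.array([[4000.0, 1000.0], [500.0, 500.0], [1e6, 1e6]])
    counts = simulate_counts(np.random.default_rng(0), mu, 0)
    counts.iloc[:, :3] = mu[:, [0]]  # exact means, zero noise
    counts.iloc[:, 3:] = mu[:, [1]]
    res = de_test(counts, ("flower", "leaf")).set_index("feature_id")
    assert res.loc["f0", "log2fc"] == pytest.approx(2.0, abs=0.05)
    assert res.loc["f0", "significant"]
    assert res.loc["f0", "direction"] == "up"
    # f1 is flat; only the small compositional shift of the library sizes
    # (f0's change) moves its normalized ratio off zero
    assert res.loc["f1", "log2fc"] == pytest.approx(0.0, abs=0.01)
    assert res.loc["f1", "direction"] == "none"


def test_de_contrast_swap_negates_log2fc():
    rng = np.random.default_rng(21)
    mu = rng.uniform(100, 2000, size=(50, 2))
    counts = simulate_counts(rng, mu, 0.1)
    fwd = de_test(counts, ("flower", "leaf")).set_index("feature_id")
    rev = de_test(counts, ("leaf", "flower")).set_index("feature_id")
    assert np.allclose(fwd["log2fc"], -rev["log2fc"])
    assert (fwd["significant"] == rev["significant"]).all()
    assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)


def test_de_unknown_method_lists_available():
    counts = simulate_counts(np.random.default_rng(0), np.full((3, 2), 100.0), 0)
    with pytest.raises(ValueError, match="pooled_z"):
        de_test(counts, ("flower", "leaf"), method="degseq")


def test_de_binomial_exact_agrees_with_z_on_large_counts():
    rng = np.random.default_rng(4)
    mu = rng.uniform(500, 2000, size=(20, 2))
    counts = simulate_counts(rng, mu, 0)
    z = de_test(counts, ("flower", "leaf"), method="pooled_z")
    ex = de_test(counts, ("flower", "leaf"), method="binomial_exact")
    # same features called at q<=0.01 in the large-count regime
    assert (z["significant"] == ex["significant"]).all()


def naive_average_linkage_heights(dist):
    """O(n^3) agglomerative average linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a][b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def test_cluster_identical_rows_merge_first():
    m = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
        index=["a", "b", "c"],
    )
    order, tree = hierarchical_cluster(m, distance="euclidean")
    assert set(map(int, tree[0, :2])) == {0, 1}  # a and b first, at height 0
    assert tree[0, 2] == pytest.approx(0.0)
    assert set(order) == {"a", "b", "c"}


def test_cluster_recovers_planted_split():
    m = pd.DataFrame(
        [[10, 10, 0, 0], [11, 9, 0, 0], [0, 0, 10, 10], [0, 0, 9, 11]],
        index=list("abcd"),
        dtype=float,
    )
    order, _ = hierarchical_cluster(m, distance="euclidean")
    pos = {label: i for i, label in enumerate(order)}
    assert abs(pos["a"] - pos["b"]) == 1 and abs(pos["c"] - pos["d"]) == 1


def test_cluster_merge_heights_match_naive_oracle():
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.normal(size=(8, 6)), index=[f"r{i}" for i in range(8)])
    _, tree = hierarchical_cluster(m, distance="euclidean")
    dist = np.sqrt(
        ((m.to_numpy()[:, None, :] - m.to_numpy()[None, :, :]) ** 2).sum(-1)
    )
    assert np.allclose(sorted(tree[:, 2]), naive_average_linkage_heights(dist))


def test_cluster_constant_row_correlation_distance():
    m = pd.DataFrame(
        [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=list("abc")
    )
    order, tree = hierarchical_cluster(m, distance="correlation")
    # the two proportional rows merge at distance ~0; the constant row
    # joins at its defined distance of 1
    assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert tree[1, 2] == pytest.approx(1.0)


def test_cluster_needs_two_rows():
    with pytest.raises(ValueError):
        hierarchical_cluster(pd.DataFrame([[1.0, 2.0]], index=["a"]))
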