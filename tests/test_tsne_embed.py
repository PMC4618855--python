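"""Exact t-SNE: affinity calibration, KL objective, optimizer contracts."""

import numpy as np
import pytest

from phenofence.tsne_embed import (
    Embedding,
    conditional_affinities,
    kl_divergence,
    perplexity_sweep,
    tsne,
)


def brute_force_affinities(X, perplexity, tol=1e-10):
    """Independent reference: per-row bandwidth bisection with explicit loops
    and base-2 entropy."""
    n = len(X)
    D2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(n)] for i in range(n)])
    P = np.zeros((n, n))
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0  # 1 / (2 sigma^2)
        for _ in range(300):
            p = np.array(
                [np.exp(-beta * D2[i, j]) if j != i else 0.0 for j in range(n)]
            )
            p /= p.sum()
            H = -sum(pj * np.log2(pj) for pj in p if pj > 0)
            if abs(2**H - perplexity) < tol:
                break
            if 2**H > perplexity:
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        P[i] = p
    return (P + P.T) / (2 * n)


def brute_force_kl(P, Y):
    n = len(Y)
    num = np.array(
        [[1.0 / (1.0 + np.sum((Y[i] - Y[j]) ** 2)) if i != j else 0.0 for j in range(n)]
         for i in range(n)]
    )
    Q = num / num.sum()
    total = 0.0
    for i in range(n):
        for j in range(n):
            if P[i, j] > 0:
                total += P[i, j] * np.log(P[i, j] / Q[i, j])
    return total


def test_three_equidistant_points_uniform_affinities():
    # with two equidistant neighbors each conditional is uniform, so every
    # achievable perplexity yields p_ij = 1/6 off the diagonal
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    aff = conditional_affinities(X, perplexity=2.0)
    off = aff.P[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1.0 / 6.0, atol=1e-10)
    assert np.allclose(np.diag(aff.P), 0.0)


def test_affinity_normalization_symmetry_and_perplexity(rng):
    X = rng.normal(size=(40, 6))
    for perp in (5.0, 15.0, 30.0):
        aff = conditional_affinities(X, perp)
        assert aff.P.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(aff.P, aff.P.T, atol=1e-12)
        # achieved conditional perplexity within 1e-4 of target per point
        n = len(X)
        D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        for i in range(n):
            beta = 1.0 / (2.0 * aff.sigmas[i] ** 2)
            p = np.exp(-beta * np.delete(D2[i], i))
            p /= p.sum()
            H = -np.sum(p * np.log(p))
            assert np.exp(H) == pytest.approx(perp, abs=1e-4)


def test_affinities_match_brute_force(rng):
    # both bandwidth searches run to near machine precision so the joint
    # affinities are comparable entrywise
    X = rng.normal(size=(12, 4))
    aff = conditional_affinities(X, perplexity=4.0, tol=1e-12, max_iter=300)
    ref = brute_force_affinities(X, perplexity=4.0, tol=1e-12)
    assert np.allclose(aff.P, ref, atol=1e-10)


def test_two_far_groups_concentrate_affinity_mass(rng):
    X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(100, 0.1, (10, 3))])
    aff = conditional_affinities(X, perplexity=5.0)
    within = aff.P[:10, :10].sum() + aff.P[10:, 10:].sum()
    assert within > 0.99


def test_perplexity_bounds():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        conditional_affinities(X, perplexity=10.0)
    with pytest.raises(ValueError):
        conditional_affinities(X, perplexity=1.0)


def test_kl_identity_nonnegativity_and_oracle(rng):
    # Q == P when the map reproduces the input geometry of a Student-t kernel:
    # easiest exact case is P built from Q itself
    Y = rng.normal(size=(6, 2))
    D2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    num = 1.0 / (1.0 + D2)
    np.fill_diagonal(num, 0.0)
    P = num / num.sum()
    assert kl_divergence(P, Y) == pytest.approx(0.0, abs=1e-12)
    # 4-point oracle match and nonnegativity on random instances
    X = rng.normal(size=(4, 3))
    aff = conditional_affinities(X, perplexity=2.0)
    Yr = rng.normal(size=(4, 2))
    assert kl_divergence(aff, Yr) == pytest.approx(brute_force_kl(aff.P, Yr), abs=1e-10)
    assert kl_divergence(aff, Yr) >= 0.0
    with pytest.raises(ValueError):
        kl_divergence(aff, np.full((4, 2), np.nan))


def test_tsne_determinism_and_kl_decrease(rng):
    X = rng.normal(size=(30, 5))
    a = tsne(X, perplexity=10, seed=7, iters=250)
    b = tsne(X, perplexity=10, seed=7, iters=250)
    assert np.array_equal(a.Y, b.Y)  # bit-identical per seed
    assert a.kl_final <= a.kl_initial
    assert np.isfinite(a.Y).all()


def test_tsne_separates_two_blobs(rng):
    """Two 11-D blobs 10 sd apart map to a 2-D layout with perfect 1-NN purity."""
    shift = 10.0 / np.sqrt(11) * np.ones(11)
    X = np.vstack([rng.normal(0, 1, (50, 11)), rng.normal(shift, 1, (50, 11))])
    labels = np.repeat([0, 1], 50)
    emb = tsne(X, perplexity=20, seed=3)
    D = ((emb.Y[:, None] - emb.Y[None, :]) ** 2).sum(-1)
    np.fill_diagonal(D, np.inf)
    purity = (labels[D.argmin(axis=1)] == labels).mean()
    assert purity >= 0.95


def test_kl_decrease_across_seed_sweep(rng):
    # full default iteration budget: the optimizer must end below its start
    X = rng.normal(size=(40, 4))
    for seed in range(10):
        emb = tsne(X, perplexity=10, seed=seed)
        assert emb.kl_final <= emb.kl_initial


def _count_blobs(emb: Embedding) -> int:
    """Tiny stand-in cluster counter: connected components at a distance cut."""
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(emb.Y))
    thresh = 3.0 * np.median(np.sort(D, axis=1)[:, 1])
    ncomp, _ = connected_components(D < thresh, directed=False)
    return ncomp


def test_perplexity_sweep_ties_break_small(rng):
    centers = rng.normal(scale=40, size=(5, 6))
    X = np.vstack([rng.normal(c, 0.5, (20, 6)) for c in centers])
    sweep = perplexity_sweep(
        X, cluster_fn=_count_blobs, values=[5, 10, 15, 20], seed=0, iters=400
    )
    counts = set(sweep.cluster_counts.values())
    if counts == {5}:  # every perplexity resolves all blobs: tie -> smallest
        assert sweep.perplexity == 5
    assert sweep.cluster_counts[sweep.perplexity] == max(sweep.cluster_counts.values())


def test_perplexity_sweep_single_blob_degenerate_tie(rng):
    X = rng.normal(size=(60, 5))
    sweep = perplexity_sweep(X, cluster_fn=lambda e: 1, values=[5, 10, 15], seed=0, iters=50)
    assert sweep.perplexity == 5
    assert set(sweep.cluster_counts.values()) == {1}


def test_sweep_recovers_blob_count_for_some_perplexity():
    """For well-separated 11-D blobs of ~50 points, some perplexity in the
    sweep yields an embedding whose BIC-selected mixture has the true
    component count (9/10 seeds)."""
    from phenofence.gmm_cluster import model_select

    recovered = 0
    for seed in range(10):
        rng = np.random.default_rng(500 + seed)
        centers = rng.normal(scale=8, size=(3, 11))
        X = np.vstack([rng.normal(c, 1, (50, 11)) for c in centers])
        for perp in (5, 15, 25, 35, 45):
            emb = tsne(X, perplexity=perp, seed=seed)
            sel = model_select(emb.Y, G_range=range(1, 7), seed=seed, n_restarts=2)
            if sel.best.G == 3:
                recovered += 1
                break
    assert recovered >= 9
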