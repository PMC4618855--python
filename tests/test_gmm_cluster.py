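"""Constrained-family EM, BIC selection, posteriors and the uncertainty filter."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phenofence.gmm_cluster import (
    FAMILIES,
    FAMILY_DESCRIPTORS,
    assign,
    bic,
    family_contains,
    fit_em,
    model_select,
    n_params,
    sample_family_covariances,
    uncertainty_filter,
)


@pytest.mark.parametrize(
    "family, G, d, expected",
    [
        ("EII", 2, 2, 6),      # 1 weight + 4 means + 1 volume
        ("VVV", 1, 2, 5),      # 2 means + 3 covariance entries
        ("VEI", 3, 2, 12),     # 2 + 6 + (3 volumes + 1 shape)
        ("EEI", 2, 3, 10),     # 1 + 6 + 3
        ("EVI", 2, 3, 12),     # 1 + 6 + (1 + 2*2)
        ("EEE", 2, 3, 13),     # 1 + 6 + 6
        ("EEV", 2, 3, 16),     # 1 + 6 + (2*3 + 2 + 1)
        ("VEV", 2, 3, 17),     # 1 + 6 + (2*3 + 2 + 2)
        ("VVI", 2, 3, 13),     # 1 + 6 + 6
        ("VII", 3, 2, 10),     # 2 + 6 + 2... volumes: 3 -> 2+6+3=11
    ],
)
def test_n_params_enumeration(family, G, d, expected):
    if family == "VII":  # 2 weights + 6 means + 3 volumes
        expected = 11
    assert n_params(family, G, d) == expected


def test_bic_arithmetic():
    class M:  # minimal stand-in
        loglik, n_params, n = 0.0, 0, 10

    assert bic(M(), 10) == 0.0
    M.loglik, M.n_params = -50.0, 4
    b1 = bic(M(), 100)
    M.n_params = 8
    assert b1 - bic(M(), 100) == pytest.approx(4 * np.log(100))


def test_single_gaussian_closed_form(rng):
    """G=1 fits reduce to the family-constrained MLE of one Gaussian."""
    X = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
    n = len(X)
    S = (X - X.mean(0)).T @ (X - X.mean(0)) / n
    for family, expected_cov in [
        ("VVV", S),
        ("EII", np.trace(S) / 2 * np.eye(2)),
        ("VVI", np.diag(np.diag(S))),
    ]:
        m = fit_em(X, 1, family, seed=0)
        assert np.allclose(m.means[0], X.mean(0), atol=1e-8)
        assert np.allclose(m.covariances[0], expected_cov, atol=1e-6)
        ll = multivariate_normal.logpdf(X, m.means[0], m.covariances[0]).sum()
        assert m.loglik == pytest.approx(ll, rel=1e-9)
    # at d=1-equivalent: BIC matches hand computation 2L - k log n
    m = fit_em(X[:, :1] * 0 + X[:, :1], 1, "EII", seed=0)
    assert m.bic == pytest.approx(2 * m.loglik - 2 * np.log(n))


def test_degenerate_point_mass_hits_regularization_floor():
    X = np.zeros((20, 2))
    m = fit_em(X, 1, "VVV", reg=1e-6, seed=0)
    assert np.allclose(m.covariances[0], 1e-6 * np.eye(2))


def test_loglik_monotone_all_families(rng):
    """EM never decreases the log-likelihood, for any covariance family."""
    for family in FAMILIES:
        covs = sample_family_covariances(family, 2, 2, rng)
        X = np.vstack(
            [rng.multivariate_normal(c, covs[k], 80) for k, c in enumerate([[0, 0], [4, 4]])]
        )
        m = fit_em(X, 2, family, seed=1, n_restarts=2)
        assert np.all(np.diff(m.loglik_path) >= -1e-7 * np.abs(m.loglik_path[1:]))


@pytest.mark.parametrize("family", FAMILIES)
def test_fitted_covariances_satisfy_family_constraints(family, rng):
    covs_true = sample_family_covariances(family, 3, 2, rng)
    centers = np.array([[0, 0], [7, 0], [0, 7]], dtype=float)
    X = np.vstack([rng.multivariate_normal(centers[k], covs_true[k], 120) for k in range(3)])
    m = fit_em(X, 3, family, seed=3)
    covs = m.covariances
    fam = FAMILY_DESCRIPTORS[family]
    eigvals = np.sort(np.linalg.eigvalsh(covs), axis=1)
    vols = np.prod(eigvals, axis=1) ** 0.5  # lambda per component (d=2)
    shapes = eigvals / vols[:, None]
    if fam.volume == "equal":
        assert np.allclose(vols, vols[0], rtol=1e-6)
    if fam.distribution == "spherical":
        assert np.allclose(eigvals[:, 0], eigvals[:, 1], rtol=1e-6)
    elif fam.shape == "equal":
        # shape eigenvalue sets identical across components after volume removal
        assert np.allclose(shapes, shapes[0], rtol=1e-5)
    if fam.distribution in ("spherical", "diagonal"):
        off = covs.copy()
        off[:, [0, 1], [0, 1]] = 0.0
        assert np.allclose(off, 0.0, atol=1e-10)


def test_1d_style_parameter_recovery(rng):
    """Two equal-variance components on a line: means recovered within 3 se."""
    n = 400
    X = np.concatenate([rng.normal(-2, 1, n // 2), rng.normal(2, 1, n // 2)])
    X = np.column_stack([X, np.zeros(n)]) + rng.normal(0, 1e-3, (n, 2))
    m = fit_em(X, 2, "EII", seed=5)
    mus = np.sort(m.means[:, 0])
    se = 1.0 / np.sqrt(n / 2)
    assert abs(mus[0] + 2) < 3 * se and abs(mus[1] - 2) < 3 * se


def test_assign_posteriors_match_brute_force(rng):
    covs = sample_family_covariances("VVV", 3, 2, rng)
    means = np.array([[0, 0], [5, 1], [-3, 4]], dtype=float)
    X = rng.normal(scale=4, size=(40, 2))
    m = fit_em(np.vstack([rng.multivariate_normal(mu, covs[k], 60)
                          for k, mu in enumerate(means)]), 3, "VVV", seed=0)
    asg = assign(m, X)
    dens = np.column_stack(
        [w * multivariate_normal.pdf(X, mu, S)
         for w, mu, S in zip(m.weights, m.means, m.covariances)]
    )
    expected = dens / dens.sum(axis=1, keepdims=True)
    assert np.allclose(asg.posterior, expected, atol=1e-10)
    assert np.allclose(asg.posterior.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(asg.uncertainty, 1 - asg.posterior.max(axis=1))
    assert np.all(asg.uncertainty <= 1 - 1 / 3 + 1e-12)


def test_assign_symmetric_midpoint_and_single_component(rng):
    X = np.vstack([rng.normal(-3, 1, (100, 2)), rng.normal(3, 1, (100, 2))])
    m = fit_em(X, 2, "EII", seed=2)
    mid = (m.means[0] + m.means[1]) / 2
    asg = assign(m, mid[None, :])
    w_equalish = abs(m.weights[0] - m.weights[1]) < 0.1
    if w_equalish:
        assert asg.uncertainty[0] == pytest.approx(0.5, abs=0.05)
    m1 = fit_em(X, 1, "VVV", seed=0)
    asg1 = assign(m1, X)
    assert np.all(asg1.uncertainty == 0.0)


def test_uncertainty_filter_strict_inequality():
    class A:
        uncertainty = np.array([0.1, 0.6, 0.5])

    retained, ignored = uncertainty_filter(A(), threshold=0.5)
    assert list(retained) == [0, 2] and list(ignored) == [1]
    # threshold 0: every point with any ambiguity is ignored
    retained, ignored = uncertainty_filter(A(), threshold=0.0)
    assert list(ignored) == [0, 1, 2] and len(retained) == 0


def test_model_select_single_blob_prefers_G1(rng):
    X = rng.normal(size=(300, 2))
    sel = model_select(X, G_range=range(1, 4), seed=0, n_restarts=2)
    assert sel.best.G == 1
    assert set(sel.table["family"]) == set(FAMILIES)
    assert len(sel.per_family_best) == len(FAMILIES)


def test_model_select_recovers_vei(rng):
    covs = sample_family_covariances("VEI", 3, 2, rng)
    centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
    X = np.vstack([rng.multivariate_normal(centers[k], covs[k], 200) for k in range(3)])
    sel = model_select(X, G_range=[3], seed=1, n_restarts=3)
    assert family_contains(sel.best.family.code, "VEI")
    assert sel.best.G == 3


def test_family_nesting_partial_order():
    for f in FAMILIES:
        assert family_contains("VVV", f)
        assert family_contains(f, f)
    assert family_contains("VEV", "VEI")
    assert family_contains("EEE", "EEI")
    assert not family_contains("EEI", "EEE")
    assert not family_contains("VII", "EEI")
    assert family_contains("VVI", "EII")
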