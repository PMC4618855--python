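"""Gaussian mixture clustering under the ten classical covariance families.

Each component covariance is parameterized through the eigenvalue
decomposition Sigma_k = lambda_k D_k A_k D_k', where the scalar lambda_k
controls volume, the diagonal matrix A_k (det A = 1) controls shape, and the
orthogonal matrix D_k controls orientation.  Constraining each factor to be
equal across components, variable, the identity, or absent yields ten nested
model families (EII, VII, EEI, VEI, EVI, VVI, EEE, EEV, VEV, VVV), the
standard repertoire of model-based clustering.  Models are fitted by EM with
family-specific constrained M-steps and compared by BIC = 2 log L - k log n
(maximized).

A point's cluster uncertainty is one minus its largest posterior component
probability; points with uncertainty above 0.5 cannot be confidently placed
in any context group and are set aside as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "FAMILIES",
    "FAMILY_DESCRIPTORS",
    "CovarianceFamily",
    "MixtureModel",
    "ClusterAssignments",
    "ModelSelection",
    "ComponentCollapseError",
    "family_contains",
    "n_params",
    "bic",
    "fit_em",
    "model_select",
    "assign",
    "uncertainty_filter",
    "sample_family_covariances",
]

#: family order mirrors the classical model table (spherical, diagonal, ellipsoidal)
FAMILIES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "EEV", "VEV", "VVV")


@dataclass(frozen=True)
class CovarianceFamily:
    code: str
    distribution: str  # spherical | diagonal | ellipsoidal
    volume: str  # equal | variable
    shape: str  # equal | variable (spherical: equal == identity)
    orientation: str  # none | coordinate-axes | equal | variable


FAMILY_DESCRIPTORS: dict[str, CovarianceFamily] = {
    "EII": CovarianceFamily("EII", "spherical", "equal", "equal", "none"),
    "VII": CovarianceFamily("VII", "spherical", "variable", "equal", "none"),
    "EEI": CovarianceFamily("EEI", "diagonal", "equal", "equal", "coordinate-axes"),
    "VEI": CovarianceFamily("VEI", "diagonal", "variable", "equal", "coordinate-axes"),
    "EVI": CovarianceFamily("EVI", "diagonal", "equal", "variable", "coordinate-axes"),
    "VVI": CovarianceFamily("VVI", "diagonal", "variable", "variable", "coordinate-axes"),
    "EEE": CovarianceFamily("EEE", "ellipsoidal", "equal", "equal", "equal"),
    "EEV": CovarianceFamily("EEV", "ellipsoidal", "equal", "equal", "variable"),
    "VEV": CovarianceFamily("VEV", "ellipsoidal", "variable", "equal", "variable"),
    "VVV": CovarianceFamily("VVV", "ellipsoidal", "variable", "variable", "variable"),
}

# ranks used for the nesting partial order: volume E<V, shape I<E<V,
# orientation axes<equal<variable (spherical shape makes orientation vacuous)
_VOL = {"E": 0, "V": 1}
_SHAPE = {"I": 0, "E": 1, "V": 2}
_ORIENT = {"I": 0, "E": 1, "V": 2}


def _axes(code: str) -> tuple[int, int, int]:
    vol, shape = _VOL[code[0]], _SHAPE[code[1]]
    if code[1] == "I":  # spherical: orientation is irrelevant
        orient = 0
    elif code[2] == "I":
        orient = 0
    elif code[2] == "E":
        orient = 1
    else:
        orient = 2
    return vol, shape, orient


def family_contains(outer: str, inner: str) -> bool:
    """True when every covariance expressible under ``inner`` is expressible
    under ``outer`` (the families are nested along volume/shape/orientation)."""
    vo, so, oo = _axes(outer)
    vi, si, oi = _axes(inner)
    return vo >= vi and so >= si and oo >= oi


class ComponentCollapseError(RuntimeError):
    """All EM restarts ended with a collapsed component."""


@dataclass
class MixtureModel:
    """A fitted constrained Gaussian mixture."""

    family: CovarianceFamily
    G: int
    weights: np.ndarray
    means: np.ndarray  # G x d
    covariances: np.ndarray  # G x d x d, family-constrained
    loglik: float
    n_params: int
    bic: float
    n: int
    converged: bool = True
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ClusterAssignments:
    """Hard labels, posterior matrix and per-point uncertainty."""

    labels: np.ndarray
    posterior: np.ndarray  # n x G
    uncertainty: np.ndarray  # 1 - max posterior

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ModelSelection:
    best: MixtureModel
    table: pd.DataFrame  # columns: family, G, bic, loglik, n_params, error
    per_family_best: pd.DataFrame


def n_params(family: str, G: int, d: int) -> int:
    """Free parameters: (G-1) weights + G*d means + family covariance count."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if G < 1 or d < 1:
        raise ValueError("G and d must be >= 1")
    rot = d * (d - 1) // 2  # parameters of one orthogonal orientation matrix
    cov = {
        "EII": 1,
        "VII": G,
        "EEI": d,
        "VEI": G + (d - 1),
        "EVI": 1 + G * (d - 1),
        "VVI": G * d,
        "EEE": d * (d + 1) // 2,
        "EEV": G * rot + (d - 1) + 1,
        "VEV": G * rot + (d - 1) + G,
        "VVV": G * d * (d + 1) // 2,
    }[family]
    return (G - 1) + G * d + cov


def bic(model: MixtureModel, n: int | None = None) -> float:
    """BIC = 2 log L - k log n; larger is better."""
    n_eff = model.n if n is None else n
    if model.n_params == 0 and model.loglik == 0:
        return 0.0
    return 2.0 * model.loglik - model.n_params * np.log(n_eff)


# ----------------------------------------------------------------------------
# constrained M-steps
# ----------------------------------------------------------------------------


def _det_normalize(diag: np.ndarray) -> np.ndarray:
    """Scale a positive vector to unit product (det A = 1)."""
    d = len(diag)
    return diag / np.exp(np.mean(np.log(diag)))


def _mstep_covariances(
    family: str, W: np.ndarray, nk: np.ndarray, n: int, inner_iters: int = 20
) -> np.ndarray:
    """Solve the family-constrained covariance update from per-component
    scatter matrices W_k (G x d x d) and responsibilities mass nk."""
    G, d, _ = W.shape
    eye = np.eye(d)
    if family == "EII":
        lam = np.trace(W.sum(axis=0)) / (n * d)
        return np.broadcast_to(lam * eye, (G, d, d)).copy()
    if family == "VII":
        lam = np.einsum("kii->k", W) / (nk * d)
        return lam[:, None, None] * eye
    if family == "EEI":
        diagsum = np.array([np.diag(Wk) for Wk in W]).sum(axis=0)
        return np.broadcast_to(np.diag(diagsum / n), (G, d, d)).copy()
    if family == "VVI":
        diags = np.array([np.diag(Wk) for Wk in W]) / nk[:, None]
        return np.array([np.diag(v) for v in diags])
    if family == "EVI":
        # closed form: A_k proportional to diag(W_k), det-normalized
        diags = np.maximum(np.array([np.diag(Wk) for Wk in W]), 1e-300)
        dets = np.exp(np.mean(np.log(diags), axis=1))  # |diag W_k|^{1/d}
        A = diags / dets[:, None]
        lam = dets.sum() / n
        return np.array([np.diag(lam * a) for a in A])
    if family == "VEI":
        # alternate lambda_k and the common diagonal shape A (det 1)
        diags = np.maximum(np.array([np.diag(Wk) for Wk in W]), 1e-300)
        A = _det_normalize(np.maximum(diags.sum(axis=0), 1e-300))
        lam = np.ones(G)
        for _ in range(inner_iters):
            lam = (diags / A).sum(axis=1) / (nk * d)
            A = _det_normalize(np.maximum((diags / lam[:, None]).sum(axis=0), 1e-300))
        return np.array([np.diag(lk * A) for lk in lam])
    if family == "EEE":
        S = W.sum(axis=0) / n
        return np.broadcast_to(S, (G, d, d)).copy()
    if family == "VVV":
        return W / nk[:, None, None]
    # EEV / VEV: eigendecompose each scatter; eigenvalues descending
    omegas = np.empty((G, d))
    rots = np.empty((G, d, d))
    for k in range(G):
        vals, vecs = np.linalg.eigh(W[k])
        order = np.argsort(vals)[::-1]
        omegas[k] = np.maximum(vals[order], 1e-300)
        rots[k] = vecs[:, order]
    if family == "EEV":
        lamA = omegas.sum(axis=0) / n  # common volume*shape across components
        return np.array([R @ np.diag(lamA) @ R.T for R in rots])
    # VEV: alternate lambda_k and common shape A (det 1)
    A = _det_normalize(np.maximum(omegas.sum(axis=0), 1e-300))
    lam = np.ones(G)
    for _ in range(20):
        lam = (omegas / A).sum(axis=1) / (nk * d)
        A = _det_normalize(np.maximum((omegas / lam[:, None]).sum(axis=0), 1e-300))
    return np.array([R @ np.diag(lk * A) @ R.T for R, lk in zip(rots, lam)])


def _regularize(covs: np.ndarray, reg: float) -> np.ndarray:
    """Floor covariance eigenvalues at ``reg`` to keep components proper."""
    G, d, _ = covs.shape
    off = covs.copy()
    idx = np.arange(d)
    off[:, idx, idx] = 0.0
    if not off.any():  # axis-aligned families: clamp the diagonal directly
        out = covs.copy()
        diag = out[:, idx, idx]
        out[:, idx, idx] = np.maximum(diag, reg)
        return out
    out = np.empty_like(covs)
    for k, S in enumerate(covs):
        vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
        out[k] = (vecs * np.maximum(vals, reg)) @ vecs.T
    return out


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    solved = np.linalg.solve(L, (X - mean).T)
    maha = np.sum(solved**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _log_prob_matrix(X: np.ndarray, model_or_parts) -> np.ndarray:
    weights, means, covs = model_or_parts
    return np.column_stack(
        [np.log(w) + _log_gaussian(X, m, S) for w, m, S in zip(weights, means, covs)]
    )


def fit_em(
    X: np.ndarray,
    G: int,
    family: str = "VVV",
    tol: float = 1e-8,
    max_iter: int = 500,
    reg: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 0,
    collapse_retries: int = 5,
) -> MixtureModel:
    """Fit a G-component mixture under a covariance family by EM.

    Initialization is kmeans++ seeding with hard nearest-center assignment
    converted to responsibilities; ``n_restarts`` independent starts are run
    and the best final log-likelihood kept.  A component collapsing (weight
    below 1/n) triggers a fresh start, up to ``collapse_retries`` extra
    attempts; if every start collapses a :class:`ComponentCollapseError` is
    raised.  The log-likelihood is non-decreasing across iterations (checked
    by tests via ``loglik_path``).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n <= G * d:
        raise ValueError(f"need n > G*d ({G * d}), got n={n}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    if G == 1:
        n_restarts = 1  # the single-component fit is deterministic
    best: MixtureModel | None = None
    attempts = n_restarts + collapse_retries
    successes = 0
    for attempt in range(attempts):
        if successes >= n_restarts:
            break
        try:
            model = _fit_once(X, G, family, tol, max_iter, reg, rng)
        except (ComponentCollapseError, np.linalg.LinAlgError):
            continue
        successes += 1
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise ComponentCollapseError(
            f"all {attempts} EM starts collapsed for family {family}, G={G}"
        )
    return best


def _fit_once(X, G, family, tol, max_iter, reg, rng) -> MixtureModel:
    n, d = X.shape
    if G == 1:
        resp = np.ones((n, 1))
    else:
        centers, _ = kmeans_plusplus(
            X, n_clusters=G, random_state=int(rng.integers(2**31 - 1))
        )
        labels = np.argmin(
            ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        resp = np.zeros((n, G))
        resp[np.arange(n), labels] = 1.0
        # guard against an empty hard cluster at init
        resp += 1e-6
        resp /= resp.sum(axis=1, keepdims=True)

    loglik_prev = -np.inf
    path: list[float] = []
    weights = means = covs = None
    for it in range(max_iter):
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1.0):  # weight < 1/n
            raise ComponentCollapseError(f"component collapsed at iteration {it}")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        W = np.empty((G, d, d))
        for k in range(G):
            Xc = X - means[k]
            W[k] = (resp[:, k][:, None] * Xc).T @ Xc
        covs = _regularize(_mstep_covariances(family, W, nk, n), reg)
        # E-step
        logp = _log_prob_matrix(X, (weights, means, covs))
        norm = logsumexp(logp, axis=1)
        loglik = float(norm.sum())
        path.append(loglik)
        resp = np.exp(logp - norm[:, None])
        if loglik - loglik_prev < tol * max(abs(loglik), 1.0) and it > 0:
            loglik_prev = loglik
            break
        loglik_prev = loglik
    k_params = n_params(family, G, d)
    model = MixtureModel(
        family=FAMILY_DESCRIPTORS[family],
        G=G,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik_prev,
        n_params=k_params,
        bic=0.0,
        n=n,
        converged=it < max_iter - 1,
        n_iter=it + 1,
        loglik_path=np.asarray(path),
    )
    model.bic = bic(model)
    return model


def model_select(
    X: np.ndarray,
    G_range: Iterable[int] = range(1, 10),
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    n_restarts: int = 5,
    **fit_kwargs,
) -> ModelSelection:
    """Fit every (family, G) pair and return the BIC-maximizing model.

    Ties are broken toward fewer parameters, then toward the earlier family
    in the canonical table order.  The full BIC table and the per-family
    maxima (one BIC per family, best over G) are both returned.
    """
    G_list = list(G_range)
    if not G_list:
        raise ValueError("G_range is empty")
    rows = []
    fits: list[MixtureModel] = []
    rng = np.random.default_rng(seed)
    for G in G_list:
        for fam in families:
            sub = int(rng.integers(2**31 - 1))
            try:
                m = fit_em(
                    X, G, family=fam, seed=sub, n_restarts=n_restarts, **fit_kwargs
                )
                fits.append(m)
                rows.append(
                    {"family": fam, "G": G, "bic": m.bic, "loglik": m.loglik,
                     "n_params": m.n_params, "error": ""}
                )
            except (ValueError, ComponentCollapseError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {"family": fam, "G": G, "bic": np.nan, "loglik": np.nan,
                     "n_params": n_params(fam, G, X.shape[1]), "error": str(exc)}
                )
    if not fits:
        table = pd.DataFrame(rows)
        raise RuntimeError(
            "every (family, G) fit failed:\n" + table.to_string(index=False)
        )
    fits.sort(
        key=lambda m: (-m.bic, m.n_params, FAMILIES.index(m.family.code))
    )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["bic"])
    per_family = (
        ok.loc[ok.groupby("family")["bic"].idxmax()]
        .set_index("family")
        .reindex([f for f in families])
        .reset_index()
    )
    return ModelSelection(best=fits[0], table=table, per_family_best=per_family)


def assign(model: MixtureModel, X: np.ndarray) -> ClusterAssignments:
    """Posterior component probabilities, hard labels and uncertainties."""
    X = np.asarray(X, dtype=float)
    logp = _log_prob_matrix(X, (model.weights, model.means, model.covariances))
    post = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    labels = post.argmax(axis=1)
    return ClusterAssignments(
        labels=labels, posterior=post, uncertainty=1.0 - post.max(axis=1)
    )


def uncertainty_filter(
    assignments: ClusterAssignments, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split point indices into (retained, ignored) by cluster uncertainty.

    A point is ignored when its uncertainty strictly exceeds the threshold
    (default 0.5): it could be either inconsistent or simply mis-clustered,
    so no verdict is attempted for it downstream.
    """
    unc = assignments.uncertainty
    ignored = np.flatnonzero(unc > threshold)
    retained = np.flatnonzero(unc <= threshold)
    return retained, ignored


def sample_family_covariances(
    family: str,
    G: int,
    d: int,
    rng: np.random.Generator,
    volume_range: tuple[float, float] = (0.5, 2.0),
    shape_spread: float = 4.0,
) -> np.ndarray:
    """Draw G covariance matrices satisfying a family's constraints.

    Used by the synthetic generator and the family-recovery experiments, so
    the draws are made *identifiable*: when a factor is variable its values
    are spread apart (volume ratio >= 2, shape eigenvalue ratio >= half of
    ``shape_spread``), and non-axis orientations are kept away from the
    coordinate axes and from each other.  Without this a nominally variable
    factor can land close to a constrained one by chance, in which case the
    more parsimonious family is the *correct* description of the realized
    parameters and family recovery is ill-posed.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    fam = FAMILY_DESCRIPTORS[family]

    def draw_volumes() -> np.ndarray:
        lo, hi = np.log(volume_range[0]), np.log(volume_range[1])
        # log-spaced with jitter: adjacent ratio at least (hi/lo)^{1/G} apart
        base = np.linspace(lo, hi, G) if G > 1 else np.array([(lo + hi) / 2.0])
        jitter = rng.uniform(-0.1, 0.1, size=G) * (hi - lo)
        return np.exp(rng.permutation(base + jitter))

    def draw_shape(k: int | None = None) -> np.ndarray:
        # diagonal with det 1 and eigenvalue ratio well away from 1; for
        # variable shapes (k given) the elongated axis rotates across
        # components and the ratio bands are spread apart, so "equal shape"
        # is never an adequate description of the draw
        spread = rng.uniform(np.sqrt(shape_spread), shape_spread)
        base = np.linspace(0.0, np.log(spread), d)
        if k is None:
            return _det_normalize(np.exp(rng.permutation(base)))
        ratio = shape_spread ** (0.5 + 0.55 * (k % 3)) * rng.uniform(0.95, 1.05)
        base = np.linspace(0.0, np.log(ratio), d)
        return _det_normalize(np.exp(np.roll(base, k)))

    def draw_rotations(k: int, distinct: bool) -> list[np.ndarray]:
        if d == 2:
            # angles stratified in (0, pi/2), away from the axes and each other
            if distinct:
                thetas = (np.arange(k) + rng.uniform(0.25, 0.75, size=k)) * (np.pi / 2) / k
            else:
                thetas = np.full(k, rng.uniform(np.pi / 10, 2 * np.pi / 5))
            return [
                np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
                for t in thetas
            ]
        mats = []
        for _ in range(k if distinct else 1):
            M = rng.normal(size=(d, d))
            Q, R = np.linalg.qr(M)
            mats.append(Q * np.sign(np.diag(R)))
        return mats if distinct else mats * k

    lam = draw_volumes() if fam.volume == "variable" else np.full(G, np.exp(rng.uniform(
        np.log(volume_range[0]), np.log(volume_range[1]))))
    if fam.distribution == "spherical":
        A = [np.ones(d)] * G
    elif fam.shape == "variable":
        A = [draw_shape(k) for k in range(G)]
    else:
        common = draw_shape()
        A = [common] * G
    if fam.distribution in ("spherical", "diagonal"):
        D = [np.eye(d)] * G
    else:
        D = draw_rotations(G, distinct=fam.orientation == "variable")
    return np.array(
        [lam[k] * (D[k] * A[k]) @ D[k].T for k in range(G)]
    )
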