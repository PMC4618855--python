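"""Exact t-SNE to two dimensions, with the perplexity-sweep selection rule.

t-SNE places a Gaussian over each point in the input space, with a per-point
bandwidth tuned by binary search so that the conditional distribution has a
requested perplexity (a smooth effective-neighbor count), and matches the
resulting joint affinities P with a Student-t (1 df) distribution Q over the
2-D map positions by gradient descent on KL(P || Q).  The implementation is
the exact O(n^2) algorithm — input sizes here are at most a few thousand —
with the original optimizer conventions (momentum schedule, early
exaggeration, adaptive per-parameter gains).

Perplexity is selected by sweeping candidate values and keeping the one whose
embedding lets the downstream mixture clustering resolve the most components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AffinityMatrix",
    "Embedding",
    "SweepResult",
    "conditional_affinities",
    "kl_divergence",
    "tsne",
    "perplexity_sweep",
]

#: floor on squared distances so duplicate points do not blow up divisions
_D2_FLOOR = 1e-12
_EPS = 1e-12


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetrized joint input-space affinities P (n x n, sums to 1)."""

    P: np.ndarray
    perplexity: float
    sigmas: np.ndarray


@dataclass(frozen=True)
class Embedding:
    """A 2-D t-SNE map with its final KL divergence."""

    Y: np.ndarray
    kl_final: float
    kl_initial: float
    perplexity_used: float
    seed: int


@dataclass(frozen=True)
class SweepResult:
    perplexity: float
    embedding: Embedding
    cluster_counts: dict[float, int]


def _sq_distances(X: np.ndarray) -> np.ndarray:
    D2 = squareform(pdist(X, "sqeuclidean"))
    np.fill_diagonal(D2, 0.0)
    return np.maximum(D2, _D2_FLOOR) - np.where(np.eye(len(X), dtype=bool), _D2_FLOOR, 0.0)


def _row_conditional(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Conditional p_{j|i} for precision beta = 1/(2 sigma^2); returns (p, perplexity)."""
    logits = -beta * d2_row
    logits -= logits.max()
    p = np.exp(logits)
    s = p.sum()
    p /= s
    # Shannon entropy in nats; perplexity = exp(H)
    nz = p > 0
    H = -np.sum(p[nz] * np.log(p[nz]))
    return p, float(np.exp(H))


def conditional_affinities(
    X: np.ndarray,
    perplexity: float,
    tol: float = 1e-4,
    max_iter: int = 64,
) -> AffinityMatrix:
    """Per-point Gaussian conditionals calibrated to ``perplexity``, symmetrized.

    For each point the bandwidth is found by binary search on the precision so
    the achieved conditional perplexity is within ``tol`` of the target; the
    joint affinity is p_ij = (p_{j|i} + p_{i|j}) / (2n).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 1.0 < perplexity < n:
        raise ValueError(f"perplexity must be in (1, n={n}), got {perplexity}")
    D2 = _sq_distances(X)
    P_cond = np.zeros((n, n))
    sigmas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        d2 = np.maximum(D2[i, idx != i], _D2_FLOOR)
        beta, lo, hi = 1.0, 0.0, np.inf
        p = None
        for _ in range(max_iter):
            p, perp = _row_conditional(d2, beta)
            if abs(perp - perplexity) < tol:
                break
            if perp > perplexity:  # too flat: increase precision
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else (beta + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        P_cond[i, idx != i] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    P = (P_cond + P_cond.T) / (2.0 * n)
    return AffinityMatrix(P=P, perplexity=float(perplexity), sigmas=sigmas)


def _q_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t (1 df) map affinities Q and the unnormalized kernel."""
    D2 = squareform(pdist(Y, "sqeuclidean"))
    num = 1.0 / (1.0 + D2)
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def kl_divergence(P: AffinityMatrix | np.ndarray, Y: np.ndarray) -> float:
    """KL(P || Q) over off-diagonal pairs with p_ij > 0; nonnegative."""
    Pm = P.P if isinstance(P, AffinityMatrix) else np.asarray(P, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise ValueError("non-finite embedding coordinates")
    Q, _ = _q_matrix(Y)
    mask = Pm > 0
    return float(np.sum(Pm[mask] * np.log(Pm[mask] / np.maximum(Q[mask], _EPS))))


def tsne(
    X: np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    iters: int = 1000,
    learning_rate: float = 200.0,
    early_exaggeration: float = 4.0,
    exaggeration_iters: int = 100,
    momentum_switch: int = 250,
    affinities: AffinityMatrix | None = None,
) -> Embedding:
    """Gradient descent on KL(P || Q) from a small random 2-D initialization.

    Deterministic given ``seed``.  ``kl_initial`` is the divergence of the
    (un-exaggerated) P against the random start; ``kl_final`` is computed
    after exaggeration is removed and is at most ``kl_initial``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points")
    aff = affinities if affinities is not None else conditional_affinities(X, perplexity)
    P = aff.P
    rng = np.random.default_rng(seed)
    Y = rng.normal(scale=1e-2, size=(n, 2))
    kl_initial = kl_divergence(P, Y)

    Pex = P * early_exaggeration
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    for it in range(iters):
        Pcur = Pex if it < exaggeration_iters else P
        Q, num = _q_matrix(Y)
        W = (Pcur - Q) * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)
        if not np.isfinite(grad).all():
            raise FloatingPointError(f"t-SNE gradient diverged at iteration {it}")
        momentum = 0.5 if it < momentum_switch else 0.8
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        update = momentum * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    kl_final = kl_divergence(P, Y)
    return Embedding(
        Y=Y,
        kl_final=kl_final,
        kl_initial=kl_initial,
        perplexity_used=float(perplexity),
        seed=seed,
    )


def perplexity_sweep(
    X: np.ndarray,
    cluster_fn: Callable[[Embedding], int],
    values: Sequence[float] | None = None,
    seed: int = 0,
    **tsne_kwargs,
) -> SweepResult:
    """Embed at each candidate perplexity and keep the one that maximizes
    the number of mixture components the clustering step can resolve.

    ``cluster_fn`` maps an Embedding to a fitted component count G.  Ties are
    broken toward the smallest perplexity.  Candidates not satisfying
    1 < perplexity < n are skipped.
    """
    n = np.asarray(X).shape[0]
    cand = [float(v) for v in (values if values is not None else range(5, 51, 5))]
    cand = [v for v in cand if 1.0 < v < n]
    if not cand:
        raise ValueError("no valid perplexity candidates for this sample size")
    counts: dict[float, int] = {}
    embeddings: dict[float, Embedding] = {}
    failures: list[str] = []
    for v in cand:
        try:
            emb = tsne(X, perplexity=v, seed=seed, **tsne_kwargs)
            counts[v] = int(cluster_fn(emb))
            embeddings[v] = emb
        except Exception as exc:  # noqa: BLE001 - collected into the failure report
            failures.append(f"perplexity {v}: {exc}")
    if not counts:
        raise RuntimeError("all perplexity candidates failed: " + "; ".join(failures))
    best = max(sorted(counts), key=lambda v: counts[v])  # ties -> smallest value
    return SweepResult(perplexity=best, embedding=embeddings[best], cluster_counts=counts)
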