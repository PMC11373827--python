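"""Fuzzy c-means memberships and the hybrid AA + FCM decomposition.

Fuzzy c-means (FCM) assigns each observation a graded membership across all
K cluster centroids via inverse-distance ratios raised to 2/(P-1), where the
fuzziness exponent P > 1 controls how blurred the assignment is (P -> 1+
gives crisp nearest-centroid assignment; P -> inf gives uniform 1/K).

The package's headline decomposition fixes the FCM centroids at the fitted
archetypes and reports the memberships of a visual field as its
decomposition coefficients.  Unlike the AA simplex projection, memberships
are strictly positive for generic fields and carry no reconstruction
residual — the decomposition is a lossless description, not a projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .archetypal import ArchetypeSet, SimplexWeights

__all__ = [
    "FcmConfig",
    "MembershipMatrix",
    "fcm_memberships",
    "fcm_update_centroids",
    "fcm_objective",
    "hybrid_decompose",
    "hybrid_decompose_matrix",
    "fcm_iterate",
]


@dataclass(frozen=True)
class FcmConfig:
    """Fuzzy-clustering controls.

    P is the fuzziness exponent (dimensionless, > 1; default 2, the standard
    choice).  ``max_iter`` and ``tol`` apply only to full FCM iteration; the
    hybrid decomposition performs no centroid updates.
    """

    P: float = 2.0
    max_iter: int = 300
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.P > 1.0:
            raise ValueError(f"fuzziness exponent P must be > 1, got {self.P}")


@dataclass(frozen=True)
class MembershipMatrix:
    """Full-FCM result: row-stochastic weights, centroids, and the SSE objective."""

    W: np.ndarray          # (n, K)
    centroids: np.ndarray  # (K, d)
    objective: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        if np.max(np.abs(W.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("membership rows must sum to 1 (tol 1e-10)")
        if W.min() < 0.0 or W.max() > 1.0:
            raise ValueError("memberships must lie in [0, 1]")


def _membership_rows(D: np.ndarray, P: float) -> np.ndarray:
    """Memberships from an (n, K) Euclidean distance matrix.

    w_ij = [ sum_k (d_ij / d_ik)^(2/(P-1)) ]^-1; rows with one or more zero
    distances get weight split equally among the coincident centroids (the
    continuous limit of the formula).
    """
    n, K = D.shape
    W = np.empty((n, K))
    zero = D <= 0.0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        Z = zero[any_zero]
        W[any_zero] = Z / Z.sum(axis=1, keepdims=True)
    reg = ~any_zero
    if reg.any():
        Dr = D[reg]
        expo = 2.0 / (P - 1.0)
        # w_ij = d_ij^-expo / sum_k d_ik^-expo, computed in log space for
        # stability at extreme P or tiny distances
        logd = np.log(Dr)
        A = -expo * logd
        A -= A.max(axis=1, keepdims=True)
        E = np.exp(A)
        W[reg] = E / E.sum(axis=1, keepdims=True)
    return W


def fcm_memberships(x: np.ndarray, centroids: np.ndarray, P: float = 2.0) -> SimplexWeights:
    """Membership weights of one point relative to fixed centroids.

    The nearer a centroid, the larger its weight; all weights are strictly
    positive unless the point coincides with a centroid, in which case the
    coincident centroid(s) receive all the weight.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if C.shape[0] == 0:
        raise ValueError("need at least one centroid")
    if not P > 1.0:
        raise ValueError("P must be > 1")
    D = np.linalg.norm(C - x[None, :], axis=1)[None, :]
    w = _membership_rows(D, P)[0]
    return SimplexWeights(w=w, method="FCM")


def fcm_update_centroids(X: np.ndarray, W: np.ndarray, P: float = 2.0) -> np.ndarray:
    """Weighted-mean centroid update: c_k = sum_i W_ik^P x_i / sum_i W_ik^P."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    Wp = W ** P
    denom = Wp.sum(axis=0)
    if np.any(denom <= 0.0):
        raise ValueError("degenerate cluster: a membership column is identically 0")
    return (Wp.T @ X) / denom[:, None]


def fcm_objective(X: np.ndarray, W: np.ndarray, centroids: np.ndarray, P: float = 2.0) -> float:
    """FCM sum-of-squares objective: sum_k sum_i W_ik^P ||x_i - c_k||^2."""
    X = np.asarray(X, dtype=float)
    C = np.asarray(centroids, dtype=float)
    W = np.asarray(W, dtype=float)
    D2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return float(np.sum((W ** P) * D2))


def hybrid_decompose(
    x: np.ndarray, archetypes: ArchetypeSet, config: FcmConfig | None = None
) -> SimplexWeights:
    """FCM membership decomposition of a field against fixed AA archetypes.

    The centroids are the fitted archetype patterns and are never iterated;
    the output is the field's membership vector (strictly positive for
    generic fields, summing to 1).
    """
    config = config or FcmConfig()
    return fcm_memberships(x, archetypes.patterns, config.P)


def hybrid_decompose_matrix(
    X: np.ndarray, archetypes: ArchetypeSet, config: FcmConfig | None = None
) -> np.ndarray:
    """Vectorized :func:`hybrid_decompose` over rows of X; returns (n, k) weights."""
    config = config or FcmConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = archetypes.patterns
    D2 = np.maximum(
        (X * X).sum(axis=1)[:, None] + (C * C).sum(axis=1)[None, :] - 2.0 * X @ C.T,
        0.0,
    )
    return _membership_rows(np.sqrt(D2), config.P)


def fcm_iterate(
    X: np.ndarray, K: int, config: FcmConfig | None = None, seed: int | None = None
) -> MembershipMatrix:
    """Full fuzzy c-means: alternate membership and centroid updates.

    Starts from seeded random row-stochastic memberships and stops when the
    objective improves by less than ``config.tol`` or after ``max_iter``
    sweeps.  Provided for validation; the hybrid pipeline never iterates
    centroids.
    """
    config = config or FcmConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < K:
        raise ValueError("need at least K data points")
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.ones(K), size=n)
    prev = np.inf
    C = fcm_update_centroids(X, W, config.P)
    for _ in range(config.max_iter):
        D2 = np.maximum(
            (X * X).sum(axis=1)[:, None] + (C * C).sum(axis=1)[None, :] - 2.0 * X @ C.T,
            0.0,
        )
        W = _membership_rows(np.sqrt(D2), config.P)
        C = fcm_update_centroids(X, W, config.P)
        obj = fcm_objective(X, W, C, config.P)
        if prev - obj < config.tol:
            break
        prev = obj
    return MembershipMatrix(W=W, centroids=C, objective=fcm_objective(X, W, C, config.P))
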