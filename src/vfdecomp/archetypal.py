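"""Archetypal analysis of visual-field TDV matrices.

Archetypal analysis (AA) factorizes a data matrix X (n rows of 52 TDVs) as
X ~ W @ A with A = B @ X, where rows of W and rows of B are constrained to
the probability simplex.  Archetypes (rows of A) therefore lie in the convex
hull of the data — the principal-convex-hull formulation — and each field is
represented as a convex combination of archetypes.  Points outside the hull
incur a positive projection residual; this "projection loss" is the property
the fuzzy-membership decomposition in :mod:`vfdecomp.fuzzy` sidesteps.

Optimization is alternating constrained least squares: the W-step is solved
by (accelerated) projected gradient with a monotone fallback, and each row
of B by exact nonnegative least squares on a sum-constraint-augmented
system, accepted only if it does not increase the objective — so the sweep
objective is guaranteed non-increasing.  Initialization uses the
furthest-sum heuristic with multiple restarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls as _nnls

__all__ = [
    "AaConfig",
    "ArchetypeSet",
    "SimplexWeights",
    "ScreeTable",
    "fit_archetypes",
    "aa_decompose",
    "reconstruction_error",
    "select_k",
    "project_simplex",
    "simplex_lstsq",
]


# ---------------------------------------------------------------------------
# Simplex primitives
# ---------------------------------------------------------------------------

def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of rows of ``v`` onto the probability simplex.

    Accepts a vector (k,) or matrix (n, k); returns the same shape.  Uses the
    sort-based algorithm; the result is exactly nonnegative and sums to 1 up
    to machine rounding.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    V = v[None, :] if single else v
    n, k = V.shape
    u = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last True per row
    theta = css[np.arange(n), rho] / (rho + 1)
    W = np.maximum(V - theta[:, None], 0.0)
    # renormalize to kill last-ulp drift in the sum
    W /= W.sum(axis=1, keepdims=True)
    return W[0] if single else W


def _pgd_simplex(
    grad_fn,
    lipschitz: float,
    w0: np.ndarray,
    *,
    max_iter: int = 2000,
    tol: float = 1e-10,
    accel: bool = True,
) -> np.ndarray:
    """Projected gradient on the simplex (FISTA acceleration optional).

    ``grad_fn`` maps the current point (same shape as ``w0``, rows on the
    simplex) to the gradient; ``lipschitz`` bounds the gradient Lipschitz
    constant.  With ``accel=False`` the iteration is plain PGD with step
    1/L, which is monotone in the objective.  Stops when the iterate moves
    less than ``tol`` (inf-norm).
    """
    step = 1.0 / max(lipschitz, 1e-300)
    w = w0
    z = w0
    t = 1.0
    for _ in range(max_iter):
        w_new = project_simplex(z - step * grad_fn(z))
        if accel:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = w_new + ((t - 1.0) / t_new) * (w_new - w)
            t = t_new
        else:
            z = w_new
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def _active_set_polish(G: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Exact KKT solve of min 0.5 w'Gw - b'w on the simplex, warm-started at w.

    Iterates equality-constrained solves on the active support, dropping
    negative coordinates and admitting coordinates whose KKT multiplier is
    violated.  Finite and exact up to the linear solver; returns ``w``
    unchanged (renormalized) if a solve is singular.
    """
    k = len(w)
    support = w > 1e-12
    if not support.any():
        support[int(np.argmax(w))] = True
    for _ in range(4 * k):
        idx = np.flatnonzero(support)
        m = len(idx)
        KKT = np.zeros((m + 1, m + 1))
        KKT[:m, :m] = G[np.ix_(idx, idx)]
        KKT[:m, m] = 1.0
        KKT[m, :m] = 1.0
        rhs = np.concatenate([b[idx], [1.0]])
        try:
            sol = np.linalg.solve(KKT, rhs)
        except np.linalg.LinAlgError:
            return project_simplex(w)
        ws, mu = sol[:m], sol[m]
        if ws.min() < -1e-12:
            support[idx[int(np.argmin(ws))]] = False
            continue
        # KKT check for excluded coordinates: gradient must not undercut mu
        full = np.zeros(k)
        full[idx] = ws
        grad = G @ full - b
        excluded = np.flatnonzero(~support)
        if len(excluded):
            viol = grad[excluded] - mu
            j = int(np.argmin(viol))
            if viol[j] < -1e-10 * max(1.0, abs(mu)):
                support[excluded[j]] = True
                continue
        # renormalize without re-projecting so inactive weights stay exactly 0
        full = np.maximum(full, 0.0)
        return full / full.sum()
    w = np.maximum(w, 0.0)
    return w / w.sum()


def simplex_lstsq(
    A: np.ndarray,
    x: np.ndarray,
    *,
    w0: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve min_w ||x - w @ A||^2 s.t. w >= 0, sum(w) = 1.

    ``A`` is (k, d) (dictionary rows), ``x`` is (d,).  Projected gradient
    locates the solution's neighbourhood and an exact active-set KKT solve
    polishes it, so the constraints hold to machine precision and the
    optimum is exact up to the linear solver.
    """
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    k = A.shape[0]
    if k == 1:
        return np.ones(1)
    G = A @ A.T
    b = A @ x
    L = float(np.linalg.norm(G, 2))
    w0 = np.full(k, 1.0 / k) if w0 is None else project_simplex(w0)
    w = _pgd_simplex(lambda w: w @ G - b, L, w0, max_iter=max_iter, tol=tol)
    return _active_set_polish(G, b, w)


def _batch_simplex_lstsq(
    A: np.ndarray,
    X: np.ndarray,
    W0: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-9,
    accel: bool = True,
) -> np.ndarray:
    """Row-wise min ||X - W @ A||_F^2 over row-stochastic W, warm-started at W0."""
    G = A @ A.T
    B = X @ A.T
    L = float(np.linalg.norm(G, 2))
    return _pgd_simplex(lambda W: W @ G - B, L, W0, max_iter=max_iter, tol=tol, accel=accel)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimplexWeights:
    """Decomposition coefficients of one field: k weights on the simplex.

    ``method`` is "AA" (simplex projection onto the archetypes, may contain
    exact zeros, has a reconstruction residual) or "FCM" (fuzzy membership,
    strictly positive for generic fields, no residual defined).
    """

    w: np.ndarray
    method: str  # "AA" | "FCM"
    residual_rss: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if self.method not in ("AA", "FCM"):
            raise ValueError(f"method must be 'AA' or 'FCM', got {self.method!r}")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class AaConfig:
    """Optimizer controls for the archetypal fit."""

    n_restarts: int = 5
    max_iter: int = 500           # alternating sweeps per restart
    tol: float = 1e-6             # relative objective improvement stop
    inner_iter: int = 200         # projected-gradient iterations per sub-step
    seed: int | None = None


@dataclass(frozen=True)
class ArchetypeSet:
    """Fitted archetypes: k patterns of 52 TDVs plus fit metadata.

    ``hull_coefficients`` stores each archetype's convex-combination weights
    over the training rows (rows >= 0, sum 1), certifying that every pattern
    lies in the convex hull of the training data.
    """

    k: int
    patterns: np.ndarray                      # (k, d)
    hull_coefficients: np.ndarray             # (k, n_train)
    fit_rss: float
    seed: int | None
    n_iter: int
    converged: bool
    labels: tuple[str, ...] | None = None
    objective_history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        P = np.asarray(self.patterns, dtype=float)
        object.__setattr__(self, "patterns", P)
        B = np.asarray(self.hull_coefficients, dtype=float)
        object.__setattr__(self, "hull_coefficients", B)
        if P.shape[0] != self.k or B.shape[0] != self.k:
            raise ValueError("patterns/hull_coefficients rows must equal k")
        if np.any(B < -1e-9) or np.max(np.abs(B.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("hull coefficients must be simplex rows (tol 1e-6)")

    def to_json(self, path) -> None:
        obj = {
            "k": self.k,
            "patterns": [[round(float(v), 10) for v in row] for row in self.patterns],
            "labels": list(self.labels) if self.labels else None,
            "fit_rss": self.fit_rss,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ArchetypeSet":
        with open(path) as fh:
            obj = json.load(fh)
        k = obj["k"]
        # a deserialized set loses its training-row certificate; store identity
        return cls(
            k=k,
            patterns=np.array(obj["patterns"]),
            hull_coefficients=np.eye(k),
            fit_rss=obj.get("fit_rss", float("nan")),
            seed=obj.get("seed"),
            n_iter=obj.get("n_iter", 0),
            converged=obj.get("converged", True),
            labels=tuple(obj["labels"]) if obj.get("labels") else None,
        )


@dataclass(frozen=True)
class ScreeTable:
    """Cross-validated reconstruction error per candidate number of archetypes."""

    k_values: tuple[int, ...]
    mean_errors: tuple[float, ...]
    fold_errors: np.ndarray  # (len(k_values), folds)
    seed: int | None

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.fold_errors,
            columns=[f"fold_{i}" for i in range(self.fold_errors.shape[1])],
        )
        df.insert(0, "k", self.k_values)
        df.insert(1, "mean_error", self.mean_errors)
        return df


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Furthest-sum seeding: indices of k mutually distant data rows.

    Starts from a random row, greedily adds the row maximizing the summed
    distance to those already selected, and re-selects the (arbitrary) first
    pick once at the end.
    """
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)

    def dists_to(j: int) -> np.ndarray:
        return np.sqrt(np.maximum(sq + sq[j] - 2.0 * (X @ X[j]), 0.0))

    idx = [int(rng.integers(n))]
    dsum = dists_to(idx[0])
    while len(idx) < k:
        dmask = dsum.copy()
        dmask[idx] = -np.inf
        j = int(np.argmax(dmask))
        idx.append(j)
        dsum = dsum + dists_to(j)
    if k > 1:  # replace the random seed point with a furthest-sum point
        dsum = dsum - dists_to(idx[0])
        dmask = dsum.copy()
        dmask[idx[1:]] = -np.inf
        idx[0] = int(np.argmax(dmask))
    return np.array(sorted(set(idx))[:k]) if len(set(idx)) >= k else np.array(idx)


def _fit_once(
    X: np.ndarray, k: int, config: AaConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    n, d = X.shape
    init = _furthest_sum(X, k, rng)
    if len(init) < k:  # degenerate duplicates; pad with random rows
        extra = rng.choice(n, size=k - len(init), replace=False)
        init = np.concatenate([init, extra])[:k]
    B = np.zeros((k, n))
    B[np.arange(k), init] = 1.0
    A = B @ X
    W = np.full((n, k), 1.0 / k)
    W = _batch_simplex_lstsq(A, X, W, max_iter=config.inner_iter)

    # B rows are solved by NNLS on a sum-constraint-augmented system; the
    # penalty weight only needs to dominate the data scale because the
    # solution is renormalized and guarded afterwards.
    M = 10.0 * max(float(np.abs(X).max()), 1.0)
    Xaug = np.vstack([X.T, M * np.ones(n)])

    def objective(Wc, Ac):
        R = X - Wc @ Ac
        return float(np.einsum("ij,ij->", R, R))

    history = [objective(W, A)]
    converged = False
    for _ in range(config.max_iter):
        # W-step: accelerated solve with a plain-PGD monotone fallback
        prev_obj = history[-1]
        W_cand = _batch_simplex_lstsq(A, X, W, max_iter=config.inner_iter)
        if objective(W_cand, A) <= prev_obj:
            W = W_cand
        else:
            W = _batch_simplex_lstsq(A, X, W, max_iter=config.inner_iter, accel=False)
        # B-step: row-wise simplex least squares with acceptance guard
        Xhat = W @ A
        wsq = np.einsum("ij,ij->j", W, W)  # ||w_.j||^2
        for j in range(k):
            if wsq[j] <= 0.0:
                continue
            Rj = X - Xhat + np.outer(W[:, j], A[j])
            t = (Rj.T @ W[:, j]) / wsq[j]
            bj, _ = _nnls(Xaug, np.concatenate([t, [M]]))
            s = bj.sum()
            if s <= 0.0:
                continue
            bj = bj / s
            a_new = bj @ X
            old_loss = float(np.sum((Rj - np.outer(W[:, j], A[j])) ** 2))
            new_loss = float(np.sum((Rj - np.outer(W[:, j], a_new)) ** 2))
            if new_loss <= old_loss + 1e-12:
                B[j] = bj
                Xhat += np.outer(W[:, j], a_new - A[j])
                A[j] = a_new
        obj = objective(W, A)
        history.append(obj)
        prev = history[-2]
        if prev - obj <= config.tol * max(prev, 1e-300):
            converged = True
            break
    return A, B, W, history, converged


def fit_archetypes(X: np.ndarray, k: int, config: AaConfig | None = None) -> ArchetypeSet:
    """Fit ``k`` archetypes to the rows of ``X`` by alternating minimization.

    Runs ``config.n_restarts`` furthest-sum-initialized restarts and returns
    the lowest-RSS fit.  The per-sweep objective is non-increasing within
    each restart (recorded in ``objective_history``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_samples, got k={k}, n={n}")
    config = config or AaConfig()
    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(max(config.n_restarts, 1)):
        A, B, W, history, converged = _fit_once(X, k, config, rng)
        if best is None or history[-1] < best[3][-1]:
            best = (A, B, W, history, converged)
    A, B, W, history, converged = best
    return ArchetypeSet(
        k=k,
        patterns=A,
        hull_coefficients=project_simplex(np.maximum(B, 0.0)),
        fit_rss=history[-1],
        seed=config.seed,
        n_iter=len(history) - 1,
        converged=converged,
        objective_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# Decomposition and model selection
# ---------------------------------------------------------------------------

def aa_decompose(x: np.ndarray, archetypes: ArchetypeSet) -> SimplexWeights:
    """Project one field onto the archetype simplex.

    Returns the weights w minimizing ||x - w @ A||^2 subject to the simplex
    constraint, together with the squared residual.  Zero weights are
    permitted and expected for fields far from some archetypes.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    w = simplex_lstsq(archetypes.patterns, x)
    resid = x - w @ archetypes.patterns
    return SimplexWeights(w=w, method="AA", residual_rss=float(resid @ resid))


def aa_decompose_matrix(X: np.ndarray, archetypes: ArchetypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`aa_decompose` over rows: returns (W, residual_rss)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    A = archetypes.patterns
    W0 = np.full((n, archetypes.k), 1.0 / archetypes.k)
    W = _batch_simplex_lstsq(A, X, W0, max_iter=2000, tol=1e-10)
    if archetypes.k > 1:
        G = A @ A.T
        B = X @ A.T
        W = np.vstack([_active_set_polish(G, B[i], W[i]) for i in range(n)])
    R = X - W @ A
    return W, np.einsum("ij,ij->i", R, R)


def reconstruction_error(X: np.ndarray, archetypes: ArchetypeSet) -> float:
    """Mean per-row squared residual of the AA simplex projection of each row."""
    _, rss = aa_decompose_matrix(np.atleast_2d(X), archetypes)
    return float(np.mean(rss))


def select_k(
    X: np.ndarray,
    k_range: Sequence[int],
    *,
    folds: int = 5,
    seed: int | None = None,
    config: AaConfig | None = None,
) -> ScreeTable:
    """Scree table: cross-validated held-out reconstruction error per k.

    For each candidate k, fits archetypes on the training folds and scores
    :func:`reconstruction_error` on the held-out fold; plain random fold
    assignment seeded by ``seed``.
    """
    from sklearn.model_selection import KFold

    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < folds:
        raise ValueError("need at least as many rows as folds")
    base = config or AaConfig(n_restarts=2)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    errs = np.empty((len(k_range), folds))
    for i, k in enumerate(k_range):
        for f, (tr, te) in enumerate(splits):
            fit_cfg = AaConfig(
                n_restarts=base.n_restarts,
                max_iter=base.max_iter,
                tol=base.tol,
                inner_iter=base.inner_iter,
                seed=(seed or 0) * 1000 + i * folds + f,
            )
            ats = fit_archetypes(X[tr], k, fit_cfg)
            errs[i, f] = reconstruction_error(X[te], ats)
    return ScreeTable(
        k_values=tuple(k_range),
        mean_errors=tuple(float(m) for m in errs.mean(axis=1)),
        fold_errors=errs,
        seed=seed,
    )
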