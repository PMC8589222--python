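"""Numerical engine for the adaptive kernel fuzzy c-means fits.

Everything here is vectorized over (clusters K, observations n, variables p).
Conventions: U is the K x n membership matrix with columns summing to 1;
V is the K x p prototype matrix (prototypes live in the original data
space — kernelization of the metric); Lambda is the K x p positive weight
matrix with a per-cluster product-one constraint.  Per-variable feature-space
squared distances are ``2 (1 - K_j(x_ij, v_kj))`` for the Gaussian kernel.

Three fitting modes share one coordinate-descent loop:

* ``complete`` — plain fit on a fully observed matrix;
* ``pds``      — partial-distance fit: all sums run over observed cells
  only, and the objective carries the ``p / I_i`` rescale per row;
* ``ocs``      — optimal completion: missing cells are auxiliary variables,
  re-imputed each iteration as membership-weighted prototype averages.

With an all-observed mask the ``pds`` and ``ocs`` paths reproduce the
``complete`` path exactly (indicator multiplications by 1.0 and empty
imputation sets are float no-ops), which the test suite relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class FitConfig:
    """Fit hyper-parameters.

    n_clusters : number of clusters K, 2 <= K < n.
    m : fuzzifier, > 1 (2.0 default).
    max_iter : iteration cap T (300 default).
    tol : convergence tolerance on \\|Delta J\\| (1e-10 default).
    n_starts : random restarts; the best final objective wins (100 default).
    seed : master seed; restart streams are spawned from it.
    inner_prototype_steps : fixed-point sweeps of the prototype map per
        outer iteration (1 default).
    weight_init : 'one' (constraint-satisfying) or 'uniform' (1/p); inert
        either way since weights are recomputed before first use.
    distance_floor : guard for zero distances in the weight and membership
        updates.
    """

    n_clusters: int
    m: float = 2.0
    max_iter: int = 300
    tol: float = 1e-10
    n_starts: int = 100
    seed: int | None = None
    inner_prototype_steps: int = 1
    weight_init: str = "one"
    distance_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.m > 1.0:
            raise ValueError("fuzzifier m must be > 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.tol < 1.0:
            raise ValueError("tol must lie in (0, 1)")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.weight_init not in ("one", "uniform"):
            raise ValueError("weight_init must be 'one' or 'uniform'")


@dataclass
class ModelState:
    """Result of one coordinate-descent run."""

    U: np.ndarray
    V: np.ndarray
    Lambda: np.ndarray | None
    J_history: np.ndarray
    n_iter: int
    converged: bool
    completed: np.ndarray | None = None
    substep_J: list = field(default_factory=list)

    @property
    def objective(self) -> float:
        return float(self.J_history[-1])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "U": self.U.tolist(),
            "V": self.V.tolist(),
            "Lambda": None if self.Lambda is None else self.Lambda.tolist(),
            "J_history": np.asarray(self.J_history).tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelState":
        d = json.loads(Path(path).read_text())
        return cls(
            U=np.asarray(d["U"]),
            V=np.asarray(d["V"]),
            Lambda=None if d["Lambda"] is None else np.asarray(d["Lambda"]),
            J_history=np.asarray(d["J_history"]),
            n_iter=d["n_iter"],
            converged=d["converged"],
        )


# ---------------------------------------------------------------- updates


def kernel_matrix(X: np.ndarray, V: np.ndarray, two_sigma_sq: np.ndarray) -> np.ndarray:
    """Per-variable Gaussian kernel values, shape (K, n, p)."""
    diff = X[None, :, :] - V[:, None, :]
    return np.exp(-(diff**2) / two_sigma_sq[None, None, :])


def kernel_distances(
    X: np.ndarray, V: np.ndarray, two_sigma_sq: np.ndarray
) -> np.ndarray:
    """Feature-space squared distances ``2 (1 - K_j)``, shape (K, n, p)."""
    return 2.0 * (1.0 - kernel_matrix(X, V, two_sigma_sq))


def init_memberships(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random fuzzy memberships: i.i.d. uniforms, columns normalized to 1."""
    if K < 2:
        raise ValueError("need at least 2 clusters")
    if n < K:
        raise ValueError("need n >= K observations")
    U = rng.uniform(size=(K, n))
    return U / U.sum(axis=0, keepdims=True)


def init_prototypes(
    X: np.ndarray, U: np.ndarray, m: float, obs: np.ndarray | None = None
) -> np.ndarray:
    """Seed prototypes: plain fuzzy mean ``sum u^m x / sum u^m``.

    With an observation indicator, sums run over observed cells only.
    """
    W = U**m
    if obs is None:
        den = W.sum(axis=1, keepdims=True)
        num = W @ X
    else:
        den = W @ obs
        num = W @ (X * obs)
    if (den <= 0).any() or not np.isfinite(den).all():
        raise ValueError("degenerate memberships: empty cluster in prototype seed")
    return num / den


def prototype_step(
    X: np.ndarray,
    W: np.ndarray,
    V_old: np.ndarray,
    two_sigma_sq: np.ndarray,
    obs: np.ndarray | None = None,
    steps: int = 1,
) -> np.ndarray:
    """Fixed-point prototype map: kernel-weighted mean around the previous
    prototype, applied ``steps`` times (W = U**m)."""
    V = V_old
    for _ in range(steps):
        Km = kernel_matrix(X, V, two_sigma_sq)
        if obs is not None:
            Km = Km * obs[None, :, :]
        num = np.einsum("ki,kij,ij->kj", W, Km, X)
        den = np.einsum("ki,kij->kj", W, Km)
        if not np.isfinite(den).all() or (den <= 0).any():
            raise FloatingPointError("prototype update denominator vanished")
        V = num / den
    return V


def weight_step(
    W: np.ndarray,
    D: np.ndarray,
    obs: np.ndarray | None = None,
    distance_floor: float = 1e-12,
) -> np.ndarray:
    """Variable weights: geometric-mean closed form under the product-one
    constraint, computed in log-space.

    ``S_kj = sum_i u_ki^m d_kij`` (observed cells only when masked);
    ``lambda_kj = (prod_l S_kl)^{1/p} / S_kj``.
    """
    if obs is not None:
        D = D * obs[None, :, :]
    S = np.einsum("ki,kij->kj", W, D)
    S = np.maximum(S, distance_floor)
    logS = np.log(S)
    return np.exp(logS.mean(axis=1, keepdims=True) - logS)


def phi_squared(
    Lam: np.ndarray, D: np.ndarray, obs: np.ndarray | None = None
) -> np.ndarray:
    """Weighted kernelized squared distance per (cluster, observation).

    For masked data this is the unscaled partial sum over observed cells;
    the ``p / I_i`` rescale is applied only in the objective, since it
    cancels inside the membership ratios.
    """
    if obs is not None:
        D = D * obs[None, :, :]
    return np.einsum("kj,kij->ki", Lam, D)


def membership_step(
    phi2: np.ndarray, m: float, distance_floor: float = 1e-12
) -> np.ndarray:
    """Closed-form membership update from the squared distances.

    Columns with one or more (near-)zero distances split membership 1
    equally among the zero-distance clusters (the standard fuzzy c-means
    singularity convention).
    """
    zero = phi2 <= distance_floor
    logw = -np.log(np.maximum(phi2, distance_floor)) / (m - 1.0)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    U = w / w.sum(axis=0, keepdims=True)
    cols = zero.any(axis=0)
    if cols.any():
        z = zero[:, cols].astype(float)
        U[:, cols] = z / z.sum(axis=0, keepdims=True)
    return U


def objective(
    W: np.ndarray, phi2: np.ndarray, row_scale: np.ndarray | None = None
) -> float:
    """J = sum_k sum_i u_ki^m phi^2_ki, optionally row-rescaled (p / I_i)."""
    if row_scale is None:
        return float(np.sum(W * phi2))
    return float(np.sum(W * phi2 * row_scale[None, :]))


def ocs_impute_matrix(U: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership-weighted prototype averages, shape (n, p).

    ``x_ij = sum_k u_ki^m v_kj / sum_k u_ki^m`` — a convex combination of
    the prototype coordinates.
    """
    W = U**m
    den = W.sum(axis=0)
    if (den <= 0).any():
        raise ValueError("all memberships zero for some observation")
    return (W.T @ V) / den[:, None]


# ------------------------------------------------------------- fit loops


def coordinate_descent(
    X: np.ndarray,
    mask: np.ndarray | None,
    two_sigma_sq: np.ndarray,
    cfg: FitConfig,
    rng: np.random.Generator,
    mode: str = "complete",
    track_substeps: bool = False,
) -> ModelState:
    """One seeded run of the alternating optimization.

    Step order per iteration: prototypes (fixed-point), weights (closed
    form), memberships (closed form), then — OCS only — re-imputation of the
    missing cells; stop when \\|J_t+1 - J_t\\| <= tol or the iteration cap is
    reached.
    """
    if mode not in ("complete", "pds", "ocs"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if cfg.n_clusters >= n:
        raise ValueError("need n_clusters < n")
    ts = np.asarray(two_sigma_sq, dtype=float)
    floor = cfg.distance_floor

    obs = None
    row_scale = None
    if mode == "pds":
        if mask is None:
            raise ValueError("pds mode requires a mask")
        obs = (~mask).astype(float)
        counts = obs.sum(axis=1)
        if (counts == 0).any():
            raise ValueError("fully-missing row: partial distance undefined")
        row_scale = p / counts
        Xw = np.where(mask, 0.0, X)
    elif mode == "ocs":
        if mask is None:
            raise ValueError("ocs mode requires a mask")
        Xw = X  # replaced by the random completion below
    else:
        if np.isnan(X).any():
            raise ValueError("complete mode requires a fully observed matrix")
        Xw = X

    U = init_memberships(n, cfg.n_clusters, rng)
    if mode == "ocs":
        # random completion, uniform over each variable's observed range
        lo = np.min(np.where(mask, np.inf, X), axis=0)
        hi = np.max(np.where(mask, -np.inf, X), axis=0)
        r, c = np.nonzero(mask)
        Xw = X.copy()
        if r.size:
            Xw[r, c] = rng.uniform(lo[c], hi[c])
    W = U**cfg.m
    V = init_prototypes(Xw, U, cfg.m, obs)
    if cfg.weight_init == "one":
        Lam = np.ones((cfg.n_clusters, p))
    else:
        Lam = np.full((cfg.n_clusters, p), 1.0 / p)

    D = kernel_distances(Xw, V, ts)
    J_prev = objective(W, phi_squared(Lam, D, obs), row_scale)
    history = [J_prev]
    substeps: list = []
    converged = False
    n_iter = 0
    for t in range(cfg.max_iter):
        n_iter = t + 1
        V = prototype_step(Xw, W, V, ts, obs, steps=cfg.inner_prototype_steps)
        D = kernel_distances(Xw, V, ts)
        # substep diagnostics use the unscaled objective: the printed weight
        # update omits the p/I_i row rescale, so it is the exact conditional
        # minimizer of the unscaled masked criterion (the membership update
        # minimizes both, the rescale being constant per column)
        if track_substeps:
            j_v = objective(W, phi_squared(Lam, D, obs))
        Lam = weight_step(W, D, obs, floor)
        phi2 = phi_squared(Lam, D, obs)
        if track_substeps:
            j_lam = objective(W, phi2)
        U = membership_step(phi2, cfg.m, floor)
        W = U**cfg.m
        if track_substeps:
            j_u = objective(W, phi2)
            substeps.append((j_v, j_lam, j_u))
        if mode == "ocs":
            imputed = ocs_impute_matrix(U, V, cfg.m)
            Xw[mask] = imputed[mask]
            D = kernel_distances(Xw, V, ts)
            phi2 = phi_squared(Lam, D, obs)
        J = objective(W, phi2, row_scale)
        history.append(J)
        if abs(J - J_prev) <= cfg.tol:
            converged = True
            break
        J_prev = J

    return ModelState(
        U=U,
        V=V,
        Lambda=Lam,
        J_history=np.asarray(history),
        n_iter=n_iter,
        converged=converged,
        completed=Xw.copy() if mode == "ocs" else None,
        substep_J=substeps,
    )


def kfcm_descent(
    X: np.ndarray,
    two_sigma_sq: float,
    cfg: FitConfig,
    rng: np.random.Generator,
) -> ModelState:
    """Unweighted baseline with one full-vector Gaussian kernel.

    Same loop structure, scalar bandwidth, no variable weights: distances
    are ``1 - K(x_i, v_k)`` with ``K = exp(-||x - v||^2 / 2 sigma^2)``, the
    objective is ``2 sum u^m (1 - K)``.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("the baseline requires complete data")
    n, p = X.shape
    floor = cfg.distance_floor

    def kmat(V: np.ndarray) -> np.ndarray:  # (K, n)
        sq = ((X[None, :, :] - V[:, None, :]) ** 2).sum(axis=2)
        return np.exp(-sq / two_sigma_sq)

    U = init_memberships(n, cfg.n_clusters, rng)
    W = U**cfg.m
    V = init_prototypes(X, U, cfg.m)
    Km = kmat(V)
    J_prev = float(2.0 * np.sum(W * (1.0 - Km)))
    history = [J_prev]
    converged = False
    n_iter = 0
    for t in range(cfg.max_iter):
        n_iter = t + 1
        for _ in range(cfg.inner_prototype_steps):
            Km = kmat(V)
            num = np.einsum("ki,ki,ij->kj", W, Km, X)
            den = (W * Km).sum(axis=1, keepdims=True)
            V = num / den
        Km = kmat(V)
        U = membership_step(2.0 * (1.0 - Km), cfg.m, floor)
        W = U**cfg.m
        J = float(2.0 * np.sum(W * (1.0 - Km)))
        history.append(J)
        if abs(J - J_prev) <= cfg.tol:
            converged = True
            break
        J_prev = J
    return ModelState(
        U=U,
        V=V,
        Lambda=None,
        J_history=np.asarray(history),
        n_iter=n_iter,
        converged=converged,
    )


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Independent per-restart generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def partial_distances(
    X: np.ndarray,
    mask: np.ndarray,
    V: np.ndarray,
    Lam: np.ndarray,
    two_sigma_sq: np.ndarray,
) -> np.ndarray:
    """Partial local adaptive kernel distance, shape (K, n).

    ``phi_dp^2(x_i, v_k) = (p / I_i) sum_j lambda_kj 2(1 - K_j) I_ij`` —
    the sum runs over observed variables and is rescaled by the reciprocal
    of the observed proportion.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, p = X.shape
    counts = (~mask).sum(axis=1)
    if (counts == 0).any():
        raise ValueError("fully-missing row: partial distance undefined")
    Xw = np.where(mask, 0.0, X)
    D = kernel_distances(Xw, V, np.asarray(two_sigma_sq, float))
    obs = (~mask).astype(float)
    part = np.einsum("kj,kij,ij->ki", Lam, D, obs)
    return part * (p / counts)[None, :]
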