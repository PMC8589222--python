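"""Functional surface over the fitting engine and estimators.

The estimator classes in :mod:`kfcmiss.cluster` are the primary interface;
these functions are thin wrappers kept for script-style use and for direct
access to the individual coordinate-descent updates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._fitting import (
    FitConfig,
    ModelState,
    init_memberships as _init_memberships,
    init_prototypes,
    kernel_distances,
    membership_step,
    objective as _objective,
    ocs_impute_matrix,
    phi_squared,
    prototype_step,
    spawn_rngs,
    weight_step,
)
from .cluster import AdaptiveKernelFuzzyCMeans, KernelFuzzyCMeans
from .kernels import KernelSpec

__all__ = [
    "FitConfig",
    "ModelState",
    "init_memberships",
    "init_prototypes",
    "update_prototypes",
    "update_weights",
    "update_memberships",
    "objective",
    "fit_vkfcm",
    "multistart_fit",
    "fit_kfcm",
]


def init_memberships(n: int, K: int, seed=None) -> np.ndarray:
    """Random fuzzy partition matrix, columns summing to one."""
    return _init_memberships(n, K, np.random.default_rng(seed))


def update_prototypes(
    X: np.ndarray,
    U: np.ndarray,
    V_old: np.ndarray,
    spec: KernelSpec,
    cfg: FitConfig,
) -> np.ndarray:
    """One (or ``cfg.inner_prototype_steps``) fixed-point prototype sweeps."""
    return prototype_step(
        X, U**cfg.m, V_old, spec.two_sigma_sq, steps=cfg.inner_prototype_steps
    )


def update_weights(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, spec: KernelSpec, cfg: FitConfig
) -> np.ndarray:
    """Closed-form adaptive variable weights (product one per cluster)."""
    D = kernel_distances(X, V, spec.two_sigma_sq)
    return weight_step(U**cfg.m, D, distance_floor=cfg.distance_floor)


def update_memberships(
    X: np.ndarray, V: np.ndarray, Lam: np.ndarray, spec: KernelSpec, cfg: FitConfig
) -> np.ndarray:
    """Closed-form membership update from the weighted kernel distances."""
    D = kernel_distances(X, V, spec.two_sigma_sq)
    return membership_step(phi_squared(Lam, D), cfg.m, cfg.distance_floor)


def objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    Lam: np.ndarray,
    spec: KernelSpec,
    cfg: FitConfig,
) -> float:
    """J = sum_k sum_i u_ki^m sum_j lambda_kj 2 (1 - K_j(x_ij, v_kj))."""
    D = kernel_distances(X, V, spec.two_sigma_sq)
    return _objective(U**cfg.m, phi_squared(Lam, D))


def _estimator_from_config(cfg: FitConfig, spec: KernelSpec | None, n_starts: int):
    return AdaptiveKernelFuzzyCMeans(
        n_clusters=cfg.n_clusters,
        m=cfg.m,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        n_init=n_starts,
        bandwidths=None if spec is None else spec.two_sigma_sq,
        weight_init=cfg.weight_init,
        inner_prototype_steps=cfg.inner_prototype_steps,
        distance_floor=cfg.distance_floor,
        random_state=cfg.seed,
    )


def fit_vkfcm(
    X: np.ndarray, cfg: FitConfig, spec: KernelSpec | None = None
) -> ModelState:
    """Single-start fit of the adaptive kernel fuzzy c-means on complete data."""
    est = _estimator_from_config(cfg, spec, n_starts=1).fit(X)
    return est.best_state_


def multistart_fit(
    X: np.ndarray,
    cfg: FitConfig,
    spec: KernelSpec | None = None,
    labels: np.ndarray | None = None,
) -> tuple[ModelState, pd.DataFrame]:
    """Monte-Carlo multi-start: ``cfg.n_starts`` seeded restarts, best final
    objective wins; the summary has one row per start."""
    est = _estimator_from_config(cfg, spec, n_starts=cfg.n_starts).fit(X, y=labels)
    return est.best_state_, est.restarts_


def fit_kfcm(
    X: np.ndarray, cfg: FitConfig, bandwidth: float | None = None
) -> ModelState:
    """Unweighted full-vector-kernel baseline (single start per cfg.seed)."""
    est = KernelFuzzyCMeans(
        n_clusters=cfg.n_clusters,
        m=cfg.m,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        n_init=cfg.n_starts,
        bandwidth=bandwidth,
        inner_prototype_steps=cfg.inner_prototype_steps,
        distance_floor=cfg.distance_floor,
        random_state=cfg.seed,
    ).fit(X)
    return ModelState(
        U=est.membership_,
        V=est.cluster_centers_,
        Lambda=None,
        J_history=est.objective_history_,
        n_iter=est.n_iter_,
        converged=est.converged_,
    )
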