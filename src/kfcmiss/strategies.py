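"""Missing-data strategy wrappers: whole-data, partial-distance, optimal
completion, and central-imputation baselines.

Each ``fit_*`` function is a thin wrapper over
:class:`~kfcmiss.cluster.AdaptiveKernelFuzzyCMeans` with the corresponding
``missing_strategy``, returning a :class:`StrategyResult` that covers every
original row (including the rows the whole-data strategy held out of the
optimization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fitting import FitConfig, ModelState, partial_distances
from .cluster import AdaptiveKernelFuzzyCMeans, _central_impute
from .dataio import IncompleteDataset
from .kernels import KernelSpec

__all__ = [
    "StrategyResult",
    "partial_distance",
    "fit_wds",
    "fit_pds",
    "fit_ocs",
    "fit_strategy",
    "ocs_impute_cell",
    "impute_central",
]


@dataclass
class StrategyResult:
    """Clustering of an incomplete dataset, reported for every original row."""

    model: ModelState
    crisp_labels: np.ndarray
    memberships_full: np.ndarray
    completed_values: np.ndarray | None
    strategy_name: str
    diagnostics: dict = field(default_factory=dict)


def partial_distance(
    x_row: np.ndarray,
    mask_row: np.ndarray,
    v_k: np.ndarray,
    lambda_k: np.ndarray,
    spec: KernelSpec,
) -> float:
    """Partial local adaptive kernel distance of one row to one prototype:
    ``(p / I_i) sum_{j observed} lambda_kj 2 (1 - K_j(x_ij, v_kj))``."""
    x = np.asarray(x_row, dtype=float)[None, :]
    mask = np.asarray(mask_row, dtype=bool)[None, :]
    out = partial_distances(
        x, mask, np.asarray(v_k, float)[None, :], np.asarray(lambda_k, float)[None, :],
        spec.two_sigma_sq,
    )
    return float(out[0, 0])


def ocs_impute_cell(u_col: np.ndarray, v_col: np.ndarray, m: float) -> float:
    """Optimal-completion imputation of one cell: the membership-weighted
    average of the prototype coordinates, ``sum_k u_k^m v_k / sum_k u_k^m``."""
    w = np.asarray(u_col, dtype=float) ** m
    den = w.sum()
    if den <= 0:
        raise ValueError("all memberships zero")
    return float(w @ np.asarray(v_col, dtype=float) / den)


def impute_central(ds: IncompleteDataset, statistic: str = "mean") -> np.ndarray:
    """Fill each masked cell with the per-variable mean or median of the
    observed values."""
    return _central_impute(ds.values, ds.mask, statistic)


def fit_strategy(
    ds: IncompleteDataset,
    strategy: str,
    cfg: FitConfig,
    spec: KernelSpec | None = None,
) -> StrategyResult:
    """Fit one missing-data strategy and package the full-n result."""
    est = AdaptiveKernelFuzzyCMeans(
        n_clusters=cfg.n_clusters,
        m=cfg.m,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        n_init=cfg.n_starts,
        missing_strategy=strategy,
        bandwidths=None if spec is None else spec.two_sigma_sq,
        weight_init=cfg.weight_init,
        inner_prototype_steps=cfg.inner_prototype_steps,
        distance_floor=cfg.distance_floor,
        random_state=cfg.seed,
    ).fit(ds.values, y=ds.labels)
    return StrategyResult(
        model=est.best_state_,
        crisp_labels=est.labels_,
        memberships_full=est.membership_,
        completed_values=est.completed_X_,
        strategy_name=est.strategy_used_,
        diagnostics={
            "n_iter": est.n_iter_,
            "converged": est.converged_,
            "n_failed_starts": est.n_failed_starts_,
            "bandwidths": est.bandwidths_,
            "restarts": est.restarts_,
        },
    )


def fit_wds(
    ds: IncompleteDataset, cfg: FitConfig, spec: KernelSpec | None = None
) -> StrategyResult:
    """Whole-data strategy: cluster the complete rows, then assign each
    incomplete row to its nearest prototype under the partial distance."""
    return fit_strategy(ds, "wds", cfg, spec)


def fit_pds(
    ds: IncompleteDataset, cfg: FitConfig, spec: KernelSpec | None = None
) -> StrategyResult:
    """Partial-distance strategy: masked update equations throughout."""
    return fit_strategy(ds, "pds", cfg, spec)


def fit_ocs(
    ds: IncompleteDataset, cfg: FitConfig, spec: KernelSpec | None = None
) -> StrategyResult:
    """Optimal-completion strategy: missing cells are optimization
    variables; the result carries the completed matrix."""
    return fit_strategy(ds, "ocs", cfg, spec)
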