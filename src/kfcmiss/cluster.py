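"""Scikit-learn style estimators for adaptive kernel fuzzy c-means.

:class:`AdaptiveKernelFuzzyCMeans` is the main estimator: fuzzy c-means with
kernelization of the metric (per-variable Gaussian kernels) and per-cluster
adaptive variable weights constrained to product one.  It accepts matrices
with NaN cells and handles them with one of five strategies:

``wds``
    Whole-data strategy: fit on the complete rows only, then assign each
    incomplete row to the nearest prototype under the partial distance.
``pds``
    Partial-distance strategy: every update sums over observed cells only;
    the objective rescales each row's distance by p / I_i.
``ocs``
    Optimal-completion strategy: missing cells are auxiliary optimization
    variables, re-imputed each iteration as membership-weighted prototype
    averages; the fitted estimator exposes the completed matrix.
``mean`` / ``median``
    Central imputation baselines: fill per-variable, then run the plain fit.

:class:`KernelFuzzyCMeans` is the unweighted baseline with a single
full-vector Gaussian kernel (complete data only).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from . import _fitting as F
from .dataio import IncompleteDataset, split_complete_incomplete
from .kernels import KernelSpec, estimate_bandwidths, estimate_scalar_bandwidth

_STRATEGIES = ("wds", "pds", "ocs", "mean", "median")


def _validate_X(X, allow_nan: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    finite = np.isfinite(X)
    if allow_nan:
        if np.isinf(X).any():
            raise ValueError("X contains infinities")
    elif not finite.all():
        raise ValueError("X must be fully finite")
    return X


def _central_impute(X: np.ndarray, mask: np.ndarray, statistic: str) -> np.ndarray:
    """Fill masked cells with the per-variable mean or median of the
    observed values; observed cells are untouched."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    out = X.copy()
    for j in range(X.shape[1]):
        col = X[~mask[:, j], j]
        if col.size == 0:
            raise ValueError(f"variable {j} has no observed values")
        fill = np.mean(col) if statistic == "mean" else np.median(col)
        out[mask[:, j], j] = fill
    return out


class AdaptiveKernelFuzzyCMeans(ClusterMixin, BaseEstimator):
    """Kernel fuzzy c-means with adaptive variable weights and
    missing-data strategies.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of clusters K, 2 <= K < n.
    m : float, default=2.0
        Fuzzifier (> 1); larger values give softer memberships.
    max_iter : int, default=300
        Iteration cap per restart.
    tol : float, default=1e-10
        Convergence tolerance on the absolute objective change.
    n_init : int, default=100
        Random restarts; the solution with the smallest final objective wins.
    missing_strategy : {'wds', 'pds', 'ocs', 'mean', 'median'}, default='pds'
        How NaN cells are handled (ignored when X is complete).
    bandwidths : array-like of shape (p,), optional
        Per-variable Gaussian bandwidths (2 sigma_j^2).  Estimated from the
        data when omitted: WDS uses complete rows only, everything else uses
        all observed pairs.
    quantile_method : str, default='linear'
        Quantile convention for the bandwidth heuristic.
    weight_init : {'one', 'uniform'}, default='one'
        Initial variable weights (recomputed before first use either way).
    inner_prototype_steps : int, default=1
        Fixed-point sweeps of the prototype map per outer iteration.
    distance_floor : float, default=1e-12
        Numerical floor for zero distances.
    warn_missing_fraction : float, default=0.25
        Missing fraction above which the whole-data strategy warns.
    random_state : int, optional
        Master seed for memberships, completions, and restart streams.

    Attributes
    ----------
    cluster_centers_ : (K, p) prototypes in the original data space.
    feature_weights_ : (K, p) adaptive weights, product one per cluster.
    membership_ : (K, n) fuzzy memberships for every input row.
    labels_ : (n,) crisp assignment (argmax membership; incomplete WDS rows
        by nearest prototype under the partial distance).
    completed_X_ : (n, p) completed matrix (OCS and imputation baselines).
    objective_ : best final objective value J.
    objective_history_ : per-iteration J of the winning restart.
    n_iter_, converged_ : iterations and convergence flag of the winner.
    bandwidths_ : (p,) Gaussian bandwidths used.
    restarts_ : DataFrame with one row per restart (J, iterations,
        convergence, and external indices when y was supplied).
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        m: float = 2.0,
        max_iter: int = 300,
        tol: float = 1e-10,
        n_init: int = 100,
        missing_strategy: str = "pds",
        bandwidths=None,
        quantile_method: str = "linear",
        weight_init: str = "one",
        inner_prototype_steps: int = 1,
        distance_floor: float = 1e-12,
        warn_missing_fraction: float = 0.25,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.missing_strategy = missing_strategy
        self.bandwidths = bandwidths
        self.quantile_method = quantile_method
        self.weight_init = weight_init
        self.inner_prototype_steps = inner_prototype_steps
        self.distance_floor = distance_floor
        self.warn_missing_fraction = warn_missing_fraction
        self.random_state = random_state

    # ------------------------------------------------------------- internals

    def _config(self) -> F.FitConfig:
        return F.FitConfig(
            n_clusters=self.n_clusters,
            m=self.m,
            max_iter=self.max_iter,
            tol=self.tol,
            n_starts=self.n_init,
            seed=self.random_state,
            inner_prototype_steps=self.inner_prototype_steps,
            weight_init=self.weight_init,
            distance_floor=self.distance_floor,
        )

    def _wds_run(self, ds, complete, complete_idx, incomplete_idx, ts, cfg, rng):
        state = F.coordinate_descent(
            complete.values, None, ts, cfg, rng, mode="complete"
        )
        n = ds.n
        U_full = np.empty((cfg.n_clusters, n))
        labels = np.empty(n, dtype=int)
        U_full[:, complete_idx] = state.U
        labels[complete_idx] = np.argmax(state.U, axis=0)
        if incomplete_idx.size:
            pd2 = F.partial_distances(
                ds.values[incomplete_idx],
                ds.mask[incomplete_idx],
                state.V,
                state.Lambda,
                ts,
            )
            labels[incomplete_idx] = np.argmin(pd2, axis=0)
            U_full[:, incomplete_idx] = F.membership_step(
                pd2, cfg.m, cfg.distance_floor
            )
        return state, U_full, labels, None

    def _fit_one(self, rng, ds, strategy, ts, cfg, split=None):
        """One restart; returns (state, memberships_full, labels, completed)."""
        if strategy == "complete":
            st = F.coordinate_descent(ds.values, None, ts, cfg, rng, mode="complete")
            return st, st.U, np.argmax(st.U, axis=0), None
        if strategy == "wds":
            complete, _, cidx, iidx = split
            return self._wds_run(ds, complete, cidx, iidx, ts, cfg, rng)
        if strategy == "pds":
            st = F.coordinate_descent(ds.values, ds.mask, ts, cfg, rng, mode="pds")
            return st, st.U, np.argmax(st.U, axis=0), None
        if strategy == "ocs":
            st = F.coordinate_descent(ds.values, ds.mask, ts, cfg, rng, mode="ocs")
            return st, st.U, np.argmax(st.U, axis=0), st.completed
        if strategy in ("mean", "median"):
            filled = _central_impute(ds.values, ds.mask, strategy)
            st = F.coordinate_descent(filled, None, ts, cfg, rng, mode="complete")
            return st, st.U, np.argmax(st.U, axis=0), filled
        raise ValueError(f"unknown strategy {strategy!r}")

    # ------------------------------------------------------------------ API

    def fit(self, X, y=None):
        """Fit the clustering; X may contain NaN for missing cells.

        When ``y`` (a-priori class labels) is given it is used only for the
        per-restart external validity summary in ``restarts_``.
        """
        X = _validate_X(X, allow_nan=True)
        n, p = X.shape
        if not 2 <= self.n_clusters < n:
            raise ValueError("need 2 <= n_clusters < n_samples")
        mask = np.isnan(X)
        ds = IncompleteDataset(X, mask)
        cfg = self._config()

        has_missing = mask.any()
        strategy = self.missing_strategy if has_missing else "complete"
        if has_missing and strategy not in _STRATEGIES:
            raise ValueError(f"missing_strategy must be one of {_STRATEGIES}")

        split = None
        if strategy == "wds":
            if ds.missing_fraction > self.warn_missing_fraction:
                warnings.warn(
                    f"missing fraction {ds.missing_fraction:.2f} exceeds "
                    f"{self.warn_missing_fraction:.2f}; the whole-data strategy "
                    "discards incomplete rows and may be unreliable",
                    UserWarning,
                    stacklevel=2,
                )
            complete, incomplete, cidx, iidx = split_complete_incomplete(ds)
            if complete is None or complete.n < self.n_clusters:
                raise ValueError(
                    "whole-data strategy needs at least n_clusters complete rows"
                )
            split = (complete, incomplete, cidx, iidx)
            bw_source = complete
        else:
            if has_missing and (ds.observed_counts == 0).any():
                raise ValueError("fully-missing rows are not supported")
            bw_source = ds

        if self.bandwidths is not None:
            ts = np.asarray(self.bandwidths, dtype=float)
            if ts.shape != (p,) or (ts <= 0).any():
                raise ValueError("bandwidths must be p positive values")
        else:
            ts = estimate_bandwidths(bw_source, self.quantile_method).two_sigma_sq

        runs = []
        rows = []
        errors = []
        for s, rng in enumerate(F.spawn_rngs(cfg.seed, cfg.n_starts)):
            try:
                state, U_full, labels, completed = self._fit_one(
                    rng, ds, strategy, ts, cfg, split
                )
            except (FloatingPointError, ValueError) as err:
                errors.append((s, err))
                continue
            runs.append((state, U_full, labels, completed))
            row = {
                "start": s,
                "objective": state.objective,
                "n_iter": state.n_iter,
                "converged": state.converged,
            }
            if y is not None:
                from .evaluation import confusion_matrix, corrected_rand, f_measure, oerc

                cm = confusion_matrix(labels, np.asarray(y, dtype=int))
                row["corrected_rand"] = corrected_rand(cm)
                row["f_measure"] = f_measure(cm)
                if cm.counts.shape[0] == cm.counts.shape[1]:
                    row["oerc"] = oerc(cm)
            rows.append(row)
        if not runs:
            raise RuntimeError(f"all {cfg.n_starts} restarts failed: {errors[:3]}")

        best = int(np.argmin([st.objective for st, *_ in runs]))
        state, U_full, labels, completed = runs[best]

        self.strategy_used_ = strategy
        self.bandwidths_ = ts
        self.kernel_spec_ = KernelSpec(ts)
        self.cluster_centers_ = state.V
        self.feature_weights_ = state.Lambda
        self.membership_ = U_full
        self.labels_ = labels
        self.completed_X_ = completed
        self.objective_ = state.objective
        self.objective_history_ = np.asarray(state.J_history)
        self.n_iter_ = state.n_iter
        self.converged_ = state.converged
        self.best_state_ = state
        self.best_start_ = int(rows[best]["start"]) if rows else 0
        self.restarts_ = pd.DataFrame(rows)
        self.n_failed_starts_ = len(errors)
        self.n_features_in_ = p
        return self

    def _check_fitted(self):
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("estimator is not fitted")

    def transform_memberships(self, X) -> np.ndarray:
        """Fuzzy memberships of new rows (NaN allowed), shape (K, n)."""
        self._check_fitted()
        X = _validate_X(X, allow_nan=True)
        pd2 = F.partial_distances(
            X, np.isnan(X), self.cluster_centers_, self.feature_weights_,
            self.bandwidths_,
        )
        return F.membership_step(pd2, self.m, self.distance_floor)

    def predict(self, X) -> np.ndarray:
        """Crisp nearest-prototype assignment under the (partial) adaptive
        kernel distance; rows may contain NaN."""
        self._check_fitted()
        X = _validate_X(X, allow_nan=True)
        pd2 = F.partial_distances(
            X, np.isnan(X), self.cluster_centers_, self.feature_weights_,
            self.bandwidths_,
        )
        return np.argmin(pd2, axis=0)


class KernelFuzzyCMeans(ClusterMixin, BaseEstimator):
    """Baseline kernel fuzzy c-means with one full-vector Gaussian kernel.

    No variable weighting; complete data only.  ``bandwidth`` is the scalar
    2 sigma^2, estimated by the quantile heuristic on full-vector squared
    distances when omitted.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        *,
        m: float = 2.0,
        max_iter: int = 300,
        tol: float = 1e-10,
        n_init: int = 100,
        bandwidth: float | None = None,
        quantile_method: str = "linear",
        inner_prototype_steps: int = 1,
        distance_floor: float = 1e-12,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.bandwidth = bandwidth
        self.quantile_method = quantile_method
        self.inner_prototype_steps = inner_prototype_steps
        self.distance_floor = distance_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate_X(X, allow_nan=False)
        n, p = X.shape
        if not 2 <= self.n_clusters < n:
            raise ValueError("need 2 <= n_clusters < n_samples")
        bw = (
            float(self.bandwidth)
            if self.bandwidth is not None
            else estimate_scalar_bandwidth(X, self.quantile_method)
        )
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
        cfg = F.FitConfig(
            n_clusters=self.n_clusters,
            m=self.m,
            max_iter=self.max_iter,
            tol=self.tol,
            n_starts=self.n_init,
            seed=self.random_state,
            inner_prototype_steps=self.inner_prototype_steps,
            distance_floor=self.distance_floor,
        )
        states = [
            F.kfcm_descent(X, bw, cfg, rng)
            for rng in F.spawn_rngs(cfg.seed, cfg.n_starts)
        ]
        best = min(states, key=lambda s: s.objective)
        self.bandwidth_ = bw
        self.cluster_centers_ = best.V
        self.membership_ = best.U
        self.labels_ = np.argmax(best.U, axis=0)
        self.objective_ = best.objective
        self.objective_history_ = np.asarray(best.J_history)
        self.n_iter_ = best.n_iter
        self.converged_ = best.converged
        self.restarts_ = pd.DataFrame(
            {
                "start": range(len(states)),
                "objective": [s.objective for s in states],
                "n_iter": [s.n_iter for s in states],
                "converged": [s.converged for s in states],
            }
        )
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("estimator is not fitted")
        X = _validate_X(X, allow_nan=False)
        sq = ((X[None, :, :] - self.cluster_centers_[:, None, :]) ** 2).sum(axis=2)
        return np.argmin(sq, axis=0)
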