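"""Per-variable Gaussian kernels and the bandwidth estimation heuristic.

Each variable j gets its own Gaussian kernel
``K_j(x, v) = exp(-(x - v)^2 / 2 sigma_j^2)``.  The bandwidth parameter
stored is ``2 sigma_j^2``, estimated as the average of the 0.1 and 0.9
quantiles of the squared pairwise differences ``(x_ij - x_kj)^2`` over all
unordered pairs of observed entries of that variable.  Since ``K(x, x) = 1``
for the Gaussian kernel, the induced squared distance in feature space is
``2 (1 - K_j(x, v))``, bounded in [0, 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import IncompleteDataset


@dataclass
class KernelSpec:
    """Per-variable Gaussian bandwidths (the ``2 sigma_j^2`` terms)."""

    two_sigma_sq: np.ndarray

    def __post_init__(self) -> None:
        self.two_sigma_sq = np.asarray(self.two_sigma_sq, dtype=float)
        if self.two_sigma_sq.ndim != 1:
            raise ValueError("two_sigma_sq must be a 1-D array")
        if not np.isfinite(self.two_sigma_sq).all() or (self.two_sigma_sq <= 0).any():
            raise ValueError("all bandwidths must be strictly positive and finite")

    @property
    def p(self) -> int:
        return self.two_sigma_sq.size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.two_sigma_sq.tolist()))

    @classmethod
    def from_json(cls, path: str | Path) -> "KernelSpec":
        return cls(np.asarray(json.loads(Path(path).read_text()), dtype=float))


def _pair_quantile_bandwidth(
    x: np.ndarray, quantile_method: str, what: str
) -> float:
    """(q_0.1 + q_0.9)/2 of squared differences over unordered pairs of x."""
    if x.size < 2:
        raise ValueError(f"{what}: need at least 2 observed values")
    d = (x[:, None] - x[None, :]) ** 2
    iu = np.triu_indices(x.size, k=1)
    sq = d[iu]
    lo, hi = np.quantile(sq, [0.1, 0.9], method=quantile_method)
    bw = (lo + hi) / 2.0
    if bw <= 0:
        raise ValueError(f"{what}: zero bandwidth (constant column?)")
    return float(bw)


def estimate_bandwidths(
    ds: IncompleteDataset | np.ndarray, quantile_method: str = "linear"
) -> KernelSpec:
    """Estimate ``2 sigma_j^2`` per variable from observed pairs.

    For each variable j, squared differences are collected over all unordered
    pairs of rows where both entries are observed; the bandwidth is the mean
    of the 0.1 and 0.9 quantiles of that collection (linear-interpolation
    quantiles by default).
    """
    if isinstance(ds, np.ndarray):
        ds = IncompleteDataset(ds, np.isnan(ds))
    bws = np.empty(ds.p)
    for j in range(ds.p):
        bws[j] = _pair_quantile_bandwidth(
            ds.observed_column(j), quantile_method, f"variable {ds.variable_names[j]}"
        )
    return KernelSpec(bws)


def estimate_scalar_bandwidth(
    X: np.ndarray, quantile_method: str = "linear"
) -> float:
    """Scalar ``2 sigma^2`` for the full-vector Gaussian kernel.

    Same quantile rule, applied to full-vector squared Euclidean distances
    among complete rows.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("scalar bandwidth requires complete rows")
    d = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    iu = np.triu_indices(X.shape[0], k=1)
    sq = d[iu]
    if sq.size < 1:
        raise ValueError("need at least 2 rows")
    lo, hi = np.quantile(sq, [0.1, 0.9], method=quantile_method)
    bw = (lo + hi) / 2.0
    if bw <= 0:
        raise ValueError("zero bandwidth: all rows identical")
    return float(bw)


def gaussian_kernel_1d(x: float, v: float, spec: KernelSpec, j: int) -> float:
    """``K_j(x, v) = exp(-(x - v)^2 / two_sigma_sq[j])``, in (0, 1]."""
    if not (np.isfinite(x) and np.isfinite(v)):
        raise ValueError("kernel inputs must be finite")
    return float(np.exp(-((x - v) ** 2) / spec.two_sigma_sq[j]))


def kernel_distance_1d(x: float, v: float, spec: KernelSpec, j: int) -> float:
    """Feature-space squared distance ``2 (1 - K_j(x, v))``, in [0, 2)."""
    return 2.0 * (1.0 - gaussian_kernel_1d(x, v, spec, j))
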