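"""Seeded Gaussian-mixture generators for reproducible benchmarks.

Two frozen presets mimic the structure of the classic benchmark datasets:
``iris_like_spec`` gives three equal clusters of 50 in four variables, one
linearly separable from two closer ones; ``thyroid_like_spec`` gives one
dominant cluster (150) plus two small, more dispersed ones (35 and 30) in
five variables.  Diagonal covariances only — correlation structure is not
needed to exercise any of the update equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MixtureSpec:
    """K-component diagonal Gaussian mixture specification."""

    sizes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 2:
            raise ValueError("means and sds must be (K, p) matrices")
        if self.sizes.shape != (self.means.shape[0],):
            raise ValueError("sizes must have one entry per component")
        if (self.sizes < 1).any():
            raise ValueError("component sizes must be >= 1")
        if (self.sds <= 0).any():
            raise ValueError("component sds must be positive")

    @property
    def n(self) -> int:
        return int(self.sizes.sum())

    @property
    def p(self) -> int:
        return self.means.shape[1]


def generate_mixture(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the mixture; returns (X, labels) in generation order,
    deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    blocks = []
    labels = []
    for k, size in enumerate(spec.sizes):
        blocks.append(rng.normal(spec.means[k], spec.sds[k], size=(size, spec.p)))
        labels.append(np.full(size, k, dtype=int))
    return np.vstack(blocks), np.concatenate(labels)


def iris_like_spec(seed: int = 0) -> MixtureSpec:
    """Three clusters of 50 in 4 variables: component 0 well separated,
    components 1 and 2 adjacent (strongest contrast on the last two
    variables, echoing petal measurements)."""
    return MixtureSpec(
        sizes=[50, 50, 50],
        means=[
            [5.0, 3.4, 1.5, 0.25],
            [5.9, 2.8, 4.3, 1.30],
            [6.9, 3.1, 5.8, 2.20],
        ],
        sds=[
            [0.35, 0.38, 0.18, 0.10],
            [0.40, 0.30, 0.35, 0.20],
            [0.40, 0.30, 0.35, 0.20],
        ],
        seed=seed,
    )


def thyroid_like_spec(seed: int = 0) -> MixtureSpec:
    """One dominant tight cluster (150) and two small dispersed ones
    (35, 30) in 5 variables, on heterogeneous scales."""
    return MixtureSpec(
        sizes=[150, 35, 30],
        means=[
            [110.0, 9.0, 1.7, 1.3, 2.5],
            [95.0, 18.0, 5.5, 1.0, 1.5],
            [125.0, 4.0, 1.0, 8.0, 15.0],
        ],
        sds=[
            [8.0, 2.0, 0.45, 0.45, 1.5],
            [12.0, 4.0, 1.60, 0.50, 1.5],
            [10.0, 1.5, 0.40, 5.00, 8.0],
        ],
        seed=seed,
    )
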