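"""MCAR (missing completely at random) mask generation.

Each cell of an n x p grid is masked independently with probability theta,
independent of the data values — the Bernoulli mechanism P(M | X, theta) =
P(M | theta).  An optional row guard resamples any fully-masked row so that
every observation keeps at least one observed variable (partial distances
and nearest-prototype assignment are undefined for empty rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import IncompleteDataset

logger = logging.getLogger(__name__)


@dataclass
class MissingConfig:
    """Parameters of the MCAR mechanism.

    theta : per-cell missingness probability in [0, 1].
    seed : integer seed for the mask generator.
    row_guard : when True, fully-missing rows are resampled.
    """

    theta: float
    seed: int = 0
    row_guard: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def generate_mcar_mask(n: int, p: int, cfg: MissingConfig) -> np.ndarray:
    """Draw an n x p boolean MCAR mask (True = missing).

    Deterministic given ``cfg.seed``.  With ``row_guard`` on, any row that
    comes out fully masked is redrawn from the same stream until at least one
    cell stays observed (the resampling count is logged).
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    if cfg.row_guard and cfg.theta >= 1.0:
        raise ValueError("theta = 1 with row_guard is unsatisfiable")
    rng = np.random.default_rng(cfg.seed)
    mask = rng.random((n, p)) < cfg.theta
    if cfg.row_guard:
        resamples = 0
        full = np.where(mask.all(axis=1))[0]
        while full.size:
            mask[full] = rng.random((full.size, p)) < cfg.theta
            resamples += full.size
            full = full[mask[full].all(axis=1)]
        if resamples:
            logger.info("row_guard resampled %d fully-missing row draw(s)", resamples)
    return mask


def apply_mask(
    X: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray | None = None,
    variable_names: list[str] | None = None,
) -> IncompleteDataset:
    """Mask a complete matrix, keeping observed cells bit-identical to X."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape != mask.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs mask {mask.shape}")
    if np.isnan(X).any():
        raise ValueError("X must be complete (no pre-existing missing cells)")
    return IncompleteDataset(
        X, mask, variable_names or [], labels=labels
    )
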