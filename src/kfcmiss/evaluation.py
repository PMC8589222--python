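"""External cluster validity indices and imputation diagnostics.

Implements the adjusted-for-chance Rand index (Hubert–Arabie form), the
class-weighted best-match F-measure, the overall error rate of
classification (OERC) after an optimal one-to-one cluster-to-class mapping,
a per-cluster per-variable consistency statistic comparing moments before
and after imputation, and the correlation / standard-deviation diagnostics
used to expose variance underestimation by central imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .dataio import IncompleteDataset

__all__ = [
    "ConfusionMatrix",
    "ConsistencyReport",
    "crisp_partition",
    "confusion_matrix",
    "map_clusters_to_classes",
    "corrected_rand",
    "f_measure",
    "oerc",
    "consistency",
    "imputation_diagnostics",
    "truncate_toward_zero",
]


@dataclass
class ConfusionMatrix:
    """Cluster-vs-class contingency table: rows = clusters, columns = the
    a-priori classes."""

    counts: np.ndarray
    cluster_labels: list | None = None
    class_labels: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 2-D table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def crisp_partition(U: np.ndarray) -> np.ndarray:
    """Defuzzify memberships: argmax per column, ties to the lowest index."""
    U = np.asarray(U, dtype=float)
    return np.argmax(U, axis=0)


def confusion_matrix(
    pred: np.ndarray,
    true: np.ndarray,
    K: int | None = None,
    C: int | None = None,
) -> ConfusionMatrix:
    """Contingency table ``counts[k, c] = #{i : pred_i = k, true_i = c}``."""
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    K = int(pred.max()) + 1 if K is None else K
    C = int(true.max()) + 1 if C is None else C
    counts = np.zeros((K, C), dtype=int)
    np.add.at(counts, (pred, true), 1)
    return ConfusionMatrix(counts)


def map_clusters_to_classes(cm: ConfusionMatrix) -> np.ndarray:
    """One-to-one cluster -> class permutation maximizing the mapped
    diagonal (optimal assignment); requires as many clusters as classes."""
    K, C = cm.counts.shape
    if K != C:
        raise ValueError("cluster-to-class mapping requires K = C")
    rows, cols = linear_sum_assignment(-cm.counts)
    mapping = np.empty(K, dtype=int)
    mapping[rows] = cols
    return mapping


def corrected_rand(cm: ConfusionMatrix) -> float:
    """Adjusted-for-chance Rand index from the contingency table.

    Pair-counting form: with ``S = sum_kc C(n_kc, 2)``, row/column pair sums
    ``A``/``B`` and ``N = C(n, 2)``, the index is
    ``(S - A B / N) / ((A + B)/2 - A B / N)``; 1 means identical partitions,
    values near 0 chance-level agreement.
    """
    counts = cm.counts
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 observations")
    S = comb(counts, 2).sum()
    A = comb(counts.sum(axis=1), 2).sum()
    B = comb(counts.sum(axis=0), 2).sum()
    expected = A * B / comb(n, 2)
    denom = (A + B) / 2.0 - expected
    if denom == 0:  # single-cluster vs single-class degenerate case
        return 1.0 if S == expected else 0.0
    return float((S - expected) / denom)


def _f1(counts: np.ndarray, k: int, c: int) -> float:
    if counts[k, c] == 0:
        return 0.0
    precision = counts[k, c] / counts[k].sum()
    recall = counts[k, c] / counts[:, c].sum()
    return 2.0 * precision * recall / (precision + recall)


def f_measure(cm: ConfusionMatrix) -> float:
    """Class-weighted best-match F-measure.

    ``FM = sum_c (n_c / n) max_k F1(k, c)`` with precision = cell/row sum
    and recall = cell/column sum.  Empty classes are skipped with a warning.
    """
    counts = cm.counts
    n = counts.sum()
    total = 0.0
    for c in range(counts.shape[1]):
        n_c = counts[:, c].sum()
        if n_c == 0:
            warnings.warn(f"class {c} is empty; skipped in F-measure", UserWarning)
            continue
        total += (n_c / n) * max(
            _f1(counts, k, c) for k in range(counts.shape[0])
        )
    return float(total)


def oerc(cm: ConfusionMatrix) -> float:
    """Overall error rate of classification: the misclassified fraction
    after the optimal one-to-one cluster-to-class mapping."""
    mapping = map_clusters_to_classes(cm)
    mapped_diag = cm.counts[np.arange(len(mapping)), mapping].sum()
    return float(1.0 - mapped_diag / cm.n)


@dataclass
class ConsistencyReport:
    """Per-cluster per-variable standardized moment differences d_k(j)
    between the observed data and the completed data."""

    d: np.ndarray
    mean_before: np.ndarray
    var_before: np.ndarray
    mean_after: np.ndarray
    var_after: np.ndarray

    @property
    def max(self) -> float:
        return float(np.nanmax(self.d))


def consistency(
    ds_before: IncompleteDataset,
    completed: np.ndarray,
    labels: np.ndarray,
    denominator: str = "sqrt",
    ddof: int = 1,
) -> ConsistencyReport:
    """Consistency of imputed values with each variable's original scale.

    For cluster k and variable j, let (mu0, s0^2) be mean and variance of
    the *observed* cells of the rows assigned to k, and (mu1, s1^2) the same
    moments over *all* cells of those rows in the completed matrix.  Then

        d_k(j) = |mu0 - mu1| / sqrt(s0^2 + s1^2)        (default), or
        d_k(j) = |mu0 - mu1| / (s0^2 + s1^2)            (denominator='sum').

    Values near zero indicate imputations consistent with the original
    scale.  Cells with fewer than 2 observed values yield NaN with a
    warning.  Sample variance (ddof=1) by default.
    """
    if denominator not in ("sqrt", "sum"):
        raise ValueError("denominator must be 'sqrt' or 'sum'")
    completed = np.asarray(completed, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if completed.shape != ds_before.values.shape:
        raise ValueError("completed matrix shape mismatch")
    if labels.shape != (ds_before.n,):
        raise ValueError("labels must cover every row")
    K = labels.max() + 1
    p = ds_before.p
    d = np.full((K, p), np.nan)
    mu0 = np.full((K, p), np.nan)
    s0 = np.full((K, p), np.nan)
    mu1 = np.full((K, p), np.nan)
    s1 = np.full((K, p), np.nan)
    for k in range(K):
        rows = labels == k
        for j in range(p):
            obs = rows & ~ds_before.mask[:, j]
            if obs.sum() < 2:
                warnings.warn(
                    f"cluster {k}, variable {j}: fewer than 2 observed values; "
                    "consistency undefined",
                    UserWarning,
                )
                continue
            before = ds_before.values[obs, j]
            after = completed[rows, j]
            mu0[k, j] = before.mean()
            s0[k, j] = before.var(ddof=ddof)
            mu1[k, j] = after.mean()
            s1[k, j] = after.var(ddof=ddof)
            num = abs(mu0[k, j] - mu1[k, j])
            den = s0[k, j] + s1[k, j]
            if denominator == "sqrt":
                den = math.sqrt(den)
            d[k, j] = 0.0 if (num == 0.0 and den == 0.0) else num / den
    return ConsistencyReport(d, mu0, s0, mu1, s1)


def imputation_diagnostics(
    complete_original: np.ndarray,
    completed: np.ndarray,
    variable_pair: tuple[int, int],
) -> dict:
    """Pearson correlation of a variable pair and per-variable standard
    deviations, before vs after imputation."""
    a = np.asarray(complete_original, dtype=float)
    b = np.asarray(completed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    j1, j2 = variable_pair
    for M, tag in ((a, "original"), (b, "completed")):
        if np.std(M[:, j1]) == 0 or np.std(M[:, j2]) == 0:
            raise ValueError(f"zero variance in the {tag} matrix: correlation undefined")
    return {
        "correlation_before": float(np.corrcoef(a[:, j1], a[:, j2])[0, 1]),
        "correlation_after": float(np.corrcoef(b[:, j1], b[:, j2])[0, 1]),
        "sd_before": (float(a[:, j1].std(ddof=1)), float(a[:, j2].std(ddof=1))),
        "sd_after": (float(b[:, j1].std(ddof=1)), float(b[:, j2].std(ddof=1))),
    }


def truncate_toward_zero(x: float, decimals: int) -> float:
    """Truncate (not round) toward zero at the given decimal count.

    A relative epsilon absorbs binary floating-point artifacts so that,
    e.g., an exact 0.1 truncates to 0.1000 rather than 0.0999.
    """
    scaled = x * 10.0**decimals
    nudge = math.copysign(1e-9 * max(1.0, abs(scaled)), scaled)
    return math.trunc(scaled + nudge) / 10.0**decimals
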