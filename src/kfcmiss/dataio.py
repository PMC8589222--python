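"""Reading, writing and partitioning of incomplete numeric datasets.

An incomplete dataset is a rectangular numeric matrix (rows = observations,
columns = variables) together with a binary missing-indicator mask
``m_ij`` (1 = missing).  Masked cells are stored as NaN and are never used
in arithmetic; all downstream computation consults the mask, not the
sentinel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_NA_MARKERS = frozenset({"NA", "", "NaN", "na"})


class DataFormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class IncompleteDataset:
    """Numeric matrix plus missing-value mask and optional class labels.

    Attributes
    ----------
    values : (n, p) float array
        Data matrix.  Cells where ``mask`` is True hold NaN.
    mask : (n, p) bool array
        True where the value is missing (the indicator ``m_ij = 1``).
    variable_names : list of str
        Column names, length p.
    labels : (n,) int array or None
        Optional a-priori class labels, coded 0..C-1 in order of first
        appearance.
    label_names : list or None
        Original label categories, index-aligned with the integer codes.
    """

    values: np.ndarray
    mask: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    label_names: list | None = None
    validate_columns: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("dataset must have at least one row and one column")
        if not self.variable_names:
            self.variable_names = [f"V{j + 1}" for j in range(p)]
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must equal number of columns")
        if self.validate_columns:
            observed_per_col = (~self.mask).sum(axis=0)
            if (observed_per_col < 2).any():
                bad = [
                    self.variable_names[j]
                    for j in np.where(observed_per_col < 2)[0]
                ]
                raise ValueError(
                    "every variable needs at least 2 observed values for "
                    f"bandwidth estimation; offending column(s): {bad}"
                )
        # keep the sentinel well-defined and inert
        self.values = self.values.copy()
        self.values[self.mask] = np.nan
        if np.isnan(self.values[~self.mask]).any():
            raise ValueError("observed (unmasked) cells must be finite numbers")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be a length-n vector")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def observed_counts(self) -> np.ndarray:
        """Per-row count of observed cells, ``I_i = sum_j (1 - m_ij)``."""
        return (~self.mask).sum(axis=1)

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean())

    def observed_column(self, j: int) -> np.ndarray:
        """Observed values of variable ``j`` (mask applied)."""
        return self.values[~self.mask[:, j], j]


def _encode_labels(raw: pd.Series) -> tuple[np.ndarray, list]:
    names: list = []
    codes = np.empty(len(raw), dtype=int)
    lookup: dict = {}
    for i, v in enumerate(raw):
        if v not in lookup:
            lookup[v] = len(names)
            names.append(v)
        codes[i] = lookup[v]
    return codes, names


def read_dataset(
    path: str | Path,
    na_markers: set[str] | frozenset[str] = DEFAULT_NA_MARKERS,
    label_column: str | None = None,
) -> IncompleteDataset:
    """Read a CSV file (header row required) into an :class:`IncompleteDataset`.

    Cells matching one of ``na_markers`` (after whitespace strip,
    case-sensitive) become missing.  ``label_column``, if given, is removed
    from the numeric block and returned as integer class labels.
    """
    path = Path(path)
    with path.open() as fh:
        header = next(csv.reader(fh))
    seen: set[str] = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:
        raise DataFormatError(f"duplicate header names: {dupes}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    labels = label_names = None
    if label_column is not None:
        if label_column not in df.columns:
            raise DataFormatError(f"label column {label_column!r} not in header")
        labels, label_names = _encode_labels(df[label_column])
        df = df.drop(columns=[label_column])
    n, p = df.shape
    values = np.empty((n, p), dtype=float)
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in na_markers:
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"cell at row {i + 1}, column {col!r} is not numeric "
                    f"nor a missing marker: {cell!r}"
                ) from None
    return IncompleteDataset(
        values, mask, list(df.columns), labels=labels, label_names=label_names
    )


def write_dataset(
    ds: IncompleteDataset, path: str | Path, na_marker: str = "NA"
) -> None:
    """Write dataset to CSV, masked cells as ``na_marker``; labels appended
    as a ``label`` column when present."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(ds.variable_names)
        if ds.labels is not None:
            header.append("label")
        writer.writerow(header)
        for i in range(ds.n):
            row = [
                na_marker if ds.mask[i, j] else repr(float(ds.values[i, j]))
                for j in range(ds.p)
            ]
            if ds.labels is not None:
                name = (
                    ds.label_names[ds.labels[i]]
                    if ds.label_names is not None
                    else ds.labels[i]
                )
                row.append(name)
            writer.writerow(row)


def write_mask(ds: IncompleteDataset, path: str | Path) -> None:
    """Companion 0/1 mask CSV (same shape and header as the data)."""
    pd.DataFrame(ds.mask.astype(int), columns=ds.variable_names).to_csv(
        path, index=False
    )


def split_complete_incomplete(
    ds: IncompleteDataset,
) -> tuple[IncompleteDataset | None, IncompleteDataset | None, np.ndarray, np.ndarray]:
    """Split rows into the complete-case block and the incomplete block.

    Returns ``(complete, incomplete, complete_idx, incomplete_idx)`` where the
    index arrays map subset rows back to the original row positions.  Either
    subset may be None when empty.  A fully-missing row is an error: no
    partial distance is computable for it.
    """
    counts = ds.observed_counts
    if (counts == 0).any():
        bad = np.where(counts == 0)[0].tolist()
        raise ValueError(
            f"row(s) {bad} are fully missing; re-generate the mask or drop them"
        )
    complete_idx = np.where(counts == ds.p)[0]
    incomplete_idx = np.where(counts < ds.p)[0]

    def _subset(idx: np.ndarray) -> IncompleteDataset | None:
        if idx.size == 0:
            return None
        # subsets may legitimately leave a column nearly unobserved;
        # bandwidth estimation re-validates where it matters
        return IncompleteDataset(
            ds.values[idx],
            ds.mask[idx],
            list(ds.variable_names),
            labels=None if ds.labels is None else ds.labels[idx],
            label_names=ds.label_names,
            validate_columns=False,
        )

    return _subset(complete_idx), _subset(incomplete_idx), complete_idx, incomplete_idx


def write_completed(
    ds: IncompleteDataset,
    imputed_values: np.ndarray,
    path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    """Serialize a completed matrix; observed cells must be untouched.

    Writes a plain CSV with no missing markers, plus a companion mask CSV
    recording which cells were imputed (defaults to ``<path>.mask.csv``).
    """
    imputed_values = np.asarray(imputed_values, dtype=float)
    if imputed_values.shape != ds.values.shape:
        raise ValueError("imputed matrix shape mismatch")
    obs = ~ds.mask
    if not np.array_equal(imputed_values[obs], ds.values[obs]):
        raise ValueError("imputed matrix disagrees with observed cells")
    if not np.isfinite(imputed_values).all():
        raise ValueError("completed matrix must be fully finite")
    path = Path(path)
    pd.DataFrame(imputed_values, columns=ds.variable_names).to_csv(path, index=False)
    if mask_path is None:
        mask_path = path.with_suffix(path.suffix + ".mask.csv")
    write_mask(ds, mask_path)
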