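"""Cell-level signal intensities, QC filtering and empirical quantile features.

Quantitative pathology platforms report a protein signal intensity for every
segmented cell in a tissue sample.  Instead of collapsing a subject's cell
signal intensity (CSI) distribution into its mean (the conventional "mean
signal intensity" marker, here ``ccmsi``), this module summarises the whole
distribution by its empirical quantile function evaluated on a grid of
probabilities.  Each quantile ``Q_n(p)`` then becomes one candidate predictor
of outcome.

The empirical quantile is the pure order statistic (inverse ECDF, no
interpolation): for a sample of size ``n`` and probability ``p`` in (0, 1) it
returns the ``k``-th smallest observation with ``k = ceil(n * p)``.  Every
returned value is therefore an actual observed cell intensity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "CellSample",
    "QuantileGrid",
    "QuantileMatrix",
    "DEFAULT_GRID",
    "read_cell_table",
    "qc_filter",
    "empirical_quantile",
    "build_quantile_matrix",
    "compartment_mean",
    "QuantileFeaturizer",
]


@dataclass(frozen=True)
class CellSample:
    """One subject's vector of per-cell signal intensities."""

    subject_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(
                f"subject {self.subject_id!r}: intensities must be a "
                "non-empty 1-d array"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"subject {self.subject_id!r}: non-finite intensities"
            )
        object.__setattr__(self, "intensities", arr)

    @property
    def n_cells(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class QuantileGrid:
    """Strictly increasing probabilities in (0, 1) at which quantiles are taken."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("grid probabilities must lie strictly in (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("grid probabilities must be strictly increasing")
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return int(self.probabilities.size)

    def __iter__(self):
        return iter(self.probabilities)

    def labels(self) -> list[str]:
        """Column labels like ``q05`` ... ``q95``, ``q99``."""
        return [f"q{round(100 * p):02d}" for p in self.probabilities]


def _default_grid() -> QuantileGrid:
    # every 5th percentile from the 5th through the 95th, plus the 99th
    probs = np.concatenate([np.arange(1, 20) * 0.05, [0.99]])
    return QuantileGrid(np.round(probs, 2))


DEFAULT_GRID: QuantileGrid = _default_grid()


@dataclass(frozen=True)
class QuantileMatrix:
    """Subjects x probability-grid matrix of empirical quantile values."""

    subject_ids: tuple[str, ...]
    grid: QuantileGrid
    values: np.ndarray  # shape (n_subjects, len(grid))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subject_ids), len(self.grid)):
            raise ValueError("values shape inconsistent with ids and grid")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, p: float) -> np.ndarray:
        """Per-subject values of the quantile at probability ``p``."""
        j = int(np.argmin(np.abs(self.grid.probabilities - p)))
        if not math.isclose(self.grid.probabilities[j], p, abs_tol=1e-9):
            raise KeyError(f"probability {p} not on the grid")
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.grid.labels(),
        )


def read_cell_table(
    path: str | Path,
    *,
    subject_col: str = "subject_id",
    intensity_col: str = "intensity",
    sep: str | None = None,
    log_transform: bool = False,
) -> list[CellSample]:
    """Read a long-format cell table (CSV/TSV) into per-subject samples.

    One row per cell.  Row order within a subject is preserved; rows with a
    non-numeric or missing intensity are dropped with a logged count, as are
    exact duplicate rows (kept — duplicates are counted but retained, since a
    repeated (subject, cell) row may be a genuine distinct cell; see the
    project methods note).

    Parameters
    ----------
    path : str or Path
        Delimited text file with at least the subject and intensity columns.
    subject_col, intensity_col : str
        Column names; defaults ``subject_id`` / ``intensity``.
    sep : str, optional
        Field separator; inferred from the file extension when omitted
        (``.tsv``/``.txt`` -> tab, otherwise comma).
    log_transform : bool
        Apply ``log(1 + x)`` to intensities before any downstream use.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (subject_col, intensity_col) if c not in df.columns]
    if missing:
        raise KeyError(
            f"{path.name}: required column(s) {missing} not found; "
            f"available: {list(df.columns)}"
        )
    n_dup = int(df.duplicated().sum())
    if n_dup:
        logger.info("%s: %d exact duplicate rows retained", path.name, n_dup)
    raw = df[intensity_col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        logger.warning(
            "%s: dropped %d rows with non-numeric intensity", path.name, int(bad.sum())
        )
    df = df.loc[~bad.to_numpy()].copy()
    df[intensity_col] = values[~bad].astype(float)
    if df.empty:
        raise ValueError(f"{path.name}: no parseable intensity rows")
    if log_transform:
        df[intensity_col] = np.log1p(df[intensity_col])
    samples = [
        CellSample(str(sid), grp[intensity_col].to_numpy())
        for sid, grp in df.groupby(subject_col, sort=False)
    ]
    return samples


def qc_filter(
    samples: Iterable[CellSample], min_cells: int = 20
) -> list[CellSample]:
    """Retain samples with at least ``min_cells`` cells.

    Tissue cores with very few segmented cells give unstable quantile
    estimates; the default threshold of 20 cells mirrors standard tissue
    microarray quality control.  Excluded subject ids are logged.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    samples = list(samples)
    kept = [s for s in samples if s.n_cells >= min_cells]
    excluded = [s.subject_id for s in samples if s.n_cells < min_cells]
    if excluded:
        logger.info(
            "QC: excluded %d subject(s) with < %d cells: %s",
            len(excluded), min_cells, ", ".join(excluded[:20]),
        )
    if not kept:
        logger.warning("QC: no samples passed the %d-cell minimum", min_cells)
    return kept


def empirical_quantile(intensities: Sequence[float] | np.ndarray, p: float) -> float:
    """Inverse-ECDF sample quantile: the ``ceil(n*p)``-th order statistic.

    No interpolation is performed, so the result is always an element of the
    sample.  ``p`` must lie strictly in (0, 1).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    n = x.size
    # fudge guards against float round-off when n*p is an exact integer
    k = int(math.ceil(n * p - 1e-12))
    k = min(max(k, 1), n)
    return float(np.partition(x, k - 1)[k - 1])


def _quantile_row(x: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """All grid quantiles of one sample with a single sort."""
    xs = np.sort(x)
    n = xs.size
    k = np.ceil(n * probs - 1e-12).astype(int)
    np.clip(k, 1, n, out=k)
    return xs[k - 1]


def build_quantile_matrix(
    samples: Sequence[CellSample], grid: QuantileGrid = DEFAULT_GRID
) -> QuantileMatrix:
    """Evaluate the empirical quantile function of every sample on ``grid``."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    probs = grid.probabilities
    values = np.vstack([_quantile_row(s.intensities, probs) for s in samples])
    return QuantileMatrix(
        subject_ids=tuple(s.subject_id for s in samples), grid=grid, values=values
    )


def compartment_mean(sample: CellSample) -> float:
    """Arithmetic mean of a sample's cell intensities (the ccMSI comparator)."""
    if sample.n_cells == 0:
        raise ValueError("empty sample")
    return float(np.mean(sample.intensities))


class QuantileFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a long-format cell table into per-subject quantile features.

    A thin sklearn transformer over :func:`qc_filter`,
    :func:`build_quantile_matrix` and :func:`compartment_mean`: the output is
    a wide DataFrame with one row per QC-passing subject and columns
    ``q05 ... q95, q99`` (or the configured grid), ``ccmsi`` and ``n_cells``.

    Parameters
    ----------
    probabilities : array-like of float, optional
        Quantile grid; defaults to every 5th percentile from the 5th to the
        95th plus the 99th (20 probabilities).
    min_cells : int, default 20
        QC minimum number of cells per subject.
    subject_col, intensity_col : str
        Column names in the long input table.
    log_transform : bool, default False
        Apply ``log1p`` to intensities before computing features.
    """

    def __init__(
        self,
        probabilities=None,
        min_cells: int = 20,
        subject_col: str = "subject_id",
        intensity_col: str = "intensity",
        log_transform: bool = False,
    ):
        self.probabilities = probabilities
        self.min_cells = min_cells
        self.subject_col = subject_col
        self.intensity_col = intensity_col
        self.log_transform = log_transform

    def _grid(self) -> QuantileGrid:
        if self.probabilities is None:
            return DEFAULT_GRID
        return QuantileGrid(np.asarray(self.probabilities, dtype=float))

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileFeaturizer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a long-format DataFrame of cells")
        for c in (self.subject_col, self.intensity_col):
            if c not in X.columns:
                raise KeyError(f"column {c!r} not in cell table")
        self.grid_ = self._grid()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "grid_"):
            self.fit(X)
        values = pd.to_numeric(X[self.intensity_col], errors="coerce")
        keep = ~values.isna().to_numpy()
        intensity = values.to_numpy(dtype=float)[keep]
        if self.log_transform:
            intensity = np.log1p(intensity)
        subjects = X[self.subject_col].to_numpy()[keep]
        samples = [
            CellSample(str(sid), intensity[subjects == sid])
            for sid in pd.unique(subjects)
        ]
        samples = qc_filter(samples, self.min_cells)
        if not samples:
            raise ValueError("no subject passed QC")
        qm = build_quantile_matrix(samples, self.grid_)
        out = qm.to_frame()
        out["ccmsi"] = [compartment_mean(s) for s in samples]
        out["n_cells"] = [s.n_cells for s in samples]
        return out
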