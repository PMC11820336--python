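"""Wavelength grids, spectra containers, and spectral similarity metrics.

The working band of the sensor is 400-750 nm sampled every 2 nm (176 points);
the classifier consumes the 450-700 nm sub-band (126 points) where the
hemoglobin absorption features of live skin are strongest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "make_grid",
    "DEFAULT_GRID",
    "CLASSIFIER_BAND",
    "crop_band",
    "crop_columns",
    "normalize_spectrum",
    "normalize_rows",
    "fidelity",
    "rmse",
]

NormMode = Literal["sum1", "max1", "l2"]

_DIV_TOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling, inclusive of both endpoints."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(
                f"stop ({self.stop}) must exceed start ({self.start})"
            )
        span = self.stop - self.start
        ratio = span / self.step
        if abs(ratio - round(ratio)) > _DIV_TOL * max(1.0, ratio):
            raise ValueError(
                f"step {self.step} nm does not divide the span "
                f"{self.start}-{self.stop} nm"
            )

    @property
    def points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.points)

    def index_of(self, nm: float) -> int:
        """Index of an on-grid wavelength; rejects off-grid queries."""
        pos = (nm - self.start) / self.step
        idx = int(round(pos))
        if abs(pos - idx) > 1e-6 or not (0 <= idx < self.points):
            raise ValueError(f"{nm} nm is not a sample point of {self}")
        return idx

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"grid({self.start}-{self.stop} nm, step {self.step}, {self.points} pts)"


def make_grid(start: float, stop: float, step: float) -> WavelengthGrid:
    """Build a uniform wavelength grid covering [start, stop] at `step` nm."""
    return WavelengthGrid(float(start), float(stop), float(step))


#: Sensor working band: 400-750 nm at 2 nm -> 176 points.
DEFAULT_GRID = make_grid(400.0, 750.0, 2.0)

#: Band fed to the classifier (hemoglobin features live in 500-650 nm).
CLASSIFIER_BAND = (450.0, 700.0)


@dataclass
class Spectrum:
    """A sampled spectrum on a wavelength grid (linear intensity units)."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != self.grid.points:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid with "
                f"{self.grid.points} points"
            )

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.values.copy())


def crop_band(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Contiguous slice of a spectrum between two on-grid wavelengths."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be below hi ({hi})")
    i0 = s.grid.index_of(lo)
    i1 = s.grid.index_of(hi)
    sub = make_grid(lo, hi, s.grid.step)
    return Spectrum(sub, s.values[i0 : i1 + 1].copy())


def crop_columns(
    grid: WavelengthGrid, matrix: np.ndarray, lo: float, hi: float
) -> tuple[WavelengthGrid, np.ndarray]:
    """Batch form of :func:`crop_band` for an (n, L) row matrix of spectra."""
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be below hi ({hi})")
    i0 = grid.index_of(lo)
    i1 = grid.index_of(hi)
    return make_grid(lo, hi, grid.step), np.asarray(matrix, float)[:, i0 : i1 + 1]


def _norm_factor(v: np.ndarray, mode: NormMode) -> np.ndarray:
    if mode == "sum1":
        return v.sum(axis=-1)
    if mode == "max1":
        return v.max(axis=-1)
    if mode == "l2":
        return np.linalg.norm(v, axis=-1)
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_spectrum(s: Spectrum, mode: NormMode = "sum1") -> Spectrum:
    """Rescale to unit sum / unit max / unit L2 norm.

    Rejects spectra with no strictly positive value (undefined scaling).
    """
    if not np.any(s.values > 0):
        raise ValueError("cannot normalize a spectrum with no positive value")
    return Spectrum(s.grid, s.values / _norm_factor(s.values, mode))


def normalize_rows(matrix: np.ndarray, mode: NormMode = "max1") -> np.ndarray:
    """Row-wise normalization of an (n, L) spectra matrix."""
    m = np.asarray(matrix, dtype=float)
    f = _norm_factor(m, mode)
    if np.any(f <= 0):
        raise ValueError("cannot normalize rows with no positive value")
    return m / f[:, None]


def _as_probability(v: np.ndarray) -> np.ndarray:
    # Reconstructions may carry small negative excursions; clip at metric time
    # only (the solver itself stays linear).
    p = np.clip(np.asarray(v, dtype=float), 0.0, None)
    tot = p.sum()
    if tot <= 0:
        raise ValueError("spectrum has no positive mass; fidelity undefined")
    return p / tot


def _check_same_grid(x: Spectrum, y: Spectrum) -> None:
    if x.grid != y.grid:
        raise ValueError(f"grid mismatch: {x.grid} vs {y.grid}")


def fidelity(x: Spectrum, y: Spectrum) -> float:
    """Spectral fidelity F(X, Y) = (sum_m sqrt(p_m q_m))^2 in [0, 1].

    Both spectra are normalized to unit sum internally, so the metric is
    invariant to positive rescaling of either argument and symmetric; it
    equals 1 exactly when the normalized shapes coincide (squared
    Bhattacharyya coefficient between the two probability-form spectra).
    """
    _check_same_grid(x, y)
    p = _as_probability(x.values)
    q = _as_probability(y.values)
    return float(np.sqrt(p * q).sum() ** 2)


def fidelity_rows(truth: np.ndarray, est: np.ndarray) -> np.ndarray:
    """Row-wise fidelity between two (n, L) spectra matrices."""
    p = np.clip(np.asarray(truth, float), 0.0, None)
    q = np.clip(np.asarray(est, float), 0.0, None)
    p = p / p.sum(axis=1, keepdims=True)
    q = q / q.sum(axis=1, keepdims=True)
    return np.sqrt(p * q).sum(axis=1) ** 2


def rmse(x: Spectrum, y: Spectrum) -> float:
    """Root mean square error between two spectra on the same grid."""
    _check_same_grid(x, y)
    d = x.values - y.values
    return float(np.sqrt(np.mean(d * d)))
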