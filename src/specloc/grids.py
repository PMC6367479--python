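"""Frequency and elevation grids.

Frequencies live on a logarithmic grid (constant number of bins per
octave), mirroring the roughly log-spaced tonotopic axis of the cochlea.
Elevations live on a uniform grid on the midsagittal plane; the default
matches a hoop setup with 2.5 deg resolution between -60 and +85 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ElevationGrid",
    "make_frequency_grid",
    "make_elevation_grid",
    "band_mask",
]

#: default elevation range of the speaker hoop, degrees
DEFAULT_ELEVATION_RANGE = (-60.0, 85.0)
DEFAULT_ELEVATION_STEP = 2.5


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered frequencies in kHz, log-spaced at a fixed bins-per-octave density."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("frequency grid needs at least 2 points")
        if np.any(v <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def log2f(self) -> np.ndarray:
        return np.log2(self.values)

    def band_mask(self, f_lo: float, f_hi: float) -> np.ndarray:
        return band_mask(self.values, f_lo, f_hi)


@dataclass(frozen=True)
class ElevationGrid:
    """Uniformly spaced elevation angles in degrees on the midsagittal plane."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("elevation grid needs at least 2 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("elevations must be strictly increasing")
        if not np.allclose(d, d[0], atol=1e-9):
            raise ValueError("elevation grid must be uniform")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def index_of(self, elevation: float) -> int:
        """Index of an on-grid elevation; raises if ``elevation`` is off-grid."""
        i = int(np.argmin(np.abs(self.values - elevation)))
        if abs(self.values[i] - elevation) > 1e-6:
            raise ValueError(f"elevation {elevation} deg is not on the grid")
        return i


def make_frequency_grid(f_lo: float, f_hi: float, bins_per_octave: int = 64) -> FrequencyGrid:
    """Logarithmically spaced frequency grid including both endpoints.

    Parameters
    ----------
    f_lo, f_hi
        Band edges in kHz, ``0 < f_lo < f_hi``.
    bins_per_octave
        Grid density; the number of points is
        ``ceil(bins_per_octave * log2(f_hi/f_lo)) + 1``.
    """
    if f_lo <= 0 or f_hi <= 0:
        raise ValueError("frequencies must be positive")
    if f_lo >= f_hi:
        raise ValueError("f_lo must be smaller than f_hi")
    if bins_per_octave < 1:
        raise ValueError("bins_per_octave must be >= 1")
    n_octaves = np.log2(f_hi / f_lo)
    n = int(np.ceil(bins_per_octave * n_octaves)) + 1
    return FrequencyGrid(np.geomspace(f_lo, f_hi, n))


def make_elevation_grid(
    lo: float = DEFAULT_ELEVATION_RANGE[0],
    hi: float = DEFAULT_ELEVATION_RANGE[1],
    step: float = DEFAULT_ELEVATION_STEP,
) -> ElevationGrid:
    """Uniform elevation grid from ``lo`` to ``hi`` inclusive (default 59 points)."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((hi - lo) / step)) + 1
    return ElevationGrid(lo + step * np.arange(n))


def band_mask(freqs_khz: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Boolean mask of grid bins inside the closed band [f_lo, f_hi] kHz."""
    f = np.asarray(freqs_khz, dtype=float)
    return (f >= f_lo - 1e-12) & (f <= f_hi + 1e-12)
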