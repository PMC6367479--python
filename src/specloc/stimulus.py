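"""Spectral-contrast stimulus bank.

The experiment manipulates the relative level of the 6-9 kHz "notch band"
(where the dominant elevation cue of the pinna lives) against the outer
bands (0.5-6 and 9-20 kHz).  A stimulus is defined by its Notch Region
Intensity (NRI) and Outer Region Intensity (ORI), each drawn from
{29, 38, 47, 56, 65} dB SPL, giving a 5x5 matrix of 25 sounds with
spectral contrast NRI - ORI spanning -36 to +36 dB.  Band transitions are
linear-in-log-frequency ramps with a 120 dB/octave slope, mimicking the
steep digital band filters used to shape the noise tokens.

The observer model consumes amplitude spectra in dB, so stimuli are
constructed directly in the spectral domain; the stochastic bin-to-bin
jitter of a physical noise token is modelled separately as sensory noise
(see :mod:`specloc.experiment`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from specloc.grids import FrequencyGrid, make_frequency_grid

__all__ = [
    "NOTCH_BAND_KHZ",
    "STIMULUS_LEVELS_DB",
    "StimulusSpectrum",
    "StimulusMatrix",
    "make_stimulus",
    "make_stimulus_matrix",
    "spectral_contrast",
    "export_stimulus_matrix",
]

NOTCH_BAND_KHZ = (6.0, 9.0)
OUTER_BAND_LO_KHZ = 0.5  # Methods value; a 1 kHz lower edge is also seen in the field
STIMULUS_LEVELS_DB = (29.0, 38.0, 47.0, 56.0, 65.0)
DEFAULT_EDGE_SLOPE_DB_PER_OCT = 120.0


@dataclass(frozen=True)
class StimulusSpectrum:
    """Source amplitude spectrum X(f) in dB, defined by band levels."""

    grid: FrequencyGrid
    levels_db: np.ndarray
    nri: float
    ori: float

    def __post_init__(self) -> None:
        v = np.asarray(self.levels_db, dtype=float)
        if v.shape != (self.grid.n,):
            raise ValueError("levels_db must match the frequency grid")
        object.__setattr__(self, "levels_db", v)

    @property
    def contrast(self) -> float:
        return self.nri - self.ori


@dataclass(frozen=True)
class StimulusMatrix:
    """The 5x5 bank of spectral-contrast stimuli indexed by (nri, ori)."""

    stimuli: dict
    levels: tuple

    def __getitem__(self, key: tuple[float, float]) -> StimulusSpectrum:
        return self.stimuli[(float(key[0]), float(key[1]))]

    def __iter__(self):
        return iter(self.stimuli.values())

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def conditions(self) -> list[tuple[float, float]]:
        return list(self.stimuli.keys())


def make_stimulus(
    nri: float,
    ori: float,
    grid: FrequencyGrid | None = None,
    edge_slope: float = DEFAULT_EDGE_SLOPE_DB_PER_OCT,
) -> StimulusSpectrum:
    """Construct one spectral-contrast stimulus.

    The spectrum equals ``nri`` dB inside the closed 6-9 kHz notch band and
    ``ori`` dB in the outer bands, with linear-in-log-frequency ramps at
    the 6 and 9 kHz edges whose slope is ``edge_slope`` dB/octave (ramps
    extend into the outer region, so the notch band itself is flat).
    """
    if edge_slope <= 0:
        raise ValueError("edge_slope must be positive")
    grid = grid or make_frequency_grid(0.5, 20.0, 64)
    f = grid.values
    if f[0] > OUTER_BAND_LO_KHZ + 1e-9 or f[-1] < 20.0 - 1e-9:
        raise ValueError("grid must span the 0.5-20 kHz stimulus range")

    f_lo, f_hi = NOTCH_BAND_KHZ
    # octave distance from the notch band (0 inside the band)
    dist = np.zeros_like(f)
    below = f < f_lo
    above = f > f_hi
    dist[below] = np.log2(f_lo / f[below])
    dist[above] = np.log2(f[above] / f_hi)

    delta = nri - ori
    if delta == 0:
        levels = np.full_like(f, ori)
    else:
        excess = np.sign(delta) * np.maximum(0.0, abs(delta) - edge_slope * dist)
        levels = ori + excess
    return StimulusSpectrum(grid=grid, levels_db=levels, nri=float(nri), ori=float(ori))


def make_stimulus_matrix(
    grid: FrequencyGrid | None = None,
    levels: tuple = STIMULUS_LEVELS_DB,
    edge_slope: float = DEFAULT_EDGE_SLOPE_DB_PER_OCT,
) -> StimulusMatrix:
    """All (nri, ori) combinations over the experiment's level set."""
    grid = grid or make_frequency_grid(0.5, 20.0, 64)
    stimuli = {
        (float(nri), float(ori)): make_stimulus(nri, ori, grid, edge_slope)
        for nri in levels
        for ori in levels
    }
    return StimulusMatrix(stimuli=stimuli, levels=tuple(float(v) for v in levels))


def spectral_contrast(s: StimulusSpectrum) -> float:
    """Spectral contrast in dB, defined as NRI - ORI."""
    return s.nri - s.ori


def export_stimulus_matrix(matrix: StimulusMatrix, path: str | Path) -> None:
    """Write the stimulus bank as a long-form CSV.

    Columns: nri_db, ori_db, contrast_db, freq_khz, level_db.
    """
    import pandas as pd

    rows = []
    for s in matrix:
        rows.append(
            pd.DataFrame(
                {
                    "nri_db": s.nri,
                    "ori_db": s.ori,
                    "contrast_db": s.contrast,
                    "freq_khz": s.grid.values,
                    "level_db": s.levels_db,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
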