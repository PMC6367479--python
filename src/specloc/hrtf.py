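"""Synthetic (canonical) head-related transfer functions.

Human HRTF amplitude spectra on the midsagittal plane share a few robust
features that carry the elevation percept:

* a direction-independent ear-canal resonance near 2.5 kHz;
* a prominent primary spectral notch (N1) whose center frequency sweeps
  upward through the 6-9 kHz band as the source moves from low to high
  elevations, and whose depth is largest at low elevations;
* a secondary notch (N2) above N1 that is deep at low elevations and
  fades (and leaves the audible band) toward the top;
* a broad mid-band energy peak that grows with elevation — at high
  elevations pinna spectra concentrate energy in the former notch region;
* weak but monotonic elevation-dependent gain changes in the 4-6 kHz band;
* erratic, non-monotonic fine structure at the top of the spectrum, where
  the cues are idiosyncratic and perceptually unreliable.

:func:`make_canonical_hrtfs` builds a parametric gain matrix H(f; e) in dB
with exactly these ingredients: a fixed log-frequency Gaussian resonance
bump, moving negative Gaussian notches, an elevation-scaled Gaussian peak,
a linear low-band ramp, and a seeded high-band sinusoidal ripple whose
phase and rate vary erratically with elevation.

The observer model rests on two structural assumptions about the template
set: (i) every elevation's HRTF is unique (templates do not correlate with
each other over the analysis band), and (ii) source spectra do not
correlate with any template.  :func:`uniqueness_report` quantifies both on
a concrete HRTF set and stimulus bank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from specloc.grids import ElevationGrid, FrequencyGrid, make_elevation_grid, make_frequency_grid
from specloc.stats import safe_pearson, safe_pearson_rows

__all__ = [
    "HRTFParams",
    "HRTFSet",
    "UniquenessReport",
    "make_canonical_hrtfs",
    "default_hrtf_set",
    "uniqueness_report",
    "read_hrtf_table",
    "write_hrtf_table",
]

GAIN_RANGE_DB = (-15.0, 20.0)
NOTCH_CENTER_LIMITS_KHZ = (5.0, 11.0)
RESONANCE_BAND_KHZ = (2.25, 2.75)


@dataclass(frozen=True)
class HRTFParams:
    """Parameters of the canonical HRTF generator.

    Attributes
    ----------
    notch_center_low
        Notch center frequency (kHz) at the lowest elevation of the grid.
    notch_center_slope
        Upward drift of the notch center, kHz per degree of elevation.
    notch_depth
        Notch depth (dB) at the lowest elevation; the depth shrinks
        linearly to ``notch_depth * notch_depth_taper`` at the top.
    notch_width
        Gaussian sigma of the notch in octaves.
    notch2_ratio, notch2_depth, notch2_width
        Second pinna notch (N2): center at ``notch2_ratio`` times the
        primary notch center, depth ``notch2_depth`` dB at the lowest
        elevation fading to zero at the top, sigma in octaves.  At low
        elevations N2 falls near 10 kHz and is the main template
        structure inside the heavily weighted upper analysis band.
    lowband_ramp_gain
        Slope (dB/deg) of the monotonic elevation cue in the 4-6 kHz band.
    midband_peak_gain
        Peak gain (dB) of the broad mid-band elevation cue at the highest
        elevation.  Real pinna spectra at high elevations carry a broad
        energy peak in the former notch region; this is the feature that
        lets block-like high-contrast spectra masquerade as upward
        sources.
    midband_peak_center, midband_peak_width
        Center (kHz) and Gaussian sigma (octaves) of that peak.
    highband_ripple_amp
        Amplitude (dB) of the ripple above ~11 kHz.
    highband_ripple_rate
        Base ripple rate in cycles/octave; the per-elevation rate and phase
        are drawn from ``rng_seed`` so the high band varies erratically
        (non-monotonically) across elevations.
    resonance_center, resonance_gain, resonance_width
        Ear-canal resonance: center (kHz), peak gain (dB), sigma (octaves).
        The resonance is identical for every elevation.
    """

    notch_center_low: float = 5.5
    notch_center_slope: float = 5.0 / 145.0
    notch_depth: float = 12.0
    notch_depth_taper: float = 0.7
    notch_width: float = 0.25
    notch2_ratio: float = 1.8
    notch2_depth: float = 10.0
    notch2_width: float = 0.3
    lowband_ramp_gain: float = 0.03
    midband_peak_gain: float = 5.0
    midband_peak_center: float = 7.5
    midband_peak_width: float = 0.35
    highband_ripple_amp: float = 1.5
    highband_ripple_rate: float = 4.0
    highband_ripple_rate_jitter: float = 1.0
    resonance_center: float = 2.5
    resonance_gain: float = 15.0
    resonance_width: float = 0.35
    rng_seed: int = 2016

    def __post_init__(self) -> None:
        if self.notch_depth < 0 or self.notch_width <= 0:
            raise ValueError("notch depth must be >= 0 and width > 0")
        if not 0.0 <= self.notch_depth_taper <= 1.0:
            raise ValueError("notch_depth_taper must lie in [0, 1]")
        if self.highband_ripple_amp < 0 or self.resonance_width <= 0:
            raise ValueError("ripple amplitude >= 0 and resonance width > 0 required")


@dataclass(frozen=True)
class HRTFSet:
    """A bank of HRTF amplitude spectra: one dB gain row per elevation."""

    grid: FrequencyGrid
    elevations: ElevationGrid
    gains: np.ndarray  # (n_elevations, n_freqs) dB

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if g.shape != (self.elevations.n, self.grid.n):
            raise ValueError(
                f"gain matrix shape {g.shape} does not match "
                f"({self.elevations.n}, {self.grid.n})"
            )
        if not np.all(np.isfinite(g)):
            raise ValueError("gains must be finite")
        object.__setattr__(self, "gains", g)

    def row(self, elevation: float) -> np.ndarray:
        """Gain spectrum (dB) at an on-grid elevation."""
        return self.gains[self.elevations.index_of(elevation)]


@dataclass(frozen=True)
class UniquenessReport:
    """Diagnostics for the model's two structural template assumptions.

    ``correlation_matrix`` holds the elevation x elevation Pearson
    correlations of the templates over the analysis band.
    ``min_diagonal_margin`` is the smallest, over rows, of
    (diagonal - max off-diagonal); a positive value certifies that each
    template correlates best with itself (assumption i).
    ``source_decorrelation`` holds |corr| between each stimulus spectrum
    and each template row; small values certify assumption (ii).
    """

    correlation_matrix: np.ndarray
    min_diagonal_margin: float
    source_decorrelation: np.ndarray

    @property
    def max_source_correlation(self) -> float:
        if self.source_decorrelation.size == 0:
            return 0.0
        return float(self.source_decorrelation.max())


def _cos_taper_window(log2f: np.ndarray, rise: tuple[float, float],
                      fall: tuple[float, float] | None = None) -> np.ndarray:
    """Window that rises 0->1 over ``rise`` (log2-kHz) and optionally falls 1->0."""
    w = np.clip((log2f - rise[0]) / (rise[1] - rise[0]), 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    if fall is not None:
        d = np.clip((log2f - fall[0]) / (fall[1] - fall[0]), 0.0, 1.0)
        w = w * (0.5 + 0.5 * np.cos(np.pi * d))
    return w


def make_canonical_hrtfs(
    params: HRTFParams | None = None,
    grid: FrequencyGrid | None = None,
    elevations: ElevationGrid | None = None,
) -> HRTFSet:
    """Generate the canonical synthetic HRTF set.

    Per elevation row the gain (dB) is the sum of

    * the fixed ear-canal resonance bump at ``resonance_center``,
    * a negative Gaussian notch (N1) in log-frequency whose center rises
      linearly with elevation from ``notch_center_low`` and whose depth is
      maximal at the lowest elevation,
    * a secondary notch (N2) at ``notch2_ratio`` times the N1 center,
      fading with elevation,
    * a monotonic-in-elevation linear gain ramp confined to ~4-6 kHz,
    * a broad mid-band peak (~7.5 kHz) whose gain grows with elevation —
      the high-elevation energy concentration of real pinna spectra,
    * a seeded sinusoidal ripple above ~11 kHz whose phase/rate vary
      non-monotonically across elevations.

    Deterministic given ``params.rng_seed``.
    """
    params = params or HRTFParams()
    grid = grid or make_frequency_grid(0.5, 20.0, 64)
    elevations = elevations or make_elevation_grid()

    eps = elevations.values
    log2f = grid.log2f
    rng = np.random.default_rng(params.rng_seed)

    # notch trajectory: center rises linearly from the lowest elevation
    centers = params.notch_center_low + params.notch_center_slope * (eps - eps[0])
    lo, hi = NOTCH_CENTER_LIMITS_KHZ
    if centers.min() < lo or centers.max() > hi:
        raise ValueError(
            f"notch trajectory [{centers.min():.2f}, {centers.max():.2f}] kHz "
            f"leaves the allowed [{lo}, {hi}] kHz range"
        )
    span = eps[-1] - eps[0]
    rel = (eps - eps[0]) / span if span > 0 else np.zeros_like(eps)
    depths = params.notch_depth * (1.0 - (1.0 - params.notch_depth_taper) * rel)

    resonance = params.resonance_gain * np.exp(
        -0.5 * ((log2f - np.log2(params.resonance_center)) / params.resonance_width) ** 2
    )

    # low-band monotonic cue: flat 4-6 kHz core with cosine tapers, strictly
    # zero below 3.5 kHz so the ear-canal resonance stays direction-independent
    ramp_window = _cos_taper_window(
        log2f, rise=(np.log2(3.5), np.log2(4.0)), fall=(np.log2(6.0), np.log2(6.5))
    )

    # high-band ripple is confined above ~11 kHz so it never outbids the
    # notch for the in-band (5-11 kHz) gain minimum
    ripple_window = _cos_taper_window(log2f, rise=(np.log2(11.0), np.log2(11.8)))
    ripple_phase = rng.uniform(0.0, 2.0 * np.pi, size=eps.size)
    ripple_rate = params.highband_ripple_rate + params.highband_ripple_rate_jitter * rng.uniform(
        -1.0, 1.0, size=eps.size
    )

    peak_shape = np.exp(
        -0.5 * ((log2f - np.log2(params.midband_peak_center)) / params.midband_peak_width) ** 2
    )

    gains = np.empty((eps.size, grid.n))
    for i in range(eps.size):
        notch = -depths[i] * np.exp(
            -0.5 * ((log2f - np.log2(centers[i])) / params.notch_width) ** 2
        )
        notch2 = -params.notch2_depth * (1.0 - rel[i]) * np.exp(
            -0.5 * ((log2f - np.log2(params.notch2_ratio * centers[i]))
                    / params.notch2_width) ** 2
        )
        ramp = params.lowband_ramp_gain * eps[i] * ramp_window
        peak = params.midband_peak_gain * rel[i] * peak_shape
        ripple = params.highband_ripple_amp * ripple_window * np.sin(
            2.0 * np.pi * ripple_rate[i] * (log2f - np.log2(11.0)) + ripple_phase[i]
        )
        gains[i] = resonance + notch + notch2 + ramp + peak + ripple

    g_lo, g_hi = GAIN_RANGE_DB
    if gains.min() < g_lo or gains.max() > g_hi:
        raise ValueError(
            f"generated gains [{gains.min():.1f}, {gains.max():.1f}] dB exceed "
            f"the [{g_lo}, {g_hi}] dB range"
        )
    return HRTFSet(grid=grid, elevations=elevations, gains=gains)


def default_hrtf_set(seed: int = 2016) -> HRTFSet:
    """Canonical HRTF set on the default grids."""
    return make_canonical_hrtfs(HRTFParams(rng_seed=seed))


def uniqueness_report(
    hrtfs: HRTFSet,
    stimuli=(),
    band: tuple[float, float] = (3.0, 12.0),
) -> UniquenessReport:
    """Check the template-uniqueness and source-decorrelation assumptions.

    Pearson correlations are computed over the grid bins inside ``band``
    (default the 3-12 kHz analysis band).  ``stimuli`` is an iterable of
    objects with a ``levels_db`` attribute (or plain per-bin dB arrays) on
    the same frequency grid.
    """
    mask = hrtfs.grid.band_mask(*band)
    if mask.sum() < 3:
        raise ValueError("analysis band must contain at least 3 frequency bins")
    rows = hrtfs.gains[:, mask]
    n = rows.shape[0]
    corr = np.empty((n, n))
    for i in range(n):
        corr[i] = safe_pearson_rows(rows, rows[i])

    off = corr - 2.0 * np.eye(n)  # push the diagonal out of the row max
    margin = float(np.min(np.diag(corr) - off.max(axis=1)))

    spectra = []
    for s in stimuli:
        levels = getattr(s, "levels_db", s)
        spectra.append(np.asarray(levels, dtype=float)[mask])
    if spectra:
        src = np.abs(
            np.array([[safe_pearson(x, rows[i]) for i in range(n)] for x in spectra])
        )
    else:
        src = np.zeros((0, n))
    return UniquenessReport(
        correlation_matrix=corr, min_diagonal_margin=margin, source_decorrelation=src
    )


def write_hrtf_table(hrtfs: HRTFSet, path: str | Path) -> None:
    """Write an HRTF set as a CSV matrix.

    First row: frequencies in kHz (first cell blank); first column:
    elevations in deg; cells: gain in dB.
    """
    import pandas as pd

    df = pd.DataFrame(
        hrtfs.gains, index=hrtfs.elevations.values, columns=hrtfs.grid.values
    )
    df.index.name = "elevation_deg"
    df.to_csv(path, float_format="%.6g")


def read_hrtf_table(path: str | Path) -> HRTFSet:
    """Read an HRTF gain table written by :func:`write_hrtf_table`.

    Accepts comma- or tab-separated tables; validates that both axes are
    strictly increasing.
    """
    import pandas as pd

    df = pd.read_csv(path, index_col=0, sep=None, engine="python")
    freqs = df.columns.to_numpy(dtype=float)
    elevs = df.index.to_numpy(dtype=float)
    return HRTFSet(
        grid=FrequencyGrid(freqs),
        elevations=ElevationGrid(elevs),
        gains=df.to_numpy(dtype=float),
    )
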