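"""Virtual psychophysics experiment.

Replays the study design through the observer model: 25 spectral-contrast
stimuli x 48 randomly selected frontal directions x 1 repeat = 1200
trials, divided into 8 blocks of 150.  Targets are drawn in double-pole
coordinates with azimuth in [-90, 90] and elevation on the hoop grid
(-60..+85 deg), subject to |azimuth| + |elevation| <= 90.  Azimuth is
carried through as metadata: the model is elevation-only, and simulated
azimuth responses simply copy the target (plus optional Gaussian error)
so the regression code can be exercised on both components.

Sensory noise is additive Gaussian in dB per frequency bin, applied to
the eardrum spectrum before spectral weighting (default sigma 3 dB),
followed by a soft noise floor: the room background (default 30 dB SPL)
adds to each bin in the power domain, so bins far above the floor are
barely affected while bins near it are lifted.  This is the minimal
noise model that produces the up-down bistability seen at moderate
positive spectral contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from specloc.grids import ElevationGrid, make_elevation_grid
from specloc.hrtf import HRTFSet
from specloc.model import ModelConfig, localize
from specloc.stimulus import STIMULUS_LEVELS_DB, StimulusMatrix, make_stimulus_matrix

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "build_design",
    "add_sensory_noise",
    "run_experiment",
    "read_trials",
    "write_trials",
]

TRIAL_COLUMNS = [
    "block",
    "nri_db",
    "ori_db",
    "contrast_db",
    "azimuth_t_deg",
    "elevation_t_deg",
    "azimuth_r_deg",
    "elevation_r_deg",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-bin Gaussian dB noise plus a power-domain background floor."""

    spectral_sigma: float = 3.0
    noise_floor: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.spectral_sigma < 0:
            raise ValueError("spectral_sigma must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Shuffled crossing of stimulus conditions x targets x repeats."""

    stimulus_matrix: StimulusMatrix
    targets: np.ndarray  # (n_targets, 2): azimuth, elevation in deg
    repeats: int
    n_blocks: int
    trial_order: pd.DataFrame  # columns nri_db, ori_db, azimuth_t_deg, elevation_t_deg, block
    rng_seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trial_order)


def _draw_targets(
    n: int, elevation_grid: ElevationGrid, rng: np.random.Generator
) -> np.ndarray:
    """Random frontal (azimuth, elevation) pairs with |az| + |el| <= 90.

    Elevations are drawn from the hoop grid; azimuth uniform within the
    range the double-pole constraint allows for that elevation.
    """
    el = rng.choice(elevation_grid.values, size=n, replace=True)
    az_max = 90.0 - np.abs(el)
    az = rng.uniform(-az_max, az_max)
    return np.column_stack([az, el])


def build_design(
    levels=STIMULUS_LEVELS_DB,
    targets: int | np.ndarray = 48,
    repeats: int = 1,
    seed: int = 0,
    n_blocks: int = 8,
    elevation_grid: ElevationGrid | None = None,
    stimulus_matrix: StimulusMatrix | None = None,
) -> ExperimentDesign:
    """Build the full factorial design (stimuli x targets x repeats), shuffled.

    ``targets`` is either a count of random frontal directions or an
    explicit (n, 2) array of (azimuth, elevation) pairs.  With the default
    5 levels, 48 targets and 1 repeat this yields the study's 1200 trials
    in 8 blocks of 150.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    elevation_grid = elevation_grid or make_elevation_grid()
    stimulus_matrix = stimulus_matrix or make_stimulus_matrix(levels=tuple(levels))
    rng = np.random.default_rng(seed)
    if np.isscalar(targets):
        if targets < 1:
            raise ValueError("need at least one target")
        tgt = _draw_targets(int(targets), elevation_grid, rng)
    else:
        tgt = np.atleast_2d(np.asarray(targets, dtype=float))

    conds = stimulus_matrix.conditions
    rows = [
        (nri, ori, az, el)
        for _ in range(repeats)
        for (nri, ori) in conds
        for az, el in tgt
    ]
    df = pd.DataFrame(rows, columns=["nri_db", "ori_db", "azimuth_t_deg", "elevation_t_deg"])
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    df["block"] = (np.arange(len(df)) * n_blocks) // max(len(df), 1)
    return ExperimentDesign(
        stimulus_matrix=stimulus_matrix,
        targets=tgt,
        repeats=repeats,
        n_blocks=n_blocks,
        trial_order=df,
        rng_seed=seed,
    )


def add_sensory_noise(
    spectrum_db: np.ndarray, nm: NoiseModel, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Perturb a dB spectrum with per-bin Gaussian noise and the room floor.

    The floor combines in the power domain:
    ``L' = 10 log10(10^(L/10) + 10^(floor/10))`` — physically correct
    superposition of uncorrelated sound power.  A floor of ``-inf``
    disables it.
    """
    rng = rng or np.random.default_rng(nm.rng_seed)
    s = np.asarray(spectrum_db, dtype=float)
    if nm.spectral_sigma > 0:
        s = s + rng.normal(0.0, nm.spectral_sigma, size=s.shape)
    if np.isfinite(nm.noise_floor):
        s = 10.0 * np.log10(10.0 ** (s / 10.0) + 10.0 ** (nm.noise_floor / 10.0))
    return s


def run_experiment(
    design: ExperimentDesign,
    hrtfs: HRTFSet,
    cfg: ModelConfig | None = None,
    noise: NoiseModel | None = None,
    azimuth_response_sigma: float = 0.0,
) -> pd.DataFrame:
    """Run every trial of a design through the observer model.

    Returns a trial table with one perceived elevation per trial.
    Deterministic given the design/model/noise seeds.  When ``noise`` is
    None the stimulus spectrum enters the model unperturbed (and without
    the background floor).
    """
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(noise.rng_seed if noise is not None else cfg.rng_seed)
    out = design.trial_order.copy()
    responses = np.empty(len(out))
    az_resp = out["azimuth_t_deg"].to_numpy().copy()
    for k, row in enumerate(out.itertuples(index=False)):
        x = design.stimulus_matrix[(row.nri_db, row.ori_db)]
        noise_db = None
        if noise is not None:
            # express noise + floor as an additive perturbation of X(f)
            perturbed = add_sensory_noise(x.levels_db, noise, rng)
            noise_db = perturbed - x.levels_db
        responses[k] = localize(
            x, row.elevation_t_deg, hrtfs, cfg, noise_db=noise_db, rng=rng
        )
    if azimuth_response_sigma > 0:
        az_resp = az_resp + rng.normal(0.0, azimuth_response_sigma, size=az_resp.size)
    out["contrast_db"] = out["nri_db"] - out["ori_db"]
    out["azimuth_r_deg"] = az_resp
    out["elevation_r_deg"] = responses
    return out[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False, float_format="%.6g")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
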