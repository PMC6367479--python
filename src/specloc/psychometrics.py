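"""Psychometric analysis: robust stimulus-response regressions and coordinates.

Localization performance per stimulus condition is summarized by the
linear fit ``e_R = g * e_T + b`` of response elevation on target
elevation, estimated by minimizing the mean absolute error (MAE) — a
least-absolute-deviations fit, less sensitive to outliers (e.g. up-down
confusions) than least squares.  Alongside the gain ``g`` and bias ``b``
(deg) we report Pearson's r, the coefficient of determination r², the
residual SD around the fitted line, and the mean absolute localization
error.

Coordinates follow the double-pole convention: azimuth is the angle to
the midsagittal plane and elevation the angle to the horizontal plane, so
``|azimuth| + |elevation| <= 90 deg`` for any frontal direction.  A
response reported as "behind" is unfolded to the rear hemifield via
``e_rear = 180 - e_front``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from specloc.stats import safe_pearson

__all__ = [
    "RegressionFit",
    "ConditionSummary",
    "fit_linear_mae",
    "grid_search_mae",
    "summarize_conditions",
    "contrast_profile",
    "level_profile",
    "double_pole_from_cartesian",
    "rear_unfold",
]


@dataclass(frozen=True)
class RegressionFit:
    """Result of one stimulus-response regression.

    ``gain`` is dimensionless, ``bias``/``residual_sd``/``mae`` are in
    degrees.  ``degenerate`` flags a fit on zero-variance targets, for
    which the gain is undefined (NaN) and the bias is the response median.
    """

    gain: float
    bias: float
    r: float
    r2: float
    residual_sd: float
    mae: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition regression fits plus contrast/level profiles."""

    fits: pd.DataFrame        # one row per (nri, ori) condition
    by_contrast: pd.DataFrame  # anti-diagonal profile (mean fit per contrast)
    by_level: pd.DataFrame     # main-diagonal profile (flat spectra)


def _mae(params: np.ndarray, t: np.ndarray, r: np.ndarray) -> float:
    g, b = params
    return float(np.mean(np.abs(r - (g * t + b))))


def fit_linear_mae(targets, responses, xatol: float = 1e-6) -> RegressionFit:
    """Fit ``response = g * target + b`` by minimizing mean absolute error.

    The objective is convex in (g, b); a Nelder-Mead simplex initialized
    at the least-squares solution converges to the global optimum
    (parameter tolerance ``xatol``).  Zero-variance targets make the gain
    unidentifiable: the fit is flagged degenerate with b = median(response).
    """
    t = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("targets and responses must be 1-D arrays of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite data")

    if np.ptp(t) < 1e-12:
        b = float(np.median(r))
        resid = r - b
        return RegressionFit(
            gain=float("nan"), bias=b, r=0.0, r2=0.0,
            residual_sd=float(np.std(resid, ddof=1)) if t.size > 1 else 0.0,
            mae=float(np.mean(np.abs(resid))), n=t.size, degenerate=True,
        )

    # The MAE surface is convex but piecewise linear and a single
    # Nelder-Mead run can stall on a kink; deterministic perturbed
    # restarts around the running optimum give the simplex fresh geometry
    # and reach the global optimum in practice.
    x = np.asarray(np.polyfit(t, r, 1))
    best = _mae(x, t, r)
    for dg, db in ((0.0, 0.0), (0.02, 0.0), (0.0, 2.0),
                   (-0.02, 0.0), (0.0, -2.0), (0.01, 1.0)):
        res = minimize(
            _mae, x0=x + np.array([dg, db]), args=(t, r), method="Nelder-Mead",
            options={"xatol": min(xatol, 1e-8), "fatol": 1e-12,
                     "maxiter": 10_000},
        )
        if res.fun < best:
            x, best = res.x, res.fun
    g, b = x
    resid = r - (g * t + b)
    rho = safe_pearson(t, r)
    return RegressionFit(
        gain=float(g), bias=float(b), r=rho, r2=rho * rho,
        residual_sd=float(np.std(resid, ddof=1)),
        mae=float(np.mean(np.abs(resid))), n=t.size,
    )


def grid_search_mae(
    targets,
    responses,
    g_range: tuple[float, float] = (-2.0, 2.0),
    b_range: tuple[float, float] = (-90.0, 90.0),
    resolution: float = 0.001,
    coarse_points: int = 41,
) -> tuple[float, float, float]:
    """Brute-force MAE minimization by iteratively refined grid search.

    Independent check for :func:`fit_linear_mae`: scans a (gain, bias)
    grid, zooming around the best cell until the grid step drops below
    ``resolution`` in both parameters.  The search runs on mean-centered
    targets (intercept ``b' = b + g * mean(t)``) so the two axes are
    decorrelated and the convex MAE valley is axis-aligned; refinement
    then cannot lose the global optimum.  Returns (g, b, mae) in the
    original parameterization.
    """
    t = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    t_mean = t.mean()
    tc = t - t_mean
    g_lo, g_hi = g_range
    g_span = max(abs(g_lo), abs(g_hi))
    b_lo = b_range[0] - g_span * abs(t_mean)
    b_hi = b_range[1] + g_span * abs(t_mean)
    while True:
        gs = np.linspace(g_lo, g_hi, coarse_points)
        bs = np.linspace(b_lo, b_hi, coarse_points)
        err = np.mean(
            np.abs(r[None, None, :] - (gs[:, None, None] * tc[None, None, :] + bs[None, :, None])),
            axis=2,
        )
        i, j = np.unravel_index(np.argmin(err), err.shape)
        dg = gs[1] - gs[0]
        db = bs[1] - bs[0]
        if dg <= resolution and db <= resolution:
            return float(gs[i]), float(bs[j] - gs[i] * t_mean), float(err[i, j])
        g_lo, g_hi = gs[i] - 3.0 * dg, gs[i] + 3.0 * dg
        b_lo, b_hi = bs[j] - 3.0 * db, bs[j] + 3.0 * db


def _fit_to_row(nri: float, ori: float, fit: RegressionFit) -> dict:
    return {
        "nri_db": nri,
        "ori_db": ori,
        "contrast_db": nri - ori,
        "gain": fit.gain,
        "bias_deg": fit.bias,
        "r": fit.r,
        "r2": fit.r2,
        "residual_sd_deg": fit.residual_sd,
        "mae_deg": fit.mae,
        "n": fit.n,
        "degenerate": fit.degenerate,
    }


def summarize_conditions(trials: pd.DataFrame, pool_profiles: bool = False) -> ConditionSummary:
    """Per-condition regressions over a trial table, plus profiles.

    ``trials`` needs columns ``nri_db, ori_db, elevation_t_deg,
    elevation_r_deg``.  Conditions with fewer than 3 trials are flagged
    and excluded from the profiles.  Profiles aggregate along the
    stimulus matrix: by spectral contrast (anti-diagonals) and by sound
    level (the flat-spectrum main diagonal).  By default profile values
    average the per-condition fit parameters; ``pool_profiles`` instead
    pools the trials sharing a contrast and refits.
    """
    rows = []
    for (nri, ori), sub in trials.groupby(["nri_db", "ori_db"], sort=True):
        if len(sub) < 3:
            rows.append(
                {"nri_db": nri, "ori_db": ori, "contrast_db": nri - ori,
                 "gain": np.nan, "bias_deg": np.nan, "r": np.nan, "r2": np.nan,
                 "residual_sd_deg": np.nan, "mae_deg": np.nan, "n": len(sub),
                 "degenerate": True}
            )
            continue
        fit = fit_linear_mae(sub["elevation_t_deg"], sub["elevation_r_deg"])
        rows.append(_fit_to_row(nri, ori, fit))
    fits = pd.DataFrame(rows).sort_values(["nri_db", "ori_db"]).reset_index(drop=True)

    valid = fits[~fits["degenerate"]]
    if pool_profiles:
        crows = []
        for c, sub in trials.groupby(trials["nri_db"] - trials["ori_db"]):
            if len(sub) < 3:
                continue
            fit = fit_linear_mae(sub["elevation_t_deg"], sub["elevation_r_deg"])
            crows.append({"contrast_db": c, "gain": fit.gain, "bias_deg": fit.bias,
                          "r2": fit.r2, "n": fit.n})
        by_contrast = pd.DataFrame(crows).sort_values("contrast_db").reset_index(drop=True)
    else:
        by_contrast = (
            valid.groupby("contrast_db")[["gain", "bias_deg", "r2"]]
            .mean()
            .reset_index()
        )
    by_level = (
        valid[valid["contrast_db"] == 0]
        .sort_values("nri_db")[["nri_db", "gain", "bias_deg", "r2"]]
        .rename(columns={"nri_db": "level_db"})
        .reset_index(drop=True)
    )
    return ConditionSummary(fits=fits, by_contrast=by_contrast, by_level=by_level)


def contrast_profile(summary: ConditionSummary) -> pd.DataFrame:
    """Gain/bias/r2 as a function of spectral contrast (anti-diagonals)."""
    return summary.by_contrast


def level_profile(summary: ConditionSummary) -> pd.DataFrame:
    """Gain/bias/r2 along the flat-spectrum main diagonal (sound level)."""
    return summary.by_level


def double_pole_from_cartesian(direction) -> tuple[float, float]:
    """Double-pole (azimuth, elevation) in degrees from a unit direction.

    Convention: x rightward (toward the right ear), y forward (out of the
    face), z upward.  Azimuth is the angle between the direction and the
    midsagittal (x = 0) plane; elevation the angle to the horizontal
    (z = 0) plane.  For any frontal unit vector
    ``|azimuth| + |elevation| <= 90``.
    """
    v = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    x, y, z = v / norm
    azimuth = np.degrees(np.arcsin(np.clip(x, -1.0, 1.0)))
    elevation = np.degrees(np.arcsin(np.clip(z, -1.0, 1.0)))
    return float(azimuth), float(elevation)


def rear_unfold(elevation_front: float) -> float:
    """Unfold a mirror-imaged frontal response to the rear hemifield.

    ``e_rear = 180 - e_front``; an involution (applying it twice returns
    the input), with +90 deg (zenith) its fixed point.  Accepts the full
    front + rear elevation circle [-90, 270] deg so the map can be
    inverted.
    """
    if not -90.0 <= elevation_front <= 270.0:
        raise ValueError("elevation must lie in [-90, 270] deg")
    return 180.0 - elevation_front
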