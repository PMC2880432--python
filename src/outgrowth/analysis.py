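"""Growth-curve analysis: population doublings, plateaus, and the
plateau-width / initial-variant-fraction power law.

A serial-passage culture seeded with a small fraction f of long-lived
variant cells grows exponentially until most normal cells reach their
division limit, then stalls: cumulative population doublings flatten while
the rare variant colonies re-expand from their rims.  The duration W of
that stall (the plateau width) shrinks as f grows; across a sweep of f the
relation is well described by an inverse power law W = a * f^(-b), whose
inversion f = (a/W)^(1/b) estimates the variant fraction initially present
in a culture from its observed plateau width alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import ConfigurationError


class AnalysisError(ValueError):
    """Record or point set unusable for the requested analysis."""


def population_doublings(collected: float, plated: float) -> float:
    """PD = log(A/B)/log 2 for A cells collected from B plated."""
    if collected <= 0 or plated <= 0:
        raise AnalysisError("cell counts must be positive")
    return math.log(collected / plated) / math.log(2.0)


@dataclass
class PlateauEstimate:
    """A detected growth plateau.

    ``censored`` flags a plateau still open at the end of the record (the
    culture never resumed growth within the horizon -- e.g. it went
    extinct), whose width is a lower bound only.
    """

    start: float            # days
    width: float            # days
    baseline_rate: float    # doublings/day of the early exponential phase
    threshold_used: float   # fraction of baseline below which growth = plateau
    censored: bool = False


def detect_plateau(record: pd.DataFrame,
                   rate_threshold_fraction: float = 0.25,
                   window_days: float = 2.0,
                   baseline_days: Optional[float] = None,
                   resample_days: float = 0.125) -> PlateauEstimate:
    """Find the longest interval of significantly sub-exponential growth.

    The cumulative-PD curve is interpolated onto a uniform time grid and a
    centred moving-window rate (PD/day over ``window_days``) is computed.
    The baseline is the realized mean rate over the first passage (or over
    ``baseline_days`` when the record has no passage bookkeeping, e.g. a
    synthetic curve); the plateau is the longest contiguous stretch whose
    smoothed rate falls below ``rate_threshold_fraction`` times baseline.
    Width 0 means no plateau.
    """
    if not 0 < rate_threshold_fraction < 1:
        raise ConfigurationError("rate_threshold_fraction must be in (0, 1)")
    if "time_days" not in record.columns or "cumulative_pd" not in record.columns:
        raise AnalysisError("record needs time_days and cumulative_pd columns")
    rec = record.sort_values("time_days")
    t = rec["time_days"].to_numpy(dtype=float)
    y = rec["cumulative_pd"].to_numpy(dtype=float)
    if t.size < 3 or t[-1] - t[0] <= window_days:
        raise AnalysisError("record too short for plateau detection")

    if baseline_days is None:
        if "passage" not in rec.columns or rec["passage"].max() < 1:
            raise AnalysisError(
                "record spans fewer than 2 passages; pass baseline_days")
        first = rec[rec["passage"] == 0]
        baseline_days = float(first["time_days"].max())
    if baseline_days <= 0:
        raise AnalysisError("baseline window is empty")
    baseline_rate = float(np.interp(baseline_days, t, y)
                          - np.interp(0.0, t, y)) / baseline_days
    if baseline_rate <= 0:
        raise AnalysisError("no growth in the baseline window")

    grid = np.arange(t[0], t[-1] + resample_days / 2, resample_days)
    pd_grid = np.interp(grid, t, y)
    half = window_days / 2.0
    lo = np.interp(np.clip(grid - half, t[0], t[-1]), grid, pd_grid)
    hi = np.interp(np.clip(grid + half, t[0], t[-1]), grid, pd_grid)
    span = np.clip(grid + half, t[0], t[-1]) - np.clip(grid - half, t[0], t[-1])
    rate = (hi - lo) / np.maximum(span, 1e-12)

    threshold = rate_threshold_fraction * baseline_rate
    below = rate < threshold

    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for i, flag in enumerate(below):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len == 0:
        return PlateauEstimate(start=float("nan"), width=0.0,
                               baseline_rate=baseline_rate,
                               threshold_used=rate_threshold_fraction)
    start = float(grid[best_start])
    width = float(best_len * resample_days)
    censored = bool(best_start + best_len >= below.size)
    return PlateauEstimate(start=start, width=width,
                           baseline_rate=baseline_rate,
                           threshold_used=rate_threshold_fraction,
                           censored=censored)


@dataclass
class PowerLawFit:
    """W = a * f^(-b), fitted by ordinary least squares in log-log space."""

    a: float                # days (scale at f = 1)
    b: float                # positive exponent
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    f_range: tuple = (0.0, 0.0)

    def predict(self, f) -> np.ndarray:
        return self.a * np.asarray(f, dtype=float) ** (-self.b)


def fit_plateau_power_law(points: Sequence[tuple]) -> PowerLawFit:
    """Fit log W = log a - b log f to (initial fraction, plateau width) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise AnalysisError("points must be (f, W) pairs")
    f, w = pts[:, 0], pts[:, 1]
    if np.any(f <= 0) or np.any(w <= 0):
        raise AnalysisError("fractions and widths must be positive")
    if np.unique(f).size < 3:
        raise AnalysisError("need at least 3 distinct fractions")
    res = stats.linregress(np.log(f), np.log(w))
    b = -res.slope
    a = math.exp(res.intercept)
    if b <= 0:
        raise AnalysisError(
            f"fitted exponent is not positive (b = {b:.3g}); widths do not "
            "decrease with the initial fraction")
    residuals = np.log(w) - (res.intercept + res.slope * np.log(f))
    return PowerLawFit(a=a, b=b, r_squared=res.rvalue ** 2,
                       residuals=residuals,
                       f_range=(float(f.min()), float(f.max())))


def infer_initial_fraction(fit: PowerLawFit, width: float) -> float:
    """Invert the power law: f = (a / W)^(1/b) for an observed plateau width."""
    if width <= 0:
        raise AnalysisError("plateau width must be positive")
    f = (fit.a / width) ** (1.0 / fit.b)
    lo, hi = fit.f_range
    if lo > 0 and not (lo <= f <= hi):
        warnings.warn(
            f"inferred fraction {f:.4g} lies outside the fitted range "
            f"[{lo:.4g}, {hi:.4g}]; extrapolating")
    return f


def relative_standard_error(records: Sequence[pd.DataFrame],
                            resample_days: float = 0.25,
                            min_mean_pd: float = 1.0) -> pd.DataFrame:
    """Per-timepoint mean, SE and RSE of cumulative PD across replicates.

    Records are interpolated onto a shared uniform time grid spanning the
    shortest replicate.  RSE = SE/mean is reported where the mean curve has
    passed ``min_mean_pd`` doublings (a relative error is not meaningful
    around zero).  With a single replicate the SE/RSE columns are NaN.
    The result carries ``attrs['max_rse']`` (NaN when not applicable).
    """
    if len(records) == 0:
        raise AnalysisError("no records given")
    t_end = min(float(r["time_days"].max()) for r in records)
    grid = np.arange(0.0, t_end + resample_days / 2, resample_days)
    curves = np.vstack([
        np.interp(grid, r["time_days"].to_numpy(dtype=float),
                  r["cumulative_pd"].to_numpy(dtype=float))
        for r in records
    ])
    mean = curves.mean(axis=0)
    if len(records) >= 2:
        se = curves.std(axis=0, ddof=1) / math.sqrt(len(records))
        with np.errstate(divide="ignore", invalid="ignore"):
            rse = np.where(mean >= min_mean_pd, se / mean, np.nan)
    else:
        se = np.full_like(mean, np.nan)
        rse = np.full_like(mean, np.nan)
    out = pd.DataFrame({
        "time_days": grid,
        "mean_cumulative_pd": mean,
        "se_cumulative_pd": se,
        "rse_cumulative_pd": rse,
    })
    finite = rse[np.isfinite(rse)] if len(records) >= 2 else np.array([])
    out.attrs["max_rse"] = float(finite.max()) if finite.size else float("nan")
    out.attrs["n_replicates"] = len(records)
    return out
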