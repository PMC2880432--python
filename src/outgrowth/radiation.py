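"""Radiation-induced senescence: exponential dose response per cell class.

The surviving (non-senescent) fraction of a population after an acute dose
D follows e^(-alpha*D), with a class-specific rate alpha per Gy.  Normal
cells are far more radiosensitive than p16-silenced variant cells, so an
irradiated culture converts mostly normal cells to the senescent state,
freeing surface area into which the radioresistant variants expand.

Default alpha values are derived from the reported assay bounds: a 2 Gy
exposure senesces >40% of pre-stasis (normal) but <5% of post-stasis
(variant) cells, >=6 Gy senesces >90% of normal cells, and 10 Gy senesces
<20% of variant cells.  alpha_normal = 0.4/Gy and alpha_variant = 0.02/Gy
satisfy all four bounds (55% and 90.9% vs 3.9% and 18.1%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .lattice import ConfigurationError

ALPHA_NORMAL_DEFAULT = 0.4   # per Gy
ALPHA_VARIANT_DEFAULT = 0.02  # per Gy

GY_PER_CGY = 0.01

ASSAY_COLUMNS = ("cell_class", "dose_gy", "sa_bgal_negative_fraction")


class FittingError(RuntimeError):
    """Dose-response data unusable for fitting."""


@dataclass
class SenescenceAssay:
    """Rows of (dose in Gy, SA-beta-gal negative fraction) for one cell class.

    ``normalized`` means the fractions are already relative to the
    unirradiated population; otherwise a dose-0 row must be present and the
    table is normalized on construction of a fit.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        missing = [c for c in ASSAY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"assay table missing columns: {missing}")
        if (self.data["dose_gy"] < 0).any():
            raise ConfigurationError("doses must be >= 0")
        y = self.data["sa_bgal_negative_fraction"]
        if ((y < 0) | (y > 1.0 + 1e-9)).any():
            raise ConfigurationError("fractions must be in [0, 1]")

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "SenescenceAssay":
        return cls(pd.read_csv(path, comment="#"), normalized=normalized)

    def classes(self) -> list[str]:
        return sorted(self.data["cell_class"].unique())

    def for_class(self, cell_class: str) -> pd.DataFrame:
        sub = self.data[self.data["cell_class"] == cell_class]
        if sub.empty:
            raise ConfigurationError(f"no assay rows for class {cell_class!r}")
        return sub


@dataclass
class DoseResponseFit:
    """Fitted survival curve e^(-alpha*D) for one cell class."""

    alpha: float
    r_squared: float
    cell_class: str

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")


@dataclass
class RadiationEvent:
    """An acute exposure applied to a running simulation.

    ``alphas`` maps cell class -> per-Gy senescence rate (a
    :class:`DoseResponseFit` is also accepted per class).
    """

    dose_gy: float
    time_hours: float = 0.0
    alphas: dict = field(default_factory=lambda: {
        "normal": ALPHA_NORMAL_DEFAULT,
        "variant": ALPHA_VARIANT_DEFAULT,
    })

    def __post_init__(self):
        if self.dose_gy < 0:
            raise ConfigurationError("dose must be >= 0")

    def alpha_for(self, cell_class: str) -> float:
        try:
            a = self.alphas[cell_class]
        except KeyError:
            raise ConfigurationError(
                f"no dose-response coefficient for class {cell_class!r}")
        return a.alpha if isinstance(a, DoseResponseFit) else float(a)


def fit_alpha(assay: SenescenceAssay, cell_class: Optional[str] = None
              ) -> DoseResponseFit:
    """Least-squares fit of e^(-alpha*D) to normalized surviving fractions.

    The fit runs on the natural scale (not log-linearized, which would
    overweight near-zero fractions); R^2 is computed on the same scale.  A
    best fit that would want alpha < 0 is clipped to 0 with a warning.
    """
    if cell_class is None:
        classes = assay.classes()
        if len(classes) != 1:
            raise ConfigurationError(
                f"assay contains classes {classes}; pass cell_class explicitly")
        cell_class = classes[0]
    sub = assay.for_class(cell_class)
    doses = sub["dose_gy"].to_numpy(dtype=float)
    y = sub["sa_bgal_negative_fraction"].to_numpy(dtype=float)

    if len(np.unique(doses)) < 2:
        raise FittingError("need at least two distinct doses")
    if np.all(doses == 0):
        raise FittingError("all doses are zero")

    if not assay.normalized:
        at_zero = y[doses == 0]
        if at_zero.size == 0:
            raise FittingError("unnormalized assay must contain dose 0")
        y = y / at_zero.mean()

    # log-linear starting value, clipped into the feasible region
    pos = (y > 0) & (doses > 0)
    if pos.any():
        slope = -np.polyfit(doses[pos], np.log(y[pos]), 1)[0]
    else:
        slope = 1.0
    p0 = max(slope, 0.0)
    if slope < 0:
        warnings.warn("best-fit alpha would be negative; clipping to 0")

    try:
        popt, _ = curve_fit(lambda d, a: np.exp(-a * d), doses, y,
                            p0=[max(p0, 1e-6)], bounds=(0.0, np.inf))
        alpha = float(popt[0])
    except RuntimeError as exc:  # pragma: no cover - bounded 1-param fit
        raise FittingError(f"dose-response fit failed: {exc}")

    # alpha = 0 is a boundary optimum (e.g. constant survival); prefer it
    # exactly whenever it fits at least as well as the interior solution
    if np.sum((y - np.exp(-alpha * doses)) ** 2) >= np.sum((y - 1.0) ** 2) - 1e-15:
        alpha = 0.0

    resid = y - np.exp(-alpha * doses)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return DoseResponseFit(alpha=alpha, r_squared=r2, cell_class=cell_class)


def induced_senescent_fraction(fit: DoseResponseFit, dose_gy: float) -> float:
    """Probability 1 - e^(-alpha*D) that a proliferative cell senesces at D Gy."""
    if dose_gy < 0:
        raise ConfigurationError("dose must be >= 0")
    return 1.0 - math.exp(-fit.alpha * dose_gy)


def irradiate(state, event: RadiationEvent):
    """Apply an acute exposure to a simulation state, in place.

    Every proliferative cell converts to the permanent senescent state
    independently with its class-specific probability 1 - e^(-alpha*D);
    already-senescent cells, footprints and counts are untouched.
    """
    state.radiation_applied = True
    if event.dose_gy == 0:
        return state
    probs = {}
    targets = [a for a in state.agents.values() if a.state == "proliferative"]
    for a in targets:
        if a.cell_class not in probs:
            alpha = event.alpha_for(a.cell_class)
            probs[a.cell_class] = 1.0 - math.exp(-alpha * event.dose_gy)
    if not targets:
        return state
    draws = state.rng.random(len(targets))
    for a, u in zip(targets, draws):
        if u < probs[a.cell_class]:
            state.senesce(a)
    return state


def senescence_induction_index(ps0: float, psd: float) -> float:
    """Radiation-induced senescence corrected for pre-existing senescence.

    (Ps(D) - Ps(0)) / (1 - Ps(0)), where Ps(0) and Ps(D) are the senescent
    fractions before and after a dose D.  The 1 - Ps(0) factor removes the
    cells that were already senescent from the susceptible denominator.  A
    negative result (Ps(D) < Ps(0)) is reported, not clipped.
    """
    if not (0.0 <= ps0 < 1.0):
        raise ConfigurationError("ps0 must be in [0, 1)")
    if not (0.0 <= psd <= 1.0):
        raise ConfigurationError("psd must be in [0, 1]")
    return (psd - ps0) / (1.0 - ps0)
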