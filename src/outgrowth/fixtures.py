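"""Synthetic fixtures: pure, seeded generators for testing every layer.

Three generators:

* ``dose_response_table`` -- assay tables drawn from the exponential
  survival model 1 - e^(-alpha*D) with optional multiplicative noise, for
  exercising the dose-response fitter against a known truth;
* ``growth_curve_table`` -- piecewise exponential / plateau / exponential
  cumulative-PD curves with a planted plateau width, for exercising the
  plateau detector;
* ``lattice_state`` -- a populated grid with a prescribed occupancy
  pattern, for engine tests.

All generators are pure functions of their arguments (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import (
    ConfigurationError,
    Grid,
    SeedingSpec,
    create_grid,
    seed_agents,
)


def dose_response_table(alpha: float = 0.4,
                        doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0),
                        noise_sigma: float = 0.0, seed: int = 0,
                        cell_class: str = "normal") -> pd.DataFrame:
    """Assay table of surviving (senescence-marker-negative) fractions.

    Values are e^(-alpha*D), multiplied by lognormal noise of the given
    sigma and clipped to [0, 1]; already normalized to the unirradiated
    population.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(doses, dtype=float)
    y = np.exp(-alpha * d)
    if noise_sigma > 0:
        y = y * rng.lognormal(mean=0.0, sigma=noise_sigma, size=d.size)
    y = np.clip(y, 0.0, 1.0)
    return pd.DataFrame({
        "cell_class": cell_class,
        "dose_gy": d,
        "sa_bgal_negative_fraction": y,
    })


def growth_curve_table(baseline_rate: float = 0.85,
                       pre_days: float = 8.0,
                       plateau_width: float = 20.0,
                       plateau_rate: float = 0.0,
                       post_days: float = 10.0,
                       sample_every_days: float = 0.125,
                       noise_sigma: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Cumulative-PD record with a planted plateau of known width.

    Exponential growth at ``baseline_rate`` PD/day for ``pre_days``, a flat
    (or ``plateau_rate``) segment of ``plateau_width`` days, then resumed
    growth for ``post_days``.  A synthetic passage column marks the first
    2.7 days as passage 0 so the detector can derive its baseline the same
    way it does for simulation records.
    """
    if plateau_width < 0 or pre_days <= 0:
        raise ConfigurationError("pre_days must be positive, width >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, pre_days + plateau_width + post_days + sample_every_days,
                  sample_every_days)
    pd_curve = np.piecewise(
        t,
        [t < pre_days,
         (t >= pre_days) & (t < pre_days + plateau_width),
         t >= pre_days + plateau_width],
        [lambda x: baseline_rate * x,
         lambda x: baseline_rate * pre_days + plateau_rate * (x - pre_days),
         lambda x: (baseline_rate * pre_days + plateau_rate * plateau_width
                    + baseline_rate * (x - pre_days - plateau_width))])
    if noise_sigma > 0:
        pd_curve = pd_curve + rng.normal(0.0, noise_sigma, size=t.size)
    first_boundary = min(2.7, pre_days)
    passage = np.where(t <= first_boundary, 0,
                       1 + np.floor((t - first_boundary) / 2.7)).astype(int)
    return pd.DataFrame({
        "time_days": t,
        "passage": passage,
        "cumulative_pd": pd_curve,
    })


def lattice_state(n_agents: int, grid_width: int = 400, grid_height: int = 400,
                  area: int = 21, class_mix: float = 0.0, seed: int = 0
                  ) -> tuple[Grid, list]:
    """A grid populated with ``n_agents`` blobs of ``area`` pixels each."""
    grid = create_grid(grid_width, grid_height)
    spec = SeedingSpec(n_agents=n_agents, class_mix=class_mix, seed=seed)
    agents = seed_agents(grid, spec, max_area=area)
    return grid, agents


@dataclass
class FixtureSpec:
    """Declarative fixture request for the CLI ``make-fixture`` command."""

    generator: str  # dose_response | growth_curve | lattice_state
    params: dict = field(default_factory=dict)
    seed: int = 0


def generate_fixture(spec: FixtureSpec, out_dir) -> list[Path]:
    """Materialize a fixture as CSV file(s); returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec.generator == "dose_response":
        df = dose_response_table(seed=spec.seed, **spec.params)
        path = out / "dose_response.csv"
        df.to_csv(path, index=False)
        return [path]
    if spec.generator == "growth_curve":
        df = growth_curve_table(seed=spec.seed, **spec.params)
        path = out / "growth_curve.csv"
        df.to_csv(path, index=False)
        return [path]
    if spec.generator == "lattice_state":
        grid, _ = lattice_state(seed=spec.seed, **spec.params)
        path = out / "lattice_labels.txt"
        np.savetxt(path, grid.occupancy, fmt="%d")
        return [path]
    raise ConfigurationError(f"unknown fixture generator {spec.generator!r}")
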