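"""Serial subculture driver: saturation-triggered harvest and replating.

A culture is grown until it covers 80% of the surface, then harvested.
Replating draws the plating aliquot (1,200 cells by default) uniformly from
the whole harvest; senescent cells in the aliquot fail to reattach and are
lost, so each new passage starts with only the proliferative members of the
aliquot, re-dispersed at random on a fresh surface.  Population doublings
accumulate as log2(collected/plated) per passage -- the experimental
bookkeeping, whose plated denominator includes the non-attaching senescent
cells and therefore flattens into a plateau while the culture is dominated
by senescent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lattice import (
    ConfigurationError,
    SeedingSpec,
    confluence,
    create_grid,
    place_blob,
)
from .dynamics import (
    DynamicsParams,
    PROLIFERATIVE,
    SimulationState,
    new_simulation,
    record_growth,
    step,
)
from .radiation import RadiationEvent, irradiate


@dataclass
class PassageConfig:
    """Serial-passage protocol parameters.

    seed_count: cells plated per passage (1,200 = 20% seeding on the default
    grid); trigger_saturation: confluence that triggers subculture (0.80);
    replicates: independent simulations averaged per condition (5);
    max_sim_days guards non-terminating all-variant runs; stop_pd optionally
    ends a run once the cumulative-PD curve has passed the feature of
    interest (e.g. a plateau plus resumed growth).

    ``max_passage_days`` subcultures a passage that has not reached the
    saturation trigger after this many days, mirroring the experimental
    protocol (stalled, senescent-dominated cultures are still harvested on
    a roughly monthly schedule).  Without it, a variant colony whose rim
    lineages exhaust their division budget gets entombed in its own
    senescent crust, permanently trapping contact-inhibited interior cells
    that trypsinization would release.
    """

    seed_count: int = 1200
    trigger_saturation: float = 0.80
    max_passages: int = 100
    max_sim_days: float = 120.0
    replicates: int = 5
    record_every_hours: float = 2.0
    stop_pd: Optional[float] = None
    sampling: str = "proportional"
    max_passage_days: float = 28.0

    def __post_init__(self):
        if self.sampling not in ("proportional", "uniform"):
            raise ConfigurationError(
                "sampling must be 'proportional' or 'uniform'")
        if self.max_passage_days <= 0:
            raise ConfigurationError("max_passage_days must be positive")
        if not (0.0 < self.trigger_saturation <= 1.0):
            raise ConfigurationError("trigger_saturation must be in (0, 1]")
        if self.seed_count < 0:
            raise ConfigurationError("seed_count must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.max_sim_days <= 0 or self.max_passages < 0:
            raise ConfigurationError("horizon must be positive")


def should_passage(state: SimulationState, config: PassageConfig) -> bool:
    """True once the culture has reached the saturation trigger."""
    return confluence(state.grid) >= config.trigger_saturation


def passage(state: SimulationState, config: PassageConfig,
            params: DynamicsParams) -> SimulationState:
    """Harvest the culture and replate onto a fresh grid.

    The plating aliquot (``seed_count`` cells, or everything if fewer) is
    drawn from the whole harvest; senescent members of the aliquot do not
    reattach.  Survivors keep their class and division count, are re-placed
    at uncrowded size with fresh random positions and cycle phases, and the
    passage counter and PD ledger advance.  A harvest whose aliquot
    contains no proliferative cell leaves an empty, terminated culture.

    Sampling modes.  ``proportional`` (default) splits the well-mixed
    harvest suspension in proportion: each (class, state) subpopulation
    contributes round(n_plate * share) cells (largest-remainder
    apportionment), with the individual cells of each subpopulation chosen
    uniformly.  This mirrors a real subculture, where the ~10^6-cell
    suspension makes composition drift negligible; per-agent multinomial
    sampling at the model's ~6,000-agent scale would exaggerate that drift
    ~100-fold (and can extinguish a rare variant clone by pure bookkeeping).
    ``uniform`` draws the aliquot uniformly without replacement, keeping the
    full sampling noise.
    """
    harvest = list(state.agents.values())
    collected = len(harvest)
    if collected == 0:
        state.terminated = True
        return state

    if state.plated_count > 0:
        state.pd_completed += max(0.0, math.log2(collected / state.plated_count))

    n_plate = min(config.seed_count, collected)
    if config.sampling == "uniform":
        idx = state.rng.choice(collected, size=n_plate, replace=False)
        aliquot = [harvest[int(i)] for i in idx]
    else:
        groups: dict = {}
        for a in harvest:
            groups.setdefault((a.cell_class, a.state), []).append(a)
        keys = sorted(groups)
        shares = [len(groups[k]) * n_plate / collected for k in keys]
        quotas = [int(math.floor(s)) for s in shares]
        remainders = [s - q for s, q in zip(shares, quotas)]
        for i in sorted(range(len(keys)), key=lambda j: (-remainders[j], keys[j])):
            if sum(quotas) >= n_plate:
                break
            quotas[i] += 1
        aliquot = []
        for k, q in zip(keys, quotas):
            members = groups[k]
            q = min(q, len(members))
            idx = state.rng.choice(len(members), size=q, replace=False)
            aliquot.extend(members[int(i)] for i in idx)
    attached = [a for a in aliquot if a.state == PROLIFERATIVE]

    # fresh surface
    grid = create_grid(state.grid.width, state.grid.height, state.grid.pixel_area)
    state.grid = grid
    state.agents = {}
    for key in state.counts:
        state.counts[key] = 0
    state.plated_count = n_plate
    state.passage_index += 1

    if not attached:
        state.terminated = True
        return state

    for a in attached:
        blob = place_blob(grid, a.id, params.max_area, state.rng)
        if blob is None:  # pragma: no cover - replating density is ~20%
            raise RuntimeError("replating failed to find space")
        a.footprint.pixels = blob
        a.cycle_phase = float(state.rng.uniform(0.0, params.cycle_hours))
        a.parked_epoch = None  # fresh grid, fresh neighbourhood
        state.add_agent(a)
    return state


def run_serial_culture(dynamics: DynamicsParams, passaging: PassageConfig,
                       seeding: SeedingSpec,
                       radiation: Optional[RadiationEvent] = None,
                       grid_width: int = 400, grid_height: int = 400,
                       pixel_area: Optional[float] = None,
                       seed: Optional[int] = None,
                       replicate: int = 0) -> pd.DataFrame:
    """Run one multi-passage culture and return its growth record.

    The record has one row per ``record_every_hours`` plus a row at every
    passage boundary; it stops at ``max_passages``, ``max_sim_days``,
    ``stop_pd`` or terminal emptiness.  An optional radiation event converts
    proliferative cells to the senescent state when the clock reaches its
    scheduled time.
    """
    state = new_simulation(seeding, dynamics, grid_width=grid_width,
                           grid_height=grid_height, pixel_area=pixel_area,
                           seed=seed)
    rows = [record_growth(state, replicate)]
    record_gap = max(passaging.record_every_hours, dynamics.dt)
    next_record = record_gap
    passage_started = 0.0

    if (radiation is not None and not state.radiation_applied
            and radiation.time_hours <= 0.0):
        irradiate(state, radiation)

    while True:
        if state.clock / 24.0 >= passaging.max_sim_days:
            break
        if passaging.stop_pd is not None and state.cumulative_pd() >= passaging.stop_pd:
            break
        if state.terminated or state.n_proliferative == 0:
            # nothing will ever divide again; extend the record to the
            # horizon so replicate averaging has a shared time base
            state.terminated = True
            state.clock = passaging.max_sim_days * 24.0
            rows.append(record_growth(state, replicate))
            break
        step(state, dynamics)
        if (radiation is not None and not state.radiation_applied
                and state.clock >= radiation.time_hours):
            irradiate(state, radiation)
        if state.clock >= next_record - 1e-9:
            rows.append(record_growth(state, replicate))
            next_record += record_gap
        overdue = (state.clock - passage_started
                   >= passaging.max_passage_days * 24.0)
        if should_passage(state, passaging) or overdue:
            if state.passage_index + 1 > passaging.max_passages:
                break
            rows.append(record_growth(state, replicate))
            passage(state, passaging, dynamics)
            passage_started = state.clock
            rows.append(record_growth(state, replicate))

    df = pd.DataFrame(rows)
    df.attrs["terminated"] = state.terminated
    df.attrs["seed"] = seed
    return df


def run_replicates(dynamics: DynamicsParams, passaging: PassageConfig,
                   seeding: SeedingSpec, n: Optional[int] = None,
                   base_seed: int = 0,
                   radiation: Optional[RadiationEvent] = None,
                   grid_width: int = 400, grid_height: int = 400,
                   pixel_area: Optional[float] = None
                   ) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Run ``n`` independently seeded replicates (seeds ``base_seed + i``).

    Returns the individual growth records and a per-timepoint summary with
    the mean, standard error and relative standard error of cumulative PD
    (see :func:`outgrowth.analysis.relative_standard_error`).
    """
    from .analysis import relative_standard_error

    if n is None:
        n = passaging.replicates
    if n < 1:
        raise ConfigurationError("need at least one replicate")
    records = []
    for i in range(n):
        rec = run_serial_culture(dynamics, passaging, seeding,
                                 radiation=radiation, grid_width=grid_width,
                                 grid_height=grid_height,
                                 pixel_area=pixel_area,
                                 seed=base_seed + i, replicate=i)
        records.append(rec)
    summary = relative_standard_error(records)
    return records, summary


def sweep_initial_fractions(fractions, dynamics: DynamicsParams,
                            passaging: PassageConfig, seed_count: int = 1200,
                            replicates_per_fraction: int = 1,
                            base_seed: int = 0,
                            radiation: Optional[RadiationEvent] = None,
                            grid_width: int = 400, grid_height: int = 400,
                            rate_threshold_fraction: float = 0.25,
                            window_days: float = 2.0) -> pd.DataFrame:
    """Measure plateau width across initial variant fractions.

    Runs ``replicates_per_fraction`` serial cultures at each fraction and
    returns one row per run: fraction, replicate, plateau width and start,
    and whether the width is censored (plateau never ended within the
    horizon, e.g. variant lineage lost at replating) -- censored rows should
    be excluded from power-law fitting.
    """
    from .analysis import detect_plateau

    rows = []
    run_index = 0
    for f in fractions:
        for r in range(replicates_per_fraction):
            seeding = SeedingSpec(n_agents=seed_count, class_mix=float(f))
            rec = run_serial_culture(
                dynamics, passaging, seeding, radiation=radiation,
                grid_width=grid_width, grid_height=grid_height,
                seed=base_seed + run_index)
            run_index += 1
            est = detect_plateau(rec,
                                 rate_threshold_fraction=rate_threshold_fraction,
                                 window_days=window_days)
            rows.append({
                "initial_fraction": float(f),
                "replicate": r,
                "plateau_width_days": est.width,
                "plateau_start_days": est.start,
                "censored": est.censored or bool(rec.attrs.get("terminated")),
            })
    return pd.DataFrame(rows)
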