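"""Time-stepped population dynamics: space-gated division and senescence.

Four rules govern every cell:

1. a cell divides when its cycle completes, provided there is open space in
   its immediate surroundings;
2. when space is scarce the division still happens, but the daughters are
   *compressed*, down to a minimum footprint;
3. a cell that has completed its class-specific division limit permanently
   converts to a senescent state and never divides again;
4. senescent cells are lost at subculture (they do not reattach; enforced by
   the passaging layer).

Division is strictly local: daughters are carved out of the mother's own
pixels plus free space reachable within a few pixels of her boundary.  A
cell buried inside a confluent patch therefore cannot divide until space
opens nearby, which makes colonies of unlimited-division cells expand at
their rim -- the spatial mechanism behind the growth plateau and its
dependence on the initial variant fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lattice import (
    DEFAULT_MAX_AREA,
    DEFAULT_MIN_AREA,
    ConfigurationError,
    Footprint,
    Grid,
    SeedingSpec,
    accrete_blob,
    confluence,
    create_grid,
    accrete_in_mask,
    free_mask_near,
    free_pixels_near,
    partition_pool,
    seed_agents,
)

NORMAL = "normal"
VARIANT = "variant"
PROLIFERATIVE = "proliferative"
SENESCENT = "senescent"

# attempt_division outcomes
DIVIDED = "divided"
COMPRESSED_DIVIDED = "compressed_divided"
BLOCKED = "blocked"
CONVERTED_SENESCENT = "converted_senescent"


@dataclass
class Agent:
    """One cell: class, state, footprint, division history, cycle phase."""

    id: int
    cell_class: str
    state: str
    footprint: Footprint
    divisions_completed: int = 0
    division_limit: Optional[int] = None  # None = unbounded
    cycle_phase: float = 0.0  # hours into the current cycle
    # last grid erase epoch at which this cell found itself unable to divide
    # or spread; while no nearby pixel has been freed since, the attempt is
    # skipped (free space only ever appears through erasure)
    parked_epoch: Optional[int] = None

    @property
    def proliferative(self) -> bool:
        return self.state == PROLIFERATIVE

    def at_limit(self) -> bool:
        return (self.division_limit is not None
                and self.divisions_completed >= self.division_limit)


@dataclass
class DynamicsParams:
    """Engine parameters.

    cycle_hours
        Cell-cycle duration during the proliferative phase; 26 h for both
        cell classes.
    max_area / min_area
        Uncrowded and fully-compressed footprint sizes in pixels (21 and 6;
        175 and 50 um^2 at the default calibration).
    division_limit_normal / division_limit_variant
        Divisions before permanent senescent conversion; ``None`` disables
        the limit.  7 (normal) and 40 (variant) in the serial-passage
        scenario, 3 / unlimited in the co-culture validation scenario.
    dt
        Step size in hours.
    senescent_area
        Footprint (pixels) a cell spreads to on senescent conversion --
        senescent epithelial cells are enlarged and flat; the default is
        twice the uncrowded proliferative size (42 px = 350 um^2 at the
        default calibration).  Enlargement is one-time, local, and partial
        when crowded.
    division_search_radius
        How far (Chebyshev pixels from the footprint) a dividing cell may
        reach for open space.  The default, 7 px (~1.3 uncrowded cell
        diameters), lets a daughter displace past one flat senescent
        neighbour and yields a colony front speed of ~5 px per cycle --
        about one cell diameter per division round, the natural advance
        rate of a rim-limited epithelial colony.
    """

    cycle_hours: float = 26.0
    max_area: int = DEFAULT_MAX_AREA
    min_area: int = DEFAULT_MIN_AREA
    division_limit_normal: Optional[int] = 7
    division_limit_variant: Optional[int] = 40
    dt: float = 1.0
    division_search_radius: int = 7
    senescent_area: int = 42

    def __post_init__(self):
        if not (0 < self.min_area <= self.max_area):
            raise ConfigurationError("need 0 < min_area <= max_area")
        if self.cycle_hours <= 0:
            raise ConfigurationError("cycle_hours must be positive")
        if not (0 < self.dt <= self.cycle_hours):
            raise ConfigurationError("need 0 < dt <= cycle_hours")
        if self.division_search_radius < 1:
            raise ConfigurationError("division_search_radius must be >= 1")
        if self.senescent_area < self.min_area:
            raise ConfigurationError("senescent_area must be >= min_area")

    def limit_for(self, cell_class: str) -> Optional[int]:
        return (self.division_limit_normal if cell_class == NORMAL
                else self.division_limit_variant)


class SimulationState:
    """Grid + agents + clock + RNG stream, advanced by :func:`step`.

    Maintains per-(class, state) counts and population-doubling bookkeeping
    incrementally so that growth recording is O(1).
    """

    def __init__(self, grid: Grid, rng: np.random.Generator,
                 params: Optional["DynamicsParams"] = None):
        self.grid = grid
        self.rng = rng
        self.params = params
        self.agents: dict[int, Agent] = {}
        self.clock: float = 0.0  # hours
        self.passage_index: int = 0
        self.next_id: int = 1
        self.plated_count: int = 0   # B of the current passage (PD bookkeeping)
        self.pd_completed: float = 0.0  # summed log2(A/B) of finished passages
        self.terminated: bool = False
        self.radiation_applied: bool = False
        self.counts = {
            (NORMAL, PROLIFERATIVE): 0,
            (NORMAL, SENESCENT): 0,
            (VARIANT, PROLIFERATIVE): 0,
            (VARIANT, SENESCENT): 0,
        }

    # -- bookkeeping ------------------------------------------------------
    def add_agent(self, agent: Agent) -> None:
        self.agents[agent.id] = agent
        self.counts[(agent.cell_class, agent.state)] += 1

    def remove_agent(self, agent: Agent) -> None:
        del self.agents[agent.id]
        self.counts[(agent.cell_class, agent.state)] -= 1

    def senesce(self, agent: Agent) -> None:
        """Permanent senescent conversion, with one-time enlargement.

        Senescent epithelial cells are enlarged and flattened; on
        conversion the footprint spreads into adjacent free pixels toward
        ``params.senescent_area`` (partially, if crowded) and is static
        ever after.
        """
        if agent.state == SENESCENT:
            return
        self.counts[(agent.cell_class, PROLIFERATIVE)] -= 1
        self.counts[(agent.cell_class, SENESCENT)] += 1
        agent.state = SENESCENT
        params = self.params
        if (params is not None
                and params.senescent_area > agent.footprint.area
                and agent.id in self.agents
                and _window_has_free(self.grid, agent,
                                     params.division_search_radius)):
            free = free_pixels_near(self.grid, agent.footprint.pixels,
                                    params.division_search_radius)
            if free:
                _respread(self.grid, agent, free, params.senescent_area)

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def n_proliferative(self) -> int:
        return (self.counts[(NORMAL, PROLIFERATIVE)]
                + self.counts[(VARIANT, PROLIFERATIVE)])

    def cumulative_pd(self) -> float:
        """Cumulative population doublings, experimental bookkeeping.

        Completed passages contribute log2(collected/plated); the running
        passage contributes log2(current/plated), floored at zero because
        plated senescent cells that failed to attach are still part of the
        plated denominator (the same undercount the wet-lab PD formula has).
        """
        if self.plated_count <= 0:
            return self.pd_completed
        within = math.log2(max(self.n_agents, 1) / self.plated_count)
        return self.pd_completed + max(0.0, within)


def new_simulation(seeding: SeedingSpec, params: DynamicsParams,
                   grid_width: int = 400, grid_height: int = 400,
                   pixel_area: Optional[float] = None,
                   seed: Optional[int] = None) -> SimulationState:
    """Create a grid, plate the initial population, and return the state."""
    kwargs = {} if pixel_area is None else {"pixel_area": pixel_area}
    grid = create_grid(grid_width, grid_height, **kwargs)
    rng = np.random.default_rng(seed if seed is not None else seeding.seed)
    state = SimulationState(grid, rng, params)
    agents = seed_agents(grid, seeding, max_area=params.max_area,
                         cycle_hours=params.cycle_hours, rng=rng,
                         id_start=state.next_id)
    for a in agents:
        a.division_limit = params.limit_for(a.cell_class)
        state.add_agent(a)
    state.next_id += len(agents)
    state.plated_count = max(seeding.n_agents, 1) if agents else 0
    if seeding.n_agents > 0:
        state.plated_count = seeding.n_agents
    return state


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

def _window_has_free(grid: Grid, agent: Agent, radius: int) -> bool:
    """Cheap prefilter: any free pixel in the bounding window of the agent?"""
    r0, c0, r1, c1 = agent.footprint.bounding_box()
    win = grid.occupancy[max(0, r0 - radius):r1 + radius + 1,
                         max(0, c0 - radius):c1 + radius + 1]
    return not win.all()


def _respread(grid: Grid, agent: Agent, free: set, max_area: int) -> int:
    """Grow a compressed cell into adjacent free pixels, toward ``max_area``.

    Accretes footprint-adjacent members of ``free`` nearest the centroid,
    one at a time (so the footprint stays 8-connected).  Returns the number
    of pixels gained.
    """
    from .lattice import _NEIGH8

    pixels = agent.footprint.pixels
    gained = 0
    remaining = set(free) - pixels
    if not remaining:
        return 0
    candidates = {q for q in remaining
                  if any((q[0] + dr, q[1] + dc) in pixels
                         for dr, dc in _NEIGH8)}
    sum_r = sum(p[0] for p in pixels)
    sum_c = sum(p[1] for p in pixels)
    while len(pixels) < max_area and candidates:
        n = len(pixels)
        cy, cx = sum_r / n, sum_c / n
        best = None
        bd = 0.0
        for q in candidates:
            d = (q[0] - cy) ** 2 + (q[1] - cx) ** 2
            if best is None or d < bd or (d == bd and q < best):
                best, bd = q, d
        candidates.discard(best)
        remaining.discard(best)
        grid.paint([best], agent.id)
        pixels.add(best)
        sum_r += best[0]
        sum_c += best[1]
        gained += 1
        for dr, dc in _NEIGH8:
            q = (best[0] + dr, best[1] + dc)
            if q in remaining and q not in candidates:
                candidates.add(q)
    return gained


def attempt_division(state: SimulationState, agent: Agent,
                     params: DynamicsParams) -> str:
    """Resolve one due division. Returns the outcome class.

    Order of checks: division-limit conversion (rule 3); uncrowded division
    (rule 1: enough open space in the surrounding neighbourhood, daughter
    placed at full size); compressed division (rule 2: mother plus local
    free space split into two footprints down to the minimum size); else
    blocked, with the completed timer held so that space freed later is
    used at the next step.
    """
    if agent.at_limit():
        state.senesce(agent)
        return CONVERTED_SENESCENT

    grid = state.grid
    radius = params.division_search_radius
    r0b, c0b, r1b, c1b = agent.footprint.bounding_box()
    epoch = grid.epoch_near(r0b - radius, c0b - radius, r1b + radius, c1b + radius)
    if agent.parked_epoch is not None and epoch <= agent.parked_epoch:
        return BLOCKED

    mother_pixels = agent.footprint.pixels
    if not _window_has_free(grid, agent, radius):
        if len(mother_pixels) < 2 * params.min_area:
            agent.parked_epoch = epoch
            return BLOCKED
        free_mask = None
        nfree = 0
        fr0 = fc0 = 0
    else:
        free_mask, fr0, fc0 = free_mask_near(grid, mother_pixels, radius)
        nfree = int(free_mask.sum())

    total = len(mother_pixels) + nfree
    if total < 2 * params.min_area:
        # Too little room to divide.  The cell still re-spreads into the
        # free pixels it can reach (up to its uncrowded size), so a
        # compressed rim cell creeps through narrow gaps between senescent
        # neighbours and keeps consuming the available area.
        gained = 0
        if nfree and len(mother_pixels) < params.max_area:
            free = _mask_to_set(free_mask, fr0, fc0)
            gained = _respread(grid, agent, free, params.max_area)
        if gained == 0:
            agent.parked_epoch = epoch
        return BLOCKED

    cy, cx = agent.footprint.centroid

    # rule 1: ample surrounding space -> daughter placed at full size,
    # mother footprint untouched
    if nfree >= params.max_area:
        rr, cc = np.nonzero(free_mask)
        d = (rr - (cy - fr0)) ** 2 + (cc - (cx - fc0)) ** 2
        order = np.lexsort((cc, rr, d))
        seed_local = (int(rr[order[0]]), int(cc[order[0]]))
        blob_local = accrete_in_mask(free_mask, seed_local, params.max_area)
        if len(blob_local) == params.max_area:
            blob = {(r + fr0, c + fc0) for r, c in blob_local}
            daughter = _spawn_daughter(state, agent, blob)
            agent.divisions_completed += 1
            agent.cycle_phase = 0.0
            agent.parked_epoch = None
            for cell in (daughter, agent):
                if cell.at_limit():  # rule 3
                    state.senesce(cell)
            return DIVIDED
        # surrounding space is fragmented; divide compressed instead

    # rule 2: compressed division over mother + nearby free pixels
    free = _mask_to_set(free_mask, fr0, fc0) if nfree else set()
    if len(free) > 2 * params.max_area:
        # cap the pool so the split stays local (nearest pixels first)
        free = set(sorted(
            free, key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2, p)
        )[:2 * params.max_area])
    pool = mother_pixels | free
    size = min(params.max_area, len(pool) // 2)

    seed_a = min(mother_pixels,
                 key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2, p))
    seed_b = max(pool,
                 key=lambda p: ((p[0] - seed_a[0]) ** 2 + (p[1] - seed_a[1]) ** 2, p))
    if seed_b == seed_a:
        agent.parked_epoch = epoch
        return BLOCKED
    split = partition_pool(pool, seed_a, seed_b, size, params.min_area)
    if split is None:
        agent.parked_epoch = epoch
        return BLOCKED
    blob_a, blob_b = split

    grid.erase(mother_pixels, agent.id)
    state.remove_agent(agent)
    # paint both daughters before any senescent conversion: conversion may
    # enlarge the footprint and must not eat the sibling's allotted pixels
    daughters = [_spawn_daughter(state, agent, blob)
                 for blob in (blob_a, blob_b)]
    for d in daughters:
        if d.at_limit():  # rule 3: conversion on reaching the limit
            state.senesce(d)
    return COMPRESSED_DIVIDED


def _mask_to_set(mask, r0: int, c0: int) -> set:
    rr, cc = np.nonzero(mask)
    return {(int(r) + r0, int(c) + c0) for r, c in zip(rr, cc)}


def _spawn_daughter(state: SimulationState, mother: Agent, blob: set) -> Agent:
    daughter = Agent(
        id=state.next_id,
        cell_class=mother.cell_class,
        state=PROLIFERATIVE,
        footprint=Footprint(blob),
        divisions_completed=mother.divisions_completed + 1,
        division_limit=mother.division_limit,
        cycle_phase=0.0,
    )
    state.next_id += 1
    state.grid.paint(blob, daughter.id)
    state.add_agent(daughter)
    return daughter


def step(state: SimulationState, params: DynamicsParams) -> SimulationState:
    """Advance the simulation clock by ``params.dt`` hours.

    Proliferative cells advance their cycle phase (capped at the cycle
    duration while blocked); cells with a completed cycle attempt division
    in an order reshuffled every step to avoid spatial bias.
    """
    state.clock += params.dt
    due = []
    for agent in state.agents.values():
        if agent.state != PROLIFERATIVE:
            continue
        agent.cycle_phase = min(agent.cycle_phase + params.dt, params.cycle_hours)
        if agent.cycle_phase >= params.cycle_hours:
            due.append(agent.id)
    if due:
        order = np.asarray(due, dtype=np.int64)
        state.rng.shuffle(order)
        for agent_id in order:
            agent = state.agents.get(int(agent_id))
            if agent is None or agent.state != PROLIFERATIVE:
                continue
            outcome = attempt_division(state, agent, params)
            if outcome == BLOCKED:
                agent.cycle_phase = params.cycle_hours  # hold, retry next step
    return state


def record_growth(state: SimulationState, replicate: int = 0) -> dict:
    """One growth-record row: clock, counts by class x state, confluence, PD."""
    c = state.counts
    return {
        "replicate": replicate,
        "passage": state.passage_index,
        "time_days": state.clock / 24.0,
        "n_normal_proliferative": c[(NORMAL, PROLIFERATIVE)],
        "n_normal_senescent": c[(NORMAL, SENESCENT)],
        "n_variant": c[(VARIANT, PROLIFERATIVE)] + c[(VARIANT, SENESCENT)],
        "n_variant_senescent": c[(VARIANT, SENESCENT)],
        "confluence": confluence(state.grid),
        "cumulative_pd": state.cumulative_pd(),
    }
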