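"""Spatial substrate for contact-inhibited epithelial growth.

The culture surface is a rectangular lattice of pixels with exclusive
occupancy: every pixel belongs to at most one cell.  A cell's *footprint*
is an 8-connected, quasi-circular set of pixels whose size varies between
a minimum (fully compressed) and a maximum (uncrowded) area.  At the
default calibration a 21-pixel footprint corresponds to 175 um^2 of
culture area, i.e. one pixel is 175/21 ~ 8.33 um^2, which makes the
6-pixel compressed footprint 50 um^2.

This module knows nothing about cell cycles or senescence; it provides
placement, free-space queries, footprint resizing and confluence
measurement for the dynamics engine built on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: um^2 per pixel at the default microscopy calibration (21 px = 175 um^2).
DEFAULT_PIXEL_AREA = 175.0 / 21.0

#: Default uncrowded / fully-compressed footprint sizes, in pixels.
DEFAULT_MAX_AREA = 21
DEFAULT_MIN_AREA = 6

_NEIGH8 = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


class ConfigurationError(ValueError):
    """A structurally invalid parameter (non-positive dimension, bad fraction...)."""


class SeedingError(RuntimeError):
    """Raised when the requested number of agents cannot be placed.

    ``achievable`` reports how many agents were placed before giving up.
    """

    def __init__(self, message: str, achievable: int = 0):
        super().__init__(message)
        self.achievable = achievable


@dataclass
class Footprint:
    """An 8-connected set of lattice pixels owned by one cell."""

    pixels: set

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        n = len(self.pixels)
        sr = sum(p[0] for p in self.pixels)
        sc = sum(p[1] for p in self.pixels)
        return (sr / n, sc / n)

    def bounding_box(self) -> tuple[int, int, int, int]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return (min(rows), min(cols), max(rows), max(cols))

    def is_connected(self) -> bool:
        return _is_connected(self.pixels)


def _is_connected(pixels: set) -> bool:
    if not pixels:
        return True
    seen = set()
    start = next(iter(pixels))
    stack = [start]
    seen.add(start)
    while stack:
        r, c = stack.pop()
        for dr, dc in _NEIGH8:
            q = (r + dr, c + dc)
            if q in pixels and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(pixels)


@dataclass
class SeedingSpec:
    """How to plate a population: count, variant fraction, reproducibility seed.

    ``exact_counts`` draws exactly ``round(n_agents * class_mix)`` variants at
    seeded-random positions (keeps rare-variant scenarios, e.g. 3 of 1,200 at
    0.25%, reproducible across replicates); set it to False for per-agent
    Bernoulli class assignment.
    """

    n_agents: int
    class_mix: float = 0.0
    seed: Optional[int] = None
    exact_counts: bool = True

    def __post_init__(self):
        if self.n_agents < 0:
            raise ConfigurationError("n_agents must be >= 0")
        if not 0.0 <= self.class_mix <= 1.0:
            raise ConfigurationError("class_mix must be in [0, 1]")


class Grid:
    """2D lattice with exclusive pixel occupancy.

    ``occupancy[r, c]`` holds the owning agent id (0 = free).  The occupied
    pixel count is maintained incrementally; :func:`confluence` is O(1).
    """

    TILE = 16  # tile size for the erase-epoch map (free-space change tracking)

    __slots__ = ("width", "height", "pixel_area", "occupancy", "_occupied",
                 "tile_epoch", "erase_epoch")

    def __init__(self, width: int, height: int, pixel_area: float = DEFAULT_PIXEL_AREA):
        if width <= 0 or height <= 0:
            raise ConfigurationError(
                f"grid dimensions must be positive, got {width} x {height}")
        if pixel_area <= 0:
            raise ConfigurationError(f"pixel_area must be positive, got {pixel_area}")
        self.width = int(width)
        self.height = int(height)
        self.pixel_area = float(pixel_area)
        self.occupancy = np.zeros((self.height, self.width), dtype=np.int32)
        self._occupied = 0
        # free pixels appear only through erase(); blocked cells can sleep
        # until the epoch of a nearby tile advances
        t = Grid.TILE
        self.tile_epoch = np.zeros(((self.height + t - 1) // t,
                                    (self.width + t - 1) // t), dtype=np.int64)
        self.erase_epoch = 0

    @property
    def total_pixels(self) -> int:
        return self.width * self.height

    @property
    def occupied_pixels(self) -> int:
        return self._occupied

    def area_um2(self, n_pixels: int) -> float:
        """Physical area of ``n_pixels`` at this grid's calibration."""
        return n_pixels * self.pixel_area

    def in_bounds(self, pixel: tuple[int, int]) -> bool:
        r, c = pixel
        return 0 <= r < self.height and 0 <= c < self.width

    def is_free(self, pixel: tuple[int, int]) -> bool:
        r, c = pixel
        return self.in_bounds(pixel) and self.occupancy[r, c] == 0

    def paint(self, pixels: Iterable[tuple[int, int]], agent_id: int) -> None:
        occ = self.occupancy
        n = 0
        for r, c in pixels:
            if occ[r, c] != 0:
                raise RuntimeError(
                    f"pixel ({r},{c}) already owned by agent {occ[r, c]}")
            occ[r, c] = agent_id
            n += 1
        self._occupied += n

    def erase(self, pixels: Iterable[tuple[int, int]], agent_id: int) -> None:
        occ = self.occupancy
        t = Grid.TILE
        self.erase_epoch += 1
        n = 0
        for r, c in pixels:
            if occ[r, c] != agent_id:
                raise RuntimeError(
                    f"pixel ({r},{c}) not owned by agent {agent_id}")
            occ[r, c] = 0
            self.tile_epoch[r // t, c // t] = self.erase_epoch
            n += 1
        self._occupied -= n

    def epoch_near(self, r0: int, c0: int, r1: int, c1: int) -> int:
        """Most recent erase epoch among tiles overlapping a pixel window."""
        t = Grid.TILE
        return int(self.tile_epoch[max(0, r0) // t:r1 // t + 1,
                                   max(0, c0) // t:c1 // t + 1].max())

    def brute_force_occupied(self) -> int:
        """Full-grid scan; the oracle the incremental counter is tested against."""
        return int(np.count_nonzero(self.occupancy))


def create_grid(width: int, height: int,
                pixel_area: float = DEFAULT_PIXEL_AREA) -> Grid:
    """Create an empty culture grid (default calibration 175/21 um^2 per pixel)."""
    return Grid(width, height, pixel_area)


def confluence(grid: Grid) -> float:
    """Fraction of the culture surface covered by cells, in [0, 1]."""
    return grid.occupied_pixels / grid.total_pixels


# ---------------------------------------------------------------------------
# blob geometry: quasi-circular accretion
# ---------------------------------------------------------------------------

def accrete_blob(grid: Grid, seed: tuple[int, int], target: int,
                 pool: Optional[set] = None) -> set:
    """Grow an 8-connected quasi-circular blob of eligible pixels from ``seed``.

    Pixels are accreted one at a time, always the candidate nearest to the
    blob's running centroid (ties broken lexicographically, so the result is
    deterministic).  Eligible pixels are free pixels of the grid, or members
    of ``pool`` when given.  The grid is not modified.  The returned set may
    be smaller than ``target`` if growth stalls.
    """
    if pool is not None:
        if seed not in pool:
            return set()
    elif not grid.is_free(seed):
        return set()

    blob = {seed}
    sr, sc = seed
    sum_r, sum_c = float(sr), float(sc)
    candidates: set = set()

    def _eligible(p):
        if p in blob:
            return False
        if pool is not None:
            return p in pool
        return grid.is_free(p)

    for dr, dc in _NEIGH8:
        q = (sr + dr, sc + dc)
        if _eligible(q):
            candidates.add(q)

    while len(blob) < target and candidates:
        n = len(blob)
        cy, cx = sum_r / n, sum_c / n
        best = None
        bd = 0.0
        for q in candidates:
            d = (q[0] - cy) ** 2 + (q[1] - cx) ** 2
            if best is None or d < bd or (d == bd and q < best):
                best, bd = q, d
        candidates.discard(best)
        blob.add(best)
        sum_r += best[0]
        sum_c += best[1]
        for dr, dc in _NEIGH8:
            q = (best[0] + dr, best[1] + dc)
            if q not in candidates and _eligible(q):
                candidates.add(q)
    return blob


def split_pool(pool: set, seed_a: tuple[int, int], seed_b: tuple[int, int],
               target: int) -> tuple[set, set]:
    """Partition ``pool`` into two connected blobs grown competitively.

    Each blob accretes, in alternation, the unassigned pool pixel adjacent to
    it that lies nearest its own seed.  Growth of a blob stops at ``target``
    pixels or when it has no adjacent unassigned pixel left.  Determinism:
    ties break lexicographically.
    """
    assert seed_a in pool and seed_b in pool and seed_a != seed_b
    blobs = ({seed_a}, {seed_b})
    seeds = (seed_a, seed_b)
    taken = {seed_a, seed_b}
    cands: list[set] = [set(), set()]
    for i in (0, 1):
        r, c = seeds[i]
        for dr, dc in _NEIGH8:
            q = (r + dr, c + dc)
            if q in pool and q not in taken:
                cands[i].add(q)
    stalled = [False, False]
    while not all(stalled):
        for i in (0, 1):
            if len(blobs[i]) >= target:
                stalled[i] = True
                continue
            cands[i] -= taken
            if not cands[i]:
                stalled[i] = True
                continue
            sy, sx = seeds[i]
            best = None
            bd = 0.0
            for q in cands[i]:
                d = (q[0] - sy) ** 2 + (q[1] - sx) ** 2
                if best is None or d < bd or (d == bd and q < best):
                    best, bd = q, d
            cands[i].discard(best)
            blobs[i].add(best)
            taken.add(best)
            stalled[i] = False
            for dr, dc in _NEIGH8:
                q = (best[0] + dr, best[1] + dc)
                if q in pool and q not in taken:
                    cands[i].add(q)
        if all(len(b) >= target for b in blobs):
            break
    return blobs


def partition_pool(pool: set, seed_a: tuple[int, int], seed_b: tuple[int, int],
                   target: int, min_size: int) -> Optional[tuple[set, set]]:
    """Split ``pool`` into two connected blobs of ``min_size``..``target`` px.

    Tries competitive growth first; when that strands one side below
    ``min_size`` (possible in tightly enclosed pools), falls back to growing
    one quasi-circular blob and taking the connected remainder, from either
    seed.  Returns None when no admissible split is found.
    """
    blob_a, blob_b = split_pool(pool, seed_a, seed_b, target)
    if len(blob_a) >= min_size and len(blob_b) >= min_size:
        return blob_a, blob_b
    if len(pool) <= 2 * target + 1:
        for s1, s2 in ((seed_a, seed_b), (seed_b, seed_a)):
            one = accrete_blob(None, s1, len(pool) // 2, pool=pool)  # type: ignore[arg-type]
            rest = pool - one
            if (len(one) >= min_size and len(rest) >= min_size
                    and len(rest) <= target + 1 and _is_connected(rest)):
                return one, rest
    return None


def free_reachable(grid: Grid, pixels: set, search_radius: int) -> set:
    """Free pixels reachable within ``search_radius`` BFS layers of a footprint.

    Layered breadth-first search over *free* pixels starting from the free
    8-neighbours of the footprint boundary: a free pixel counts if it can be
    reached from the footprint through free pixels in at most
    ``search_radius`` steps.
    """
    frontier = set()
    for r, c in pixels:
        for dr, dc in _NEIGH8:
            q = (r + dr, c + dc)
            if q not in pixels and grid.is_free(q):
                frontier.add(q)
    reached = set(frontier)
    for _ in range(search_radius - 1):
        if not frontier:
            break
        nxt = set()
        for r, c in frontier:
            for dr, dc in _NEIGH8:
                q = (r + dr, c + dc)
                if q not in reached and q not in pixels and grid.is_free(q):
                    nxt.add(q)
        reached |= nxt
        frontier = nxt
    return reached


_DILATE_STRUCT = np.ones((3, 3), dtype=bool)


def free_mask_near(grid: Grid, pixels: set, radius: int
                   ) -> tuple[np.ndarray, int, int]:
    """Boolean window of free pixels within Chebyshev ``radius`` of a footprint.

    Unlike :func:`free_reachable` this is a plain neighbourhood query: a free
    pocket on the far side of a thin occupied wall still counts (a dividing
    cell may place a daughter past a flat senescent neighbour).  Returns the
    mask plus its (row, col) offset into the grid.
    """
    from scipy.ndimage import binary_dilation

    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    r0 = max(0, min(rows) - radius)
    c0 = max(0, min(cols) - radius)
    r1 = min(grid.height, max(rows) + radius + 1)
    c1 = min(grid.width, max(cols) + radius + 1)
    win = grid.occupancy[r0:r1, c0:c1]
    fp = np.zeros(win.shape, dtype=bool)
    for r, c in pixels:
        fp[r - r0, c - c0] = True
    near = binary_dilation(fp, structure=_DILATE_STRUCT, iterations=radius)
    return near & (win == 0), r0, c0


def free_pixels_near(grid: Grid, pixels: set, radius: int) -> set:
    """Set view of :func:`free_mask_near` (small pools, compressed division)."""
    mask, r0, c0 = free_mask_near(grid, pixels, radius)
    rr, cc = np.nonzero(mask)
    return {(int(r) + r0, int(c) + c0) for r, c in zip(rr, cc)}


def accrete_in_mask(mask: np.ndarray, seed: tuple[int, int], target: int) -> set:
    """Quasi-circular accretion restricted to True cells of a boolean window.

    Same geometry as :func:`accrete_blob` but with O(1) array eligibility
    tests; ``seed`` and the returned pixels are in window coordinates.
    The seed cell need not be True-masked (a daughter may start adjacent to
    the mother's boundary); all other pixels must be.
    """
    h, w = mask.shape
    blob = {seed}
    sum_r, sum_c = float(seed[0]), float(seed[1])
    candidates: set = set()

    def _push(p):
        r, c = p
        for dr, dc in _NEIGH8:
            q = (r + dr, c + dc)
            if (0 <= q[0] < h and 0 <= q[1] < w and q not in blob
                    and mask[q[0], q[1]]):
                candidates.add(q)

    _push(seed)
    while len(blob) < target and candidates:
        n = len(blob)
        cy, cx = sum_r / n, sum_c / n
        best = None
        bd = 0.0
        for q in candidates:
            d = (q[0] - cy) ** 2 + (q[1] - cx) ** 2
            if best is None or d < bd or (d == bd and q < best):
                best, bd = q, d
        candidates.discard(best)
        blob.add(best)
        sum_r += best[0]
        sum_c += best[1]
        _push(best)
    return blob


def free_adjacent_area(grid: Grid, agent, search_radius: int) -> int:
    """Count of free pixels reachable within ``search_radius`` of an agent."""
    return len(free_reachable(grid, agent.footprint.pixels, search_radius))


def resize_footprint(grid: Grid, agent, target_area: int) -> int:
    """Grow or shrink an agent's footprint toward ``target_area`` pixels.

    Growth accretes the nearest free pixel to the footprint centroid;
    shrinking releases the farthest pixels while preserving 8-connectivity.
    Returns the achieved area (may fall short of ``target_area`` when growth
    runs out of adjacent free space).  No other agent is touched.
    """
    if target_area <= 0:
        raise ConfigurationError("target_area must be positive")
    pixels = agent.footprint.pixels
    current = len(pixels)
    if target_area == current:
        return current

    if target_area > current:
        while len(pixels) < target_area:
            n = len(pixels)
            cy = sum(p[0] for p in pixels) / n
            cx = sum(p[1] for p in pixels) / n
            candidates = set()
            for r, c in pixels:
                for dr, dc in _NEIGH8:
                    q = (r + dr, c + dc)
                    if q not in pixels and grid.is_free(q):
                        candidates.add(q)
            if not candidates:
                break
            best = min(candidates,
                       key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2, p))
            grid.paint([best], agent.id)
            pixels.add(best)
        return len(pixels)

    # shrink: drop farthest-from-centroid pixels, connectivity preserved
    cy = sum(p[0] for p in pixels) / current
    cx = sum(p[1] for p in pixels) / current
    while len(pixels) > target_area:
        order = sorted(pixels,
                       key=lambda p: (-((p[0] - cy) ** 2 + (p[1] - cx) ** 2), p))
        removed = False
        for cand in order:
            rest = pixels - {cand}
            if _is_connected(rest):
                grid.erase([cand], agent.id)
                pixels.discard(cand)
                removed = True
                break
        if not removed:  # pragma: no cover - cannot happen for connected sets
            break
    return len(pixels)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def place_blob(grid: Grid, agent_id: int, area: int, rng: np.random.Generator,
               max_tries: int = 2000) -> Optional[set]:
    """Place one quasi-circular blob of ``area`` free pixels at a random spot.

    Centroid positions are rejection-sampled; returns the painted pixel set,
    or None if no position admitted a full-size blob within ``max_tries``.
    """
    h, w = grid.height, grid.width
    for _ in range(max_tries):
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        if grid.occupancy[r, c] != 0:
            continue
        blob = accrete_blob(grid, (r, c), area)
        if len(blob) == area:
            grid.paint(blob, agent_id)
            return blob
    return None


def seed_agents(grid: Grid, spec: SeedingSpec, max_area: int = DEFAULT_MAX_AREA,
                cycle_hours: float = 26.0,
                rng: Optional[np.random.Generator] = None,
                id_start: int = 1) -> list:
    """Disperse ``spec.n_agents`` cells at random non-overlapping positions.

    Every cell is placed at ``max_area`` pixels (uncrowded plating), assigned
    a class per ``spec`` and an initial cycle phase uniform in
    ``[0, cycle_hours)`` so the population divides asynchronously.

    Raises :class:`SeedingError` (with the achievable count) if the grid
    cannot accommodate the request.
    """
    from .dynamics import Agent, NORMAL, VARIANT, PROLIFERATIVE  # deferred: avoids cycle

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_agents
    if n * max_area > grid.total_pixels - grid.occupied_pixels:
        raise SeedingError(
            f"cannot place {n} agents of {max_area} px on a grid with "
            f"{grid.total_pixels - grid.occupied_pixels} free pixels",
            achievable=(grid.total_pixels - grid.occupied_pixels) // max_area)

    if spec.exact_counts:
        n_variant = int(round(n * spec.class_mix))
        variant_slots = set(rng.choice(n, size=n_variant, replace=False).tolist()) \
            if n_variant > 0 else set()
        classes = [VARIANT if i in variant_slots else NORMAL for i in range(n)]
    else:
        classes = [VARIANT if rng.random() < spec.class_mix else NORMAL
                   for _ in range(n)]

    agents = []
    for i in range(n):
        agent_id = id_start + i
        blob = place_blob(grid, agent_id, max_area, rng)
        if blob is None:
            for a in agents:  # roll back so the grid is left consistent
                grid.erase(a.footprint.pixels, a.id)
            raise SeedingError(
                f"could only place {i} of {n} agents without overlap",
                achievable=i)
        agents.append(Agent(
            id=agent_id,
            cell_class=classes[i],
            state=PROLIFERATIVE,
            footprint=Footprint(blob),
            divisions_completed=0,
            division_limit=None,
            cycle_phase=float(rng.uniform(0.0, cycle_hours)),
        ))
    return agents
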