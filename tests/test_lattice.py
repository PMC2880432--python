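"""Lattice substrate: occupancy exclusivity, confluence, seeding, footprints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from outgrowth import (
    ConfigurationError,
    DEFAULT_PIXEL_AREA,
    Footprint,
    SeedingError,
    SeedingSpec,
    confluence,
    create_grid,
    free_adjacent_area,
    resize_footprint,
    seed_agents,
)
from outgrowth.lattice import accrete_blob, free_reachable


class TestCreateGrid:
    def test_standard_grid(self):
        grid = create_grid(400, 400, 175.0 / 21.0)
        assert grid.total_pixels == 160_000
        assert confluence(grid) == 0.0
        # a 21-px cell is 175 um^2, a 6-px compressed cell is 50 um^2
        assert grid.area_um2(21) == pytest.approx(175.0)
        assert grid.area_um2(6) == pytest.approx(50.0)

    def test_minimal_grid(self):
        grid = create_grid(1, 1, 1.0)
        assert grid.total_pixels == 1

    def test_full_tiling_reaches_confluence_one(self):
        grid = create_grid(20, 20)
        grid.paint([(r, c) for r in range(20) for c in range(20)], 1)
        assert confluence(grid) == 1.0

    @pytest.mark.parametrize("w,h,area", [(0, 10, 1.0), (10, -1, 1.0), (10, 10, 0.0)])
    def test_invalid_dimensions_rejected(self, w, h, area):
        with pytest.raises(ConfigurationError):
            create_grid(w, h, area)


class TestSeeding:
    def test_standard_plating_counts_and_area(self):
        grid = create_grid(400, 400)
        agents = seed_agents(grid, SeedingSpec(n_agents=1200, class_mix=0.0025,
                                               seed=0), max_area=21)
        assert len(agents) == 1200
        # exact-count assignment: 0.25% of 1,200 = 3 variants
        assert sum(a.cell_class == "variant" for a in agents) == 3
        assert grid.occupied_pixels == 1200 * 21
        assert grid.brute_force_occupied() == 25_200
        assert all(a.footprint.area == 21 for a in agents)
        assert all(a.footprint.is_connected() for a in agents)

    def test_empty_seeding(self, small_grid):
        assert seed_agents(small_grid, SeedingSpec(n_agents=0, seed=1)) == []

    def test_seeding_is_reproducible(self):
        def placements(seed):
            grid = create_grid(80, 80)
            agents = seed_agents(grid, SeedingSpec(n_agents=50, class_mix=0.3,
                                                   seed=seed))
            return [(sorted(a.footprint.pixels), a.cell_class) for a in agents]

        assert placements(7) == placements(7)
        assert placements(7) != placements(8)

    def test_insufficient_space_reports_achievable(self):
        grid = create_grid(10, 10)
        with pytest.raises(SeedingError) as exc:
            seed_agents(grid, SeedingSpec(n_agents=10, seed=0), max_area=21)
        assert exc.value.achievable < 10

    def test_occupancy_exclusive_after_seeding(self):
        grid = create_grid(100, 100)
        agents = seed_agents(grid, SeedingSpec(n_agents=150, seed=3))
        owned = [p for a in agents for p in a.footprint.pixels]
        assert len(owned) == len(set(owned))
        for a in agents:
            for r, c in a.footprint.pixels:
                assert grid.occupancy[r, c] == a.id


class TestConfluence:
    def test_saturation_count_matches_confluence(self):
        """~6,000 full-size cells cover ~80% of the standard grid."""
        grid = create_grid(400, 400)
        agents = seed_agents(grid, SeedingSpec(n_agents=6000, seed=0),
                             max_area=21)
        assert confluence(grid) == pytest.approx(6000 * 21 / 160_000)
        assert confluence(grid) == pytest.approx(0.7875)

    @given(n=st.integers(0, 60), seed=st.integers(0, 10))
    @settings(max_examples=15, deadline=None)
    def test_confluence_matches_brute_force(self, n, seed):
        grid = create_grid(60, 60)
        seed_agents(grid, SeedingSpec(n_agents=n, seed=seed), max_area=9)
        assert grid.occupied_pixels == grid.brute_force_occupied()
        assert confluence(grid) == grid.brute_force_occupied() / 3600


class TestFreeSpace:
    def test_lone_agent_has_ample_free_area(self):
        grid = create_grid(60, 60)
        (agent,) = seed_agents(grid, SeedingSpec(n_agents=1, seed=0))
        assert free_adjacent_area(grid, agent, search_radius=5) >= 21

    def test_enclosed_agent_has_none(self):
        grid = create_grid(10, 10)
        blob = accrete_blob(grid, (5, 5), 6)
        grid.paint(blob, 1)
        ring = free_reachable(grid, blob, 2)
        grid.paint(ring, 2)
        ring2 = free_reachable(grid, blob | ring, 3)
        grid.paint(ring2, 3)

        class _A:
            id = 1
            footprint = Footprint(blob)

        assert free_adjacent_area(grid, _A(), search_radius=2) == 0

    def test_radius_one_counts_boundary_neighbours_exactly(self):
        grid = create_grid(20, 20)
        blob = {(5, 5), (5, 6), (6, 5), (6, 6)}
        grid.paint(blob, 1)
        # wall off all but k free boundary pixels
        boundary = free_reachable(grid, blob, 1)
        keep = sorted(boundary)[:3]
        grid.paint([p for p in boundary if p not in keep], 99)

        class _A:
            id = 1
            footprint = Footprint(blob)

        assert free_adjacent_area(grid, _A(), search_radius=1) == 3


class TestResizeFootprint:
    def _agent_on(self, grid, area, seed_px=(20, 20)):
        blob = accrete_blob(grid, seed_px, area)
        grid.paint(blob, 1)

        class _A:
            id = 1
            footprint = Footprint(blob)

        return _A()

    def test_shrink_to_minimum_frees_pixels(self):
        grid = create_grid(40, 40)
        agent = self._agent_on(grid, 21)
        achieved = resize_footprint(grid, agent, 6)
        assert achieved == 6
        assert agent.footprint.area == 6
        assert agent.footprint.is_connected()
        assert grid.occupied_pixels == 6  # 15 pixels freed

    def test_resize_to_current_is_noop(self):
        grid = create_grid(40, 40)
        agent = self._agent_on(grid, 12)
        before = set(agent.footprint.pixels)
        assert resize_footprint(grid, agent, 12) == 12
        assert agent.footprint.pixels == before

    def test_growth_limited_by_free_space(self):
        grid = create_grid(40, 40)
        agent = self._agent_on(grid, 6)
        boundary = free_reachable(grid, agent.footprint.pixels, 1)
        keep = set(sorted(boundary)[:10])
        far = free_reachable(grid, agent.footprint.pixels, 8)
        grid.paint([p for p in far if p not in keep], 99)
        achieved = resize_footprint(grid, agent, 21)
        assert achieved == 16  # 6 original + the 10 available neighbours
        assert agent.footprint.is_connected()

    def test_resize_leaves_other_agents_untouched(self):
        grid = create_grid(60, 60)
        agents = seed_agents(grid, SeedingSpec(n_agents=12, seed=5), max_area=21)
        others = {a.id: set(a.footprint.pixels) for a in agents[1:]}
        resize_footprint(grid, agents[0], 6)
        resize_footprint(grid, agents[0], 21)
        for a in agents[1:]:
            assert set(a.footprint.pixels) == others[a.id]
            for r, c in a.footprint.pixels:
                assert grid.occupancy[r, c] == a.id


class TestAccretion:
    @given(target=st.integers(1, 25))
    @settings(max_examples=20, deadline=None)
    def test_blob_connected_and_quasi_circular(self, target):
        grid = create_grid(30, 30)
        blob = accrete_blob(grid, (15, 15), target)
        assert len(blob) == target
        assert Footprint(blob).is_connected()
        # compact: bounding box no larger than ~2x the disk diameter
        rows = [p[0] for p in blob]
        span = max(rows) - min(rows) + 1
        assert span <= 2 * int(np.ceil(2 * np.sqrt(target / np.pi))) + 1
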