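"""Division rules: space gating, compression, senescent conversion."""

import numpy as np
import pytest

from outgrowth import (
    Agent,
    BLOCKED,
    CONVERTED_SENESCENT,
    DynamicsParams,
    Footprint,
    SeedingSpec,
    attempt_division,
    new_simulation,
    record_growth,
    step,
)
from outgrowth.lattice import accrete_blob, free_reachable

from conftest import make_sim, run_hours


class TestBasicDivision:
    def test_one_cycle_one_division(self):
        state, params = make_sim(n_agents=1, grid=60)
        run_hours(state, params, 27)
        assert state.n_agents == 2
        assert all(a.divisions_completed == 1 for a in state.agents.values())

    def test_uncrowded_daughters_at_full_size(self):
        state, params = make_sim(n_agents=1, grid=60)
        run_hours(state, params, 27)
        assert all(a.footprint.area == params.max_area
                   for a in state.agents.values())

    @pytest.mark.parametrize("limit", [1, 2, 3])
    def test_limit_saturation_closed_form(self, limit):
        """A lineage with limit L yields exactly 2^L cells, all senescent."""
        state, params = make_sim(n_agents=1, grid=120, limit_normal=limit)
        run_hours(state, params, 26 * limit + 2)
        assert state.n_agents == 2 ** limit
        assert all(a.state == "senescent" for a in state.agents.values())
        assert all(a.divisions_completed == limit
                   for a in state.agents.values())

    def test_limit_saturation_bounded_at_higher_limit(self):
        """At L = 4 a colony grown from one cell may strand an interior cell
        below the divisible size, so 2^L is an upper bound; the population
        is static afterwards and nobody exceeds the limit."""
        state, params = make_sim(n_agents=1, grid=120, limit_normal=4)
        run_hours(state, params, 26 * 4 + 2)
        assert 2 ** 3 < state.n_agents <= 2 ** 4
        assert all(a.divisions_completed <= 4 for a in state.agents.values())
        n = state.n_agents
        run_hours(state, params, 52)
        assert state.n_agents == n

    def test_senescent_population_is_static(self):
        state, params = make_sim(n_agents=5, grid=60, limit_normal=0)
        run_hours(state, params, 60)
        assert state.n_agents == 5
        assert all(a.state == "senescent" for a in state.agents.values())
        before = {a.id: set(a.footprint.pixels) for a in state.agents.values()}
        run_hours(state, params, 50)
        assert {a.id: set(a.footprint.pixels)
                for a in state.agents.values()} == before


class TestAttemptDivision:
    def _enclosed_agent(self, state, area):
        """Plant one agent of ``area`` px with zero reachable free space."""
        grid = state.grid
        blob = accrete_blob(grid, (20, 20), area)
        agent = Agent(id=500, cell_class="normal", state="proliferative",
                      footprint=Footprint(blob), division_limit=None,
                      cycle_phase=26.0)
        grid.paint(blob, agent.id)
        state.add_agent(agent)
        wall = free_reachable(grid, blob, 8)
        grid.paint(wall, 999)
        return agent

    def test_at_limit_converts_permanently(self):
        state, params = make_sim(n_agents=0, grid=40)
        grid = state.grid
        blob = accrete_blob(grid, (20, 20), 21)
        agent = Agent(id=1, cell_class="normal", state="proliferative",
                      footprint=Footprint(blob), divisions_completed=3,
                      division_limit=3, cycle_phase=26.0)
        grid.paint(blob, agent.id)
        state.add_agent(agent)
        assert attempt_division(state, agent, params) == CONVERTED_SENESCENT
        assert agent.state == "senescent"
        run_hours(state, params, 60)
        assert agent.state == "senescent" and state.n_agents == 1

    def test_fully_compressed_division_within_mother(self):
        """A 12-px cell with no free space splits into two 6-px daughters."""
        state, params = make_sim(n_agents=0, grid=50)
        agent = self._enclosed_agent(state, 12)
        mother_pixels = set(agent.footprint.pixels)
        outcome = attempt_division(state, agent, params)
        assert outcome == "compressed_divided"
        daughters = [a for a in state.agents.values() if a.id not in (500, 999)]
        assert len(daughters) == 2
        assert all(d.footprint.area == 6 for d in daughters)
        assert (daughters[0].footprint.pixels
                | daughters[1].footprint.pixels) == mother_pixels

    def test_too_small_to_divide_is_blocked(self):
        state, params = make_sim(n_agents=0, grid=50)
        agent = self._enclosed_agent(state, 11)
        assert attempt_division(state, agent, params) == BLOCKED
        assert agent.state == "proliferative"
        assert agent.footprint.area == 11

    def test_daughters_increment_division_count(self):
        state, params = make_sim(n_agents=1, grid=60)
        run_hours(state, params, 27 + 26)
        assert state.n_agents == 4
        assert all(a.divisions_completed == 2 for a in state.agents.values())


class TestInvariants:
    def _random_run(self, seed, hours=80):
        state, params = make_sim(n_agents=25, class_mix=0.3, seed=seed,
                                 grid=60, limit_normal=2, limit_variant=None)
        history = []
        for _ in range(hours):
            step(state, params)
            history.append({
                "n": state.n_agents,
                "senescent": {a.id for a in state.agents.values()
                              if a.state == "senescent"},
                "areas": [(a.state, a.footprint.area)
                          for a in state.agents.values()],
                "occupied": state.grid.occupied_pixels,
                "brute": state.grid.brute_force_occupied(),
                "footprint_sum": sum(a.footprint.area
                                     for a in state.agents.values()),
                "areas_flat": [a.footprint.area
                               for a in state.agents.values()],
            })
        return state, history

    @pytest.mark.parametrize("seed", [0, 1])
    def test_occupancy_exclusivity_and_area_bounds_every_step(self, seed):
        state, history = self._random_run(seed)
        for snap in history:
            assert snap["occupied"] == snap["brute"]
            assert snap["footprint_sum"] == snap["occupied"]
            for st_, area in snap["areas"]:
                if st_ == "proliferative":
                    assert 6 <= area <= 21
                else:  # senescent cells enlarge, up to senescent_area
                    assert 6 <= area <= 42

    def test_senescent_set_grows_monotonically(self):
        _, history = self._random_run(seed=2)
        for prev, cur in zip(history, history[1:]):
            assert prev["senescent"] <= cur["senescent"]

    def test_agent_count_never_decreases_within_passage(self):
        _, history = self._random_run(seed=3)
        for prev, cur in zip(history, history[1:]):
            assert cur["n"] >= prev["n"]

    def test_identical_seeds_identical_trajectories(self):
        _, h1 = self._random_run(seed=4)
        _, h2 = self._random_run(seed=4)
        assert [s["n"] for s in h1] == [s["n"] for s in h2]
        assert ([sorted(s["areas_flat"]) for s in h1]
                == [sorted(s["areas_flat"]) for s in h2])


class TestGrowthRecord:
    def test_fresh_seeding_has_zero_pd(self):
        state, params = make_sim(n_agents=10, grid=60, seed=1)
        row = record_growth(state)
        assert row["cumulative_pd"] == 0.0
        assert row["n_normal_proliferative"] == 10

    def test_one_doubling_is_one_pd(self):
        state, params = make_sim(n_agents=6, grid=80, seed=1)
        run_hours(state, params, 26)
        row = record_growth(state)
        assert state.n_agents == 12
        assert row["cumulative_pd"] == pytest.approx(1.0)

    def test_pd_matches_log_ratio_oracle(self):
        state, params = make_sim(n_agents=7, grid=80, seed=2)
        run_hours(state, params, 40)
        row = record_growth(state)
        assert row["cumulative_pd"] == pytest.approx(
            np.log(state.n_agents / 7) / np.log(2))
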