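"""Learning dynamics: candidate rules, synchronous step, absorption, runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divlearn import dynamics as dyn
from divlearn import networks as net
from divlearn.population import build_population, initialize_solutions
from conftest import random_micro_population, reference_step


def _pop(n_agents, n_classes, n_bits, k, mean_deg, seed, graph=None):
    g = graph or net.random_graph(n_agents, mean_deg, seed=seed)
    pop = build_population(n_agents, n_classes, (n_bits, k, 8.0), g, seed=seed + 1)
    return initialize_solutions(pop, seed=seed + 2)


class TestExplorationCandidate:
    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**10 - 1), st.integers(0, 100))
    def test_flips_exactly_one_element(self, code, seed):
        out = dyn.exploration_candidate(code, 10, np.random.default_rng(seed))
        assert bin(code ^ out).count("1") == 1

    def test_single_element_always_flips_to_opposite(self):
        rng = np.random.default_rng(0)
        assert dyn.exploration_candidate(0, 1, rng) == 1
        assert dyn.exploration_candidate(1, 1, rng) == 0

    def test_flip_positions_uniform(self):
        rng = np.random.default_rng(1)
        n_draws, bits = 15_000, 5
        flips = np.array(
            [dyn.exploration_candidate(0, bits, rng).bit_length() - 1
             for _ in range(n_draws)]
        )
        freq = np.bincount(flips, minlength=bits) / n_draws
        assert np.abs(freq - 1 / bits).max() < 4 * np.sqrt((1 / bits) * (1 - 1 / bits) / n_draws)


class TestExploitationCandidate:
    def test_best_improving_neighbour_is_chosen(self):
        pop = _pop(5, 1, 4, 0, 4, seed=10, graph=net.complete_graph(5))
        state = dyn.make_state(pop)
        for agent in range(5):
            cand = dyn.exploitation_candidate(state, agent)
            own = pop.landscapes[0]
            others = np.delete(np.arange(5), agent)
            best_val = max(own.payoff(int(pop.solutions[j])) for j in others)
            if best_val > state.payoffs[agent]:
                assert cand is not None and own.payoff(cand) == best_val
            else:
                assert cand is None

    def test_isolated_agent_has_no_candidate(self):
        pop = _pop(4, 1, 3, 0, 0, seed=3)  # edgeless graph
        state = dyn.make_state(pop)
        assert all(dyn.exploitation_candidate(state, a) is None for a in range(4))


class TestStep:
    def test_matches_naive_reference_on_micro_instances(self):
        """Vectorized synchronous step == per-agent reference, 30 instances."""
        for seed in range(30):
            pop, dyn_seed = random_micro_population(seed)
            sols = pop.solutions.copy()
            state = dyn.make_state(pop)
            rng_a = np.random.default_rng(dyn_seed)
            rng_b = np.random.default_rng(dyn_seed)
            for _ in range(8):
                state = dyn.step(state, rng_a)
                sols = reference_step(pop, sols, rng_b)
                assert np.array_equal(state.population.solutions, sols), seed

    def test_complete_graph_spreads_best_solution_in_one_step(self):
        pop = _pop(20, 1, 6, 2, 0, seed=5, graph=net.complete_graph(20))
        state = dyn.make_state(pop)
        best0 = state.payoffs.max()
        state = dyn.step(state, np.random.default_rng(0))
        assert state.payoffs.min() >= best0

    def test_all_at_optimum_is_fixed_point(self):
        pop = _pop(6, 1, 4, 1, 3, seed=8)
        pop.solutions[:] = pop.landscapes[0].global_optimum()
        state = dyn.make_state(pop)
        nxt = dyn.step(state, np.random.default_rng(2))
        assert np.array_equal(nxt.population.solutions, state.population.solutions)
        assert dyn.is_absorbed(state)

    def test_improving_neighbour_prevents_absorption(self):
        pop = _pop(2, 1, 4, 0, 1, seed=12, graph=net.complete_graph(2))
        land = pop.landscapes[0]
        opt = land.global_optimum()
        worst = int(np.argmin(land.raw_table))
        pop.solutions = np.array([opt, worst])
        assert not dyn.is_absorbed(dyn.make_state(pop))


class TestRun:
    def test_per_agent_payoffs_monotone(self):
        pop = _pop(50, 5, 10, 4, 4, seed=21)
        state = dyn.make_state(pop)
        rng = np.random.default_rng(3)
        prev = state.payoffs.copy()
        for _ in range(60):
            state = dyn.step(state, rng)
            assert (state.payoffs >= prev - 1e-15).all()
            prev = state.payoffs.copy()

    def test_absorption_is_permanent(self):
        pop = _pop(12, 2, 6, 2, 3, seed=31)
        traj = dyn.run(pop, max_steps=500, seed=32)
        assert traj.absorbed
        state = dyn.make_state(pop)  # final solutions exposed on pop
        rng = np.random.default_rng(33)
        frozen = state.population.solutions.copy()
        for _ in range(50):
            state = dyn.step(state, rng)
            assert np.array_equal(state.population.solutions, frozen)

    def test_single_agent_hill_climb_accepts_at_most_n_bits_flips(self):
        pop = _pop(1, 1, 8, 0, 0, seed=41)
        traj = dyn.run(pop, max_steps=2000, seed=42)
        assert traj.absorbed
        assert traj.final_payoffs[0] == 1.0
        assert traj.n_changed_series.sum() <= 8

    def test_smooth_task_reaches_full_performance(self):
        pop = _pop(50, 5, 10, 0, 4, seed=51)
        traj = dyn.run(pop, max_steps=50 * 10, seed=52)
        assert traj.absorbed
        assert np.allclose(traj.final_payoffs, 1.0)
        assert (traj.t_optimum >= 0).all()

    def test_deterministic_in_seed(self):
        t1 = dyn.run(_pop(30, 3, 8, 3, 4, seed=61), max_steps=200, seed=62)
        t2 = dyn.run(_pop(30, 3, 8, 3, 4, seed=61), max_steps=200, seed=62)
        assert np.array_equal(t1.mean_payoff_series, t2.mean_payoff_series)
        assert np.array_equal(t1.t_optimum, t2.t_optimum)
        assert t1.absorbed_step == t2.absorbed_step

    def test_mean_payoff_series_monotone_and_bounded(self):
        traj = dyn.run(_pop(40, 4, 8, 3, 4, seed=71), max_steps=300, seed=72)
        assert (np.diff(traj.mean_payoff_series) >= -1e-15).all()
        assert traj.mean_payoff_series.min() >= 0
        assert traj.mean_payoff_series.max() <= 1

    def test_advertised_evaluation_runs_and_stays_monotone(self):
        pop = _pop(30, 3, 8, 3, 4, seed=81)
        traj = dyn.run(pop, max_steps=200, seed=82, evaluation="advertised")
        assert (np.diff(traj.mean_payoff_series) >= -1e-15).all()

    def test_unknown_evaluation_rule_rejected(self):
        pop = _pop(4, 1, 3, 0, 2, seed=91)
        with pytest.raises(ValueError):
            dyn.step(dyn.make_state(pop), np.random.default_rng(0), evaluation="bogus")
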