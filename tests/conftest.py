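"""Shared fixtures and independent reference implementations.

``brute_raw_payoff`` evaluates an NK landscape with scalar Python
arithmetic and no lookup-table machinery; ``reference_step`` advances the
learning dynamics with a per-agent Python loop.  Both exist solely as
oracles for the vectorized implementations and must stay naive.
"""

from __future__ import annotations

import numpy as np
import pytest

from divlearn import landscapes as lsc
from divlearn.networks import Graph
from divlearn.population import Population


def brute_raw_payoff(landscape: lsc.NKLandscape, bits) -> float:
    """Raw payoff by direct per-element lookup on a bit vector."""
    bits = list(bits)
    total = 0.0
    for i in range(landscape.n_elements):
        key = bits[i]
        for j, p in enumerate(landscape.partners[i]):
            key += bits[int(p)] << (j + 1)
        total += float(landscape.contributions[i][key])
    return total / landscape.n_elements


def brute_all_raw(landscape: lsc.NKLandscape) -> np.ndarray:
    """Raw payoffs of every solution, via the brute-force evaluator."""
    n = landscape.n_elements
    return np.array(
        [
            brute_raw_payoff(landscape, [(c >> i) & 1 for i in range(n)])
            for c in range(1 << n)
        ]
    )


def reference_step(
    pop: Population, solutions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One synchronous update via a naive per-agent loop (own evaluation).

    Consumes randomness exactly per the documented contract: first
    ``rng.random(n)`` tie-break uniforms, then ``rng.integers(0, bits, n)``
    flip positions.
    """
    n = pop.n_agents
    tie_u = rng.random(n)
    flips = rng.integers(0, pop.n_elements, n)
    new = solutions.copy()
    for i in range(n):
        land = pop.landscape_of(i)
        cur = land.payoff(int(solutions[i]))
        candidate = None
        neigh = pop.graph.neighbors(i)
        if neigh.size:
            vals = [land.payoff(int(solutions[j])) for j in neigh]
            best = max(vals)
            if best > cur:
                tied = [j for j, v in zip(neigh, vals) if v == best]
                candidate = int(solutions[tied[int(tie_u[i] * len(tied))]])
        if candidate is not None:
            new[i] = candidate
        else:
            flipped = int(solutions[i]) ^ (1 << int(flips[i]))
            if land.payoff(flipped) > cur:
                new[i] = flipped
    return new


def make_toy_k0_landscape() -> lsc.NKLandscape:
    """Two-element smooth landscape: f_1 = {0:0.2, 1:0.8}, f_2 = {0:0.4, 1:0.6}."""
    return lsc.NKLandscape(
        n_elements=2,
        k_interactions=0,
        partners=np.empty((2, 0), dtype=np.int64),
        contributions=np.array([[0.2, 0.8], [0.4, 0.6]]),
    )


def random_micro_population(seed: int) -> tuple[Population, int]:
    """A tiny random population (N <= 6 agents, N_NK <= 4) for oracle tests."""
    from divlearn.population import build_population, initialize_solutions
    from divlearn.networks import random_graph

    rng = np.random.default_rng(seed)
    n_agents = int(rng.integers(1, 7))
    n_bits = int(rng.integers(1, 5))
    k = int(rng.integers(0, n_bits))
    divisors = [c for c in range(1, n_agents + 1) if n_agents % c == 0]
    n_classes = int(rng.choice(divisors))
    mean_deg = float(rng.uniform(0, n_agents - 1)) if n_agents > 1 else 0.0
    g = random_graph(n_agents, mean_deg, seed=int(rng.integers(2**31)))
    pop = build_population(
        n_agents, n_classes, (n_bits, k, 8.0), g, seed=int(rng.integers(2**31))
    )
    initialize_solutions(pop, seed=int(rng.integers(2**31)))
    return pop, int(rng.integers(2**31))


def assert_simple_undirected(graph: Graph) -> None:
    edges = graph.edges()
    assert (edges[:, 0] != edges[:, 1]).all(), "self-loop found"
    # symmetry: every (u, v) present in both adjacency lists
    for u, v in edges[: min(len(edges), 500)]:
        assert v in graph.neighbors(u) and u in graph.neighbors(v)
    # no multi-edges: neighbour lists strictly increasing
    for i in range(graph.n_nodes):
        nb = graph.neighbors(i)
        assert (np.diff(nb) > 0).all() if nb.size > 1 else True


@pytest.fixture
def toy_k0_landscape() -> lsc.NKLandscape:
    return make_toy_k0_landscape()
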