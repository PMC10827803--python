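"""Synchronous best-member learning dynamics with exploration fallback.

Each discrete step, every agent — reading only the time-t snapshot —

1. *exploits*: evaluates all neighbours' current solutions under its own
   payoff function and adopts the best one if it strictly improves on the
   agent's current payoff (ties among equally good neighbour solutions are
   broken uniformly at random);
2. otherwise *explores*: flips one uniformly chosen element of its own
   solution and keeps the result iff it strictly improves its own payoff.

All accepted changes are applied simultaneously.  Both moves require strict
improvement, so every agent's payoff is non-decreasing and the dynamics
reach an absorbing state in finite time.

RNG contract (the reproducibility and oracle-equivalence invariant): each
step consumes, from the dynamics stream, first ``rng.random(n_agents)``
(exploitation tie-break uniforms) and then ``rng.integers(0, n_elements,
n_agents)`` (exploration flip positions) — for every agent, used or not.

``evaluation="advertised"`` switches to the alternative rule in which the
agent picks the neighbour with the highest *self-reported* payoff (the
neighbour's own function) and adopts that solution only if it improves the
agent's own payoff, falling back to exploration otherwise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .metrics import CENSORED, Trajectory
from .population import Population

__all__ = [
    "SimulationState",
    "make_state",
    "exploitation_candidate",
    "exploration_candidate",
    "step",
    "is_absorbed",
    "run",
]

DEFAULT_MAX_STEPS = 1000


@dataclass
class SimulationState:
    t: int
    population: Population
    payoffs: np.ndarray  # per agent, own-landscape transformed payoff


def make_state(population: Population) -> SimulationState:
    if population.solutions is None:
        raise ValueError("population solutions not initialized")
    payoffs = population.payoff_tables[population.class_of, population.solutions]
    return SimulationState(t=0, population=population, payoffs=payoffs)


def exploitation_candidate(
    state: SimulationState, agent: int, tie_u: float = 0.0
) -> int | None:
    """Best neighbour solution under the agent's own function, if improving.

    ``tie_u`` in [0, 1) selects among equally best neighbour solutions (in
    neighbour-list order); the default picks the first maximizer.  Returns a
    solution code, or None when no neighbour strictly improves.
    """
    pop = state.population
    neigh = pop.graph.neighbors(agent)
    if neigh.size == 0:
        return None
    vals = pop.payoff_tables[pop.class_of[agent], pop.solutions[neigh]]
    best = vals.max()
    if best <= state.payoffs[agent]:
        return None
    maximizers = np.flatnonzero(vals == best)
    pick = maximizers[int(tie_u * maximizers.size)]
    return int(pop.solutions[neigh[pick]])


def exploration_candidate(
    solution: int, n_elements: int, rng: np.random.Generator
) -> int:
    """Copy of ``solution`` with one uniformly chosen element flipped."""
    flip = int(rng.integers(0, n_elements))
    return int(solution) ^ (1 << flip)


def _segment_reduce(values, starts, lengths, ufunc, fill):
    """Per-segment ufunc.reduceat that tolerates empty segments."""
    out = np.full(lengths.size, fill, dtype=values.dtype if values.size else float)
    nonempty = lengths > 0
    if nonempty.any():
        out[nonempty] = ufunc.reduceat(values, starts[nonempty])
    return out


def _propose(state: SimulationState, tie_u, flips, evaluation):
    """New solution codes for all agents, from the time-t snapshot."""
    pop = state.population
    g = pop.graph
    n = pop.n_agents
    sol = pop.solutions
    cur = state.payoffs

    deg = g.degrees
    starts = g.indptr[:-1]
    focal = np.repeat(np.arange(n), deg)
    neigh_sol = sol[g.indices]
    if evaluation == "own":
        edge_vals = pop.payoff_tables[pop.class_of[focal], neigh_sol]
    elif evaluation == "advertised":
        edge_vals = pop.payoff_tables[pop.class_of[g.indices], neigh_sol]
    else:
        raise ValueError(f"unknown evaluation rule: {evaluation!r}")

    segmax = _segment_reduce(edge_vals, starts, deg, np.maximum, -np.inf)
    is_best = edge_vals == segmax[focal]
    counts = _segment_reduce(is_best.astype(np.int64), starts, deg, np.add, 0)
    # within-segment rank of the tied-best edges
    csum = np.cumsum(is_best)
    before = np.concatenate([[0], csum])[starts]
    rank = csum - 1 - before[focal]
    choice = np.minimum((tie_u * counts).astype(np.int64), np.maximum(counts - 1, 0))
    chosen = is_best & (rank == choice[focal])
    candidate = np.full(n, -1, dtype=np.int64)
    candidate[focal[chosen]] = neigh_sol[chosen]

    if evaluation == "own":
        exploit = (deg > 0) & (segmax > cur)
    else:
        cand_own = np.where(
            candidate >= 0,
            pop.payoff_tables[pop.class_of, np.maximum(candidate, 0)],
            -np.inf,
        )
        exploit = (deg > 0) & (cand_own > cur)

    explored = sol ^ (np.int64(1) << flips.astype(np.int64))
    explore_ok = pop.payoff_tables[pop.class_of, explored] > cur
    new_sol = np.where(exploit, candidate, np.where(explore_ok, explored, sol))
    return new_sol


def step(
    state: SimulationState,
    rng: np.random.Generator,
    evaluation: str = "own",
) -> SimulationState:
    """One synchronous update; returns the time-(t+1) state."""
    pop = state.population
    tie_u = rng.random(pop.n_agents)
    flips = rng.integers(0, pop.n_elements, pop.n_agents)
    new_sol = _propose(state, tie_u, flips, evaluation)
    # shallow copy: shares graph, landscapes and payoff tables, swaps solutions
    new_pop = copy.copy(pop)
    new_pop.solutions = new_sol
    return SimulationState(
        t=state.t + 1,
        population=new_pop,
        payoffs=new_pop.payoff_tables[new_pop.class_of, new_sol],
    )


def is_absorbed(state: SimulationState) -> bool:
    """True iff no agent can ever improve again.

    Requires, for every agent, (a) no neighbour solution strictly better
    under its own function and (b) no strictly improving single-element
    flip (the agent sits at a local optimum of its own landscape).  From
    such a state every future step is the identity, for either evaluation
    rule (adoption always requires strict own-payoff improvement).
    """
    pop = state.population
    g = pop.graph
    cur = state.payoffs
    focal = np.repeat(np.arange(pop.n_agents), g.degrees)
    edge_vals = pop.payoff_tables[pop.class_of[focal], pop.solutions[g.indices]]
    segmax = _segment_reduce(edge_vals, g.indptr[:-1], g.degrees, np.maximum, -np.inf)
    if (segmax > cur).any():
        return False
    for j in range(pop.n_elements):
        flipped = pop.solutions ^ (1 << j)
        if (pop.payoff_tables[pop.class_of, flipped] > cur).any():
            return False
    return True


def run(
    population: Population,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
    evaluation: str = "own",
) -> Trajectory:
    """Iterate the dynamics to absorption or the horizon.

    Records <P>(t) (with min/max) each step, the number of agents that
    changed solution, and each agent's first-passage time to its own
    optimum.  Reaching the horizon without absorption is recorded on the
    trajectory, not an error.
    """
    state = make_state(population)
    rng = np.random.default_rng(seed)
    n = population.n_agents

    mean_s = [float(state.payoffs.mean())]
    min_s = [float(state.payoffs.min())]
    max_s = [float(state.payoffs.max())]
    changed_s = [0]
    t_opt = np.where(state.payoffs == 1.0, 0, CENSORED).astype(np.int64)

    absorbed = is_absorbed(state)
    absorbed_step: int | None = 0 if absorbed else None
    while not absorbed and state.t < max_steps:
        prev = state.population.solutions
        state = step(state, rng, evaluation)
        n_changed = int((state.population.solutions != prev).sum())
        mean_s.append(float(state.payoffs.mean()))
        min_s.append(float(state.payoffs.min()))
        max_s.append(float(state.payoffs.max()))
        changed_s.append(n_changed)
        newly = (t_opt == CENSORED) & (state.payoffs == 1.0)
        t_opt[newly] = state.t
        if n_changed == 0 and is_absorbed(state):
            absorbed = True
            absorbed_step = state.t
    population.solutions = state.population.solutions  # expose final state
    return Trajectory(
        mean_payoff_series=np.array(mean_s),
        min_payoff_series=np.array(min_s),
        max_payoff_series=np.array(max_s),
        n_changed_series=np.array(changed_s),
        t_optimum=t_opt,
        final_payoffs=state.payoffs.copy(),
        absorbed=absorbed,
        absorbed_step=absorbed_step,
        max_steps=int(max_steps),
        class_of=population.class_of.copy(),
    )
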