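"""Populations of agents partitioned into equally sized skill classes.

Each class owns one NK landscape (its payoff function); all class landscapes
share the same (n_elements, k_interactions, exponent) but are independent
random draws.  Agents are assigned to classes by a uniformly random balanced
permutation and placed on graph nodes by a random shuffle; solutions are
initialized uniformly over the full solution space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import _seeds
from .landscapes import NKLandscape, generate_landscape
from .networks import Graph

__all__ = ["LandscapeParams", "Population", "build_population", "initialize_solutions"]


class LandscapeParams(NamedTuple):
    n_elements: int
    k_interactions: int
    exponent: float = 8.0


@dataclass
class Population:
    n_agents: int
    n_classes: int
    class_of: np.ndarray  # (n_agents,) class index per agent
    landscapes: list[NKLandscape]  # one per class
    graph: Graph
    solutions: np.ndarray | None = None  # (n_agents,) solution codes
    seed: int | None = None
    # (n_classes, 2**n_elements) stacked payoff tables for vectorized lookups
    payoff_tables: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_agents % self.n_classes != 0:
            raise ValueError(
                f"n_agents={self.n_agents} not divisible by n_classes={self.n_classes}"
            )
        if self.graph.n_nodes != self.n_agents:
            raise ValueError("graph node count must equal n_agents")
        if len(self.landscapes) != self.n_classes:
            raise ValueError("need exactly one landscape per class")
        ref = self.landscapes[0]
        for l in self.landscapes[1:]:
            if (l.n_elements, l.k_interactions, l.exponent) != (
                ref.n_elements,
                ref.k_interactions,
                ref.exponent,
            ):
                raise ValueError("all class landscapes must share (n, k, exponent)")
        counts = np.bincount(self.class_of, minlength=self.n_classes)
        if not (counts == self.n_agents // self.n_classes).all():
            raise ValueError("classes must be exactly equally sized")
        self.payoff_tables = np.stack([l.payoff_table for l in self.landscapes])

    @property
    def n_elements(self) -> int:
        return self.landscapes[0].n_elements

    def landscape_of(self, agent: int) -> NKLandscape:
        return self.landscapes[int(self.class_of[agent])]

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.class_of, minlength=self.n_classes)

    # -- audit snapshot ----------------------------------------------------

    def snapshot(self, path: str | Path) -> None:
        """Write a JSON snapshot sufficient to resume or audit a run."""
        doc = {
            "n_agents": self.n_agents,
            "n_classes": self.n_classes,
            "seed": self.seed,
            "class_of": self.class_of.tolist(),
            "landscape_refs": [
                {
                    "n_elements": l.n_elements,
                    "k_interactions": l.k_interactions,
                    "exponent": l.exponent,
                    "seed": l.seed,
                }
                for l in self.landscapes
            ],
            "solutions": None if self.solutions is None else self.solutions.tolist(),
        }
        Path(path).write_text(json.dumps(doc))


def build_population(
    n_agents: int,
    n_classes: int,
    landscape_params: LandscapeParams | tuple,
    graph: Graph,
    seed: int,
) -> Population:
    """Build a population: class landscapes, class map, node placement.

    ``seed`` spawns independent named streams for each class landscape, the
    balanced class assignment and the node shuffle, so populations differing
    only in ``n_classes`` share all other random draws.
    """
    params = LandscapeParams(*landscape_params)
    if n_agents % n_classes != 0:
        raise ValueError(
            f"n_agents={n_agents} must be divisible by n_classes={n_classes}"
        )
    if graph.n_nodes != n_agents:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes, population has {n_agents} agents"
        )
    landscapes = [
        generate_landscape(
            params.n_elements,
            params.k_interactions,
            seed=_seeds.child_seed(seed, _seeds.LANDSCAPE, c),
            exponent=params.exponent,
        )
        for c in range(n_classes)
    ]
    labels = np.repeat(np.arange(n_classes), n_agents // n_classes)
    class_of = _seeds.rng(seed, _seeds.CLASS_ASSIGN).permutation(labels)
    # random agent-to-node placement; agent i then occupies node i
    placement = _seeds.rng(seed, _seeds.NODE_SHUFFLE).permutation(n_agents)
    class_of = class_of[placement]
    return Population(
        n_agents=int(n_agents),
        n_classes=int(n_classes),
        class_of=class_of,
        landscapes=landscapes,
        graph=graph,
        seed=int(seed),
    )


def initialize_solutions(population: Population, seed: int) -> Population:
    """Draw each agent's initial solution uniformly from all 2**n codes."""
    rng = np.random.default_rng(seed)
    population.solutions = rng.integers(
        0, 1 << population.n_elements, population.n_agents, dtype=np.int64
    )
    return population
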