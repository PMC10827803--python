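"""Configuration-driven sweeps over diversity × network density grids.

A sweep runs every (class count, mean degree) grid point for a fixed task,
each point over ``n_realizations`` independent realizations with
sub-seeds derived from the master seed.  Two grid cells that share a
realization index reuse identical network and initial-solution draws
whenever their configurations coincide on those components (the network
stream does not depend on the class count, and the landscape / initial
solution streams do not depend on the network density).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _seeds, dynamics, metrics, networks
from .metrics import ConditionSummary
from .population import LandscapeParams, build_population, initialize_solutions

__all__ = ["ExperimentConfig", "make_network", "run_condition", "sweep"]

NETWORK_FAMILIES = ("er", "regular", "smallworld", "complete")


@dataclass
class ExperimentConfig:
    """Full description of a diversity × density sweep."""

    n_agents: int = 1000
    n_classes: list[int] = field(default_factory=lambda: [1])
    n_elements: int = 15
    k_interactions: int = 0
    exponent: float = 8.0
    network: str = "er"
    mean_degrees: list[float] = field(default_factory=lambda: [4.0])
    rewire_prob: float = 0.1  # small-world only
    max_steps: int = 1000
    n_realizations: int = 50
    master_seed: int = 0
    evaluation: str = "own"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.network not in NETWORK_FAMILIES:
            raise ValueError(f"network must be one of {NETWORK_FAMILIES}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for c in self.n_classes:
            if self.n_agents % c != 0:
                raise ValueError(f"n_agents={self.n_agents} not divisible by C={c}")

    @property
    def landscape_params(self) -> LandscapeParams:
        return LandscapeParams(self.n_elements, self.k_interactions, self.exponent)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        doc = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def make_network(
    family: str,
    n_nodes: int,
    mean_degree: float,
    rewire_prob: float,
    seed: int,
) -> networks.Graph:
    if family == "er":
        return networks.random_graph(n_nodes, mean_degree, seed)
    if family == "regular":
        return networks.regular_random_graph(n_nodes, int(mean_degree), seed)
    if family == "smallworld":
        return networks.small_world_graph(
            n_nodes, int(mean_degree), rewire_prob, seed
        )
    if family == "complete":
        return networks.complete_graph(n_nodes)
    raise ValueError(f"unknown network family: {family!r}")


def _run_realization(
    config: ExperimentConfig, n_classes: int, mean_degree: float, realization: int
) -> metrics.Trajectory:
    master = config.master_seed
    graph = make_network(
        config.network,
        config.n_agents,
        mean_degree,
        config.rewire_prob,
        seed=_seeds.child_seed(master, realization, _seeds.NETWORK),
    )
    pop = build_population(
        config.n_agents,
        n_classes,
        config.landscape_params,
        graph,
        seed=_seeds.child_seed(master, realization, _seeds.POPULATION),
    )
    initialize_solutions(
        pop, seed=_seeds.child_seed(master, realization, _seeds.INIT_SOLUTIONS)
    )
    return dynamics.run(
        pop,
        max_steps=config.max_steps,
        seed=_seeds.child_seed(master, realization, _seeds.DYNAMICS),
        evaluation=config.evaluation,
    )


def run_condition(
    config: ExperimentConfig,
    n_classes: int,
    mean_degree: float,
    out_dir: str | Path | None = None,
    keep_trajectories: bool = False,
):
    """Run one grid point over all realizations and aggregate.

    Returns the :class:`~divlearn.metrics.ConditionSummary` (and the raw
    trajectories when ``keep_trajectories``).  When ``out_dir`` is given,
    writes summary JSON, aligned-curve and histogram CSVs, and per-
    realization trajectory CSVs.
    """
    trajs = [
        _run_realization(config, n_classes, mean_degree, r)
        for r in range(config.n_realizations)
    ]
    summary = metrics.aggregate(trajs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"C{n_classes}_k{mean_degree:g}"
        echo = config.to_dict() | {
            "condition": {"n_classes": n_classes, "mean_degree": mean_degree}
        }
        summary.write_json(out / f"summary_{tag}.json", config_echo=echo)
        summary.curves_to_csv(out / f"curves_{tag}.csv")
        summary.hist_to_csv(out / f"t_optimum_hist_{tag}.csv")
        pd.concat(
            [t.to_frame(realization_id=r) for r, t in enumerate(trajs)]
        ).to_csv(out / f"trajectories_{tag}.csv", index=False)
        pd.concat(
            [t.agents_to_frame(realization_id=r) for r, t in enumerate(trajs)]
        ).to_csv(out / f"agents_{tag}.csv", index=False)
    if keep_trajectories:
        return summary, trajs
    return summary


def _summary_row(
    n_classes: int, mean_degree: float, s: ConditionSummary | None, status: str
) -> dict:
    row = {
        "class_count": n_classes,
        "mean_degree": mean_degree,
        "status": status,
        "mean_T_O": np.nan,
        "censored_frac": np.nan,
        "mean_final_P": np.nan,
        "sd_final_P": np.nan,
        "absorbed_frac": np.nan,
        "n_realizations": 0,
    }
    if s is not None:
        row.update(
            mean_T_O=s.mean_t_optimum,
            censored_frac=s.censored_fraction,
            mean_final_P=s.mean_final_payoff,
            sd_final_P=s.sd_final_payoff,
            absorbed_frac=s.absorbed_fraction,
            n_realizations=s.n_realizations,
        )
    return row


def sweep(config: ExperimentConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Cartesian product of class counts × mean degrees, one row per cell.

    A cell that fails is recorded with its error in the ``status`` column
    and the sweep continues.
    """
    out_dir = out_dir if out_dir is not None else config.out_dir
    rows = []
    for c in config.n_classes:
        for k in config.mean_degrees:
            try:
                s = run_condition(config, c, k, out_dir=out_dir)
                rows.append(_summary_row(c, k, s, "ok"))
            except Exception as exc:  # keep sweeping past a broken cell
                rows.append(_summary_row(c, k, None, f"error: {exc}"))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.csv", index=False)
        config.save(out / "config.json")
    return table
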