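"""Summary statistics: collective performance, times to optimum, aggregates.

Collective performance at step t is the population mean of each agent's
own-function transformed payoff, <P>(t).  T_O is the first step at which an
agent holds its own landscape's optimum (own payoff exactly 1); agents that
never reach it within the horizon are censored and excluded from <T_O>
averages, with the censored fraction reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ConditionSummary",
    "mean_payoff",
    "times_to_optimum",
    "aggregate",
    "bootstrap_mean_ci",
]

CENSORED = -1  # marker in per-agent t_optimum arrays


@dataclass
class Trajectory:
    """Per-realization record of one simulation run.

    ``mean/min/max_payoff_series`` have length ``n_steps + 1`` (the t=0
    entry is the initial state).  ``t_optimum[i]`` is the first step at
    which agent i's own payoff reached exactly 1, or ``CENSORED``.
    """

    mean_payoff_series: np.ndarray
    min_payoff_series: np.ndarray
    max_payoff_series: np.ndarray
    n_changed_series: np.ndarray
    t_optimum: np.ndarray
    final_payoffs: np.ndarray
    absorbed: bool
    absorbed_step: int | None
    max_steps: int
    class_of: np.ndarray | None = None

    @property
    def n_agents(self) -> int:
        return int(self.final_payoffs.size)

    @property
    def n_steps(self) -> int:
        return int(self.mean_payoff_series.size - 1)

    @property
    def final_mean_payoff(self) -> float:
        return float(self.mean_payoff_series[-1])

    def to_frame(self, realization_id: int = 0) -> pd.DataFrame:
        """Long-format time series (one row per step)."""
        t = np.arange(self.n_steps + 1)
        return pd.DataFrame(
            {
                "realization_id": realization_id,
                "t": t,
                "mean_payoff": self.mean_payoff_series,
                "min_payoff": self.min_payoff_series,
                "max_payoff": self.max_payoff_series,
                "n_changed": self.n_changed_series,
            }
        )

    def agents_to_frame(self, realization_id: int = 0) -> pd.DataFrame:
        """Per-agent records: time to optimum (censored -> NaN) and finals."""
        t_o = self.t_optimum.astype(float)
        t_o[self.t_optimum == CENSORED] = np.nan
        return pd.DataFrame(
            {
                "realization_id": realization_id,
                "agent": np.arange(self.n_agents),
                "class": self.class_of
                if self.class_of is not None
                else np.zeros(self.n_agents, dtype=int),
                "t_optimum": t_o,
                "final_payoff": self.final_payoffs,
            }
        )


def mean_payoff(state) -> float:
    """Population mean of own-function payoffs, <P>(t)."""
    return float(np.mean(state.payoffs))


def times_to_optimum(trajectory: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent first-passage times to own optimum.

    Returns ``(times, censored)`` where ``times`` is a float array with NaN
    at censored entries and ``censored`` a boolean mask of agents that never
    reached their optimum within the horizon.
    """
    censored = trajectory.t_optimum == CENSORED
    times = trajectory.t_optimum.astype(float)
    times[censored] = np.nan
    return times, censored


@dataclass
class ConditionSummary:
    """Realization-averaged statistics for one experimental condition."""

    n_realizations: int
    n_agents: int
    max_steps: int
    mean_payoff_curve: np.ndarray  # aligned over t, short runs padded
    min_payoff_curve: np.ndarray
    max_payoff_curve: np.ndarray
    final_mean_payoffs: np.ndarray  # per realization
    mean_final_payoff: float
    sd_final_payoff: float
    pooled_t_optimum: np.ndarray  # all uncensored agent T_O values pooled
    mean_t_optimum: float  # pooled across agents and realizations
    mean_t_optimum_by_realization: float  # mean of per-realization means
    censored_fraction: float
    absorbed_fraction: float
    t_optimum_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_realizations": self.n_realizations,
            "n_agents": self.n_agents,
            "max_steps": self.max_steps,
            "mean_final_payoff": self.mean_final_payoff,
            "sd_final_payoff": self.sd_final_payoff,
            "mean_t_optimum": self.mean_t_optimum,
            "mean_t_optimum_by_realization": self.mean_t_optimum_by_realization,
            "censored_fraction": self.censored_fraction,
            "absorbed_fraction": self.absorbed_fraction,
        }

    def write_json(self, path: str | Path, config_echo: dict | None = None) -> None:
        doc = self.to_dict()
        if config_echo is not None:
            doc["config"] = config_echo
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    def curves_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t": np.arange(self.mean_payoff_curve.size),
                "mean_payoff": self.mean_payoff_curve,
                "min_payoff": self.min_payoff_curve,
                "max_payoff": self.max_payoff_curve,
            }
        ).to_csv(path, index=False)

    def hist_to_csv(self, path: str | Path) -> None:
        counts, edges = self.t_optimum_hist
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ).to_csv(path, index=False)


def _pad_to(series: np.ndarray, length: int) -> np.ndarray:
    """Extend a series with its final (absorbing) value."""
    if series.size >= length:
        return series[:length]
    return np.concatenate([series, np.full(length - series.size, series[-1])])


def aggregate(trajectories, hist_bin_width: float = 1.0) -> ConditionSummary:
    """Aggregate identically configured realizations into one summary.

    Time series are aligned by t; runs that absorbed early are padded with
    their absorbing value.  T_O values are pooled across all agents of all
    realizations (the per-realization-mean variant is reported alongside).
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("need at least one trajectory")
    n_agents = {t.n_agents for t in trajs}
    horizons = {t.max_steps for t in trajs}
    if len(n_agents) > 1 or len(horizons) > 1:
        raise ValueError("cannot aggregate trajectories from mixed configurations")
    length = max(t.n_steps for t in trajs) + 1
    mean_curve = np.mean([_pad_to(t.mean_payoff_series, length) for t in trajs], axis=0)
    min_curve = np.mean([_pad_to(t.min_payoff_series, length) for t in trajs], axis=0)
    max_curve = np.mean([_pad_to(t.max_payoff_series, length) for t in trajs], axis=0)

    finals = np.array([t.final_mean_payoff for t in trajs])
    pooled, per_real_means, n_censored, n_total = [], [], 0, 0
    for t in trajs:
        times, censored = times_to_optimum(t)
        ok = times[~censored]
        pooled.append(ok)
        per_real_means.append(ok.mean() if ok.size else np.nan)
        n_censored += int(censored.sum())
        n_total += censored.size
    pooled = np.concatenate(pooled)
    valid_real_means = [m for m in per_real_means if not np.isnan(m)]
    if pooled.size:
        hi = pooled.max() + hist_bin_width
        edges = np.arange(0, hi + hist_bin_width, hist_bin_width)
        hist = np.histogram(pooled, bins=edges)
    else:
        hist = (np.array([]), np.array([0.0]))
    return ConditionSummary(
        n_realizations=len(trajs),
        n_agents=n_agents.pop(),
        max_steps=horizons.pop(),
        mean_payoff_curve=mean_curve,
        min_payoff_curve=min_curve,
        max_payoff_curve=max_curve,
        final_mean_payoffs=finals,
        mean_final_payoff=float(finals.mean()),
        sd_final_payoff=float(finals.std(ddof=1)) if finals.size > 1 else 0.0,
        pooled_t_optimum=pooled,
        mean_t_optimum=float(pooled.mean()) if pooled.size else float("nan"),
        mean_t_optimum_by_realization=float(np.mean(valid_real_means))
        if valid_real_means
        else float("nan"),
        censored_fraction=n_censored / n_total,
        absorbed_fraction=float(np.mean([t.absorbed for t in trajs])),
        t_optimum_hist=hist,
    )


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, (n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return (
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1 - alpha)),
    )
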