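"""Simulation designs: goal-frequency profiles, teaching-fraction sweeps,
and the cumulative-cultural-evolution criterion.

A sweep varies the fraction of the R-round budget spent on teaching and
compares each lineage's per-generation mean reward with the fixed-budget
individual-learning baseline.  A generation whose mean strictly exceeds
the baseline exhibits cumulative cultural evolution (CCE): the chain has
reached performance that a lone agent with the same time budget does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generations import LineageConfig, run_individual_baseline, run_lineage
from .learning import LearningParams, Trajectory
from .network import TaskNetwork, chain_network, generate_task_network

__all__ = [
    "SweepResult",
    "goal_frequency_table",
    "fraction_to_T",
    "sweep_teaching_fraction",
    "detect_cce",
    "make_test_fixtures",
]


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one teaching fraction within a sweep."""

    R: int
    teaching_fraction: float  # percent of R
    T: int
    mean_reward_per_generation: tuple[float, ...]  # across lineages
    final_mean: float
    final_sd: float
    baseline_mean: float
    cce_flag: bool

    def __post_init__(self) -> None:
        if self.cce_flag != (self.final_mean > self.baseline_mean):
            raise ValueError("cce_flag must equal final_mean > baseline_mean")

    def to_frame(self) -> pd.DataFrame:
        means = self.mean_reward_per_generation
        return pd.DataFrame(
            {
                "R": self.R,
                "teaching_fraction": self.teaching_fraction,
                "T": self.T,
                "generation": np.arange(len(means)),
                "mean_reward": means,
                "baseline_mean": self.baseline_mean,
                "cce_flag": self.cce_flag,
            }
        )


def goal_frequency_table(outcomes) -> dict[int, int]:
    """Count how many rounds ended at each goal (index 0 = step-cap failure).

    Accepts an iterable of :class:`Trajectory` objects or of raw goal
    indices.  Counts cover indices 0..6 and sum to the number of rounds.
    """
    counts = {k: 0 for k in range(7)}
    for item in outcomes:
        goal = item.terminal_goal if isinstance(item, Trajectory) else int(item)
        counts[goal] = counts.get(goal, 0) + 1
    return counts


def fraction_to_T(fraction: float, R: int) -> int:
    """Teaching rounds for a percentage of the budget, rounding half up.

    ``fraction`` is in percent: 25% of R=10 gives T=3.
    """
    return int(np.floor(fraction / 100.0 * R + 0.5))


def sweep_teaching_fraction(
    net: TaskNetwork,
    R: int,
    fractions: "list[float]",
    n_lineages: int,
    n_generations: int,
    seed: int,
    teacher_mode: str = "probabilistic",
    params: "LearningParams | None" = None,
    baseline_n_agents: int = 1000,
) -> list[SweepResult]:
    """Run independent lineages for each teaching fraction (percent of R).

    The baseline (mean round-R reward of ``baseline_n_agents``
    fixed-budget individual learners) is computed once per sweep.  Seeds
    are spawned per (fraction, lineage) from the master seed, so adding
    lineages or fractions never perturbs existing ones.
    """
    params = params or LearningParams()
    for f in fractions:
        T = fraction_to_T(f, R)
        if not 1 <= T < R:
            raise ValueError(f"fraction {f}% of R={R} gives T={T}, need 1 <= T < R")
    baseline = run_individual_baseline(
        net, R, baseline_n_agents,
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,))), params,
    )
    results = []
    for i, f in enumerate(fractions):
        T = fraction_to_T(f, R)
        cfg = LineageConfig(
            R=R, T=T, n_generations=n_generations,
            teacher_mode=teacher_mode, params=params,
        )
        rewards = np.zeros((n_lineages, n_generations))
        for j in range(n_lineages):
            # keyed per (T, lineage): lineage j of fraction f keeps its
            # stream no matter how many lineages or fractions run
            ss = np.random.SeedSequence(seed, spawn_key=(1, T, j))
            records = run_lineage(cfg, net, np.random.default_rng(ss))
            rewards[j] = [rec.final_reward for rec in records]
        per_gen = rewards.mean(axis=0)
        final_mean = float(per_gen[-1])
        results.append(
            SweepResult(
                R=R,
                teaching_fraction=float(f),
                T=T,
                mean_reward_per_generation=tuple(float(x) for x in per_gen),
                final_mean=final_mean,
                final_sd=float(rewards[:, -1].std(ddof=1)) if n_lineages > 1 else 0.0,
                baseline_mean=baseline.mean,
                cce_flag=final_mean > baseline.mean,
            )
        )
    return results


def detect_cce(per_generation_means, baseline_mean: float) -> "int | None":
    """First generation whose mean strictly exceeds the baseline, else None."""
    series = list(per_generation_means)
    if not series:
        raise ValueError("per_generation_means is empty")
    for g, m in enumerate(series):
        if m > baseline_mean:
            return g
    return None


def make_test_fixtures() -> dict[str, TaskNetwork]:
    """Small deterministic networks for unit tests and worked examples.

    Chains of 2..7 nodes (goals at every distance per the distance
    rule), a 2-cluster toy of 3+3 nodes, and a fixed-seed instance of
    the standard 3x20 three-cluster network.
    """
    fixtures: dict[str, TaskNetwork] = {}
    for n in range(2, 8):
        fixtures[f"chain{n}"] = chain_network(n)
    fixtures["two_cluster"] = generate_task_network(
        np.random.default_rng(7), n_clusters=2, n_per_cluster=3,
        edge_prob=1.0, n_goals=2, goal_clusters="any",
    )
    fixtures["three_cluster"] = generate_task_network(np.random.default_rng(2023))
    return fixtures
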