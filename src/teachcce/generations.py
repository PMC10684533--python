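"""Transmission chains: generations under an R-round learning budget.

Each generation is a single fresh agent with ``R`` rounds to spend.
The first generation learns individually for all ``R`` rounds; later
generations spend the first ``T`` rounds being taught the previous
generation's final-round path and the remaining ``R - T`` rounds
exploring on their own.  The path taken in a generation's final round
becomes the next generation's lesson (probabilistic teacher) — or, in
the greedy variant, the argmax walk over the generation's learned
state–action values.

Two reference processes calibrate what counts as cumulative cultural
evolution: the fixed-budget baseline (independent agents with the same
R rounds and no teaching) and the immortal agent (one never-resetting
individual learner, i.e. transmission with no information loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import AgentMemory, LearningParams, Trajectory, run_individual_round
from .network import TaskNetwork
from .teaching import TaughtPath, extract_greedy_path, extract_taught_path, run_teaching_round

__all__ = [
    "LineageConfig",
    "GenerationRecord",
    "BaselineResult",
    "run_generation",
    "run_lineage",
    "run_individual_baseline",
    "run_immortal_agent",
]

TEACHER_MODES = ("probabilistic", "greedy")


@dataclass(frozen=True)
class LineageConfig:
    """Everything one lineage run needs besides the network and the rng."""

    R: int
    T: int
    n_generations: int
    teacher_mode: str = "probabilistic"
    teach_last_success: bool = False
    params: LearningParams = field(default_factory=LearningParams)

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 <= self.T < self.R:
            raise ValueError(f"need 0 <= T < R, got T={self.T}, R={self.R}")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.teacher_mode not in TEACHER_MODES:
            raise ValueError(f"teacher_mode must be one of {TEACHER_MODES}")


@dataclass(frozen=True)
class GenerationRecord:
    """Outcome of one generation: its final (R-th) round only."""

    generation: int
    final_reward: int
    final_goal: int
    final_path_length: int

    def __post_init__(self) -> None:
        if self.final_reward != self.final_goal**2:
            raise ValueError("final_reward must equal final_goal squared")


@dataclass(frozen=True)
class BaselineResult:
    """Final-round rewards of independent fixed-budget individual learners."""

    mean: float
    sd: float
    rewards: tuple[int, ...]


def run_generation(
    net: TaskNetwork,
    taught_path: "TaughtPath | None",
    R: int,
    T: int,
    rng: np.random.Generator,
    params: "LearningParams | None" = None,
    generation: int = 0,
    memory: "AgentMemory | None" = None,
) -> tuple[GenerationRecord, Trajectory, AgentMemory]:
    """One generation's R rounds: T forced replays, then R−T explorations.

    ``taught_path`` must be ``None`` exactly when this is a first
    generation (then all R rounds are individual and T is ignored as 0).
    Returns the generation's record, its final-round trajectory (the
    next generation's lesson source) and its end-of-life memory (the
    greedy teacher reads this).
    """
    params = params or LearningParams()
    if taught_path is None:
        T = 0
    elif not 0 <= T < R:
        raise ValueError(f"need 0 <= T < R, got T={T}, R={R}")
    if memory is None:
        memory = AgentMemory.zeros(net, params)
    if taught_path is not None and T > 0:
        taught_path.validate(net)
        for _ in range(T):
            run_teaching_round(memory, taught_path, validate=False)
    final: "Trajectory | None" = None
    for _ in range(R - T):
        final = run_individual_round(memory, rng)
    assert final is not None  # R - T >= 1 is guaranteed by T < R
    record = GenerationRecord(
        generation=generation,
        final_reward=final.reward,
        final_goal=final.terminal_goal,
        final_path_length=final.n_steps,
    )
    return record, final, memory


def run_lineage(
    cfg: LineageConfig,
    net: TaskNetwork,
    rng: np.random.Generator,
) -> list[GenerationRecord]:
    """A full transmission chain of ``cfg.n_generations`` generations.

    Every generation starts from a blank memory; only the taught path
    crosses the generation boundary.  With ``teach_last_success`` the
    lesson falls back to the teacher's most recent successful round
    when its final round failed (by default the failed path is taught
    as-is).
    """
    records: list[GenerationRecord] = []
    lesson: "TaughtPath | None" = None
    last_success: "Trajectory | None" = None
    for g in range(cfg.n_generations):
        memory = AgentMemory.zeros(net, cfg.params)
        if lesson is not None and cfg.T > 0:
            lesson.validate(net)
            for _ in range(cfg.T):
                run_teaching_round(memory, lesson, validate=False)
        T_used = 0 if lesson is None else cfg.T
        final: "Trajectory | None" = None
        gen_success: "Trajectory | None" = None
        for _ in range(cfg.R - T_used):
            final = run_individual_round(memory, rng)
            if final.terminal_goal > 0:
                gen_success = final
        assert final is not None
        if gen_success is None and lesson is not None and lesson.terminal_goal > 0:
            # all teaching rounds replay the lesson; a successful lesson
            # counts as this generation's last success until an
            # individual round supersedes it
            gen_success = Trajectory(
                states=lesson.states,
                terminal_goal=lesson.terminal_goal,
                reward=lesson.reward,
            )
        records.append(
            GenerationRecord(
                generation=g,
                final_reward=final.reward,
                final_goal=final.terminal_goal,
                final_path_length=final.n_steps,
            )
        )
        if cfg.teacher_mode == "greedy":
            lesson = extract_greedy_path(memory)
        else:
            source = final
            if cfg.teach_last_success and final.terminal_goal == 0 and gen_success is not None:
                source = gen_success
            lesson = extract_taught_path(source)
    return records


def run_individual_baseline(
    net: TaskNetwork,
    R: int,
    n_agents: int,
    rng: np.random.Generator,
    params: "LearningParams | None" = None,
) -> BaselineResult:
    """Fixed-budget reference: n independent agents, R individual rounds each.

    Returns the mean and (sample) standard deviation of the round-R
    reward — the dashed reference line against which generational
    performance defines cumulative cultural evolution.
    """
    params = params or LearningParams()
    rewards = []
    for _ in range(n_agents):
        memory = AgentMemory.zeros(net, params)
        final: "Trajectory | None" = None
        for _ in range(R):
            final = run_individual_round(memory, rng)
        assert final is not None
        rewards.append(final.reward)
    arr = np.asarray(rewards, dtype=float)
    sd = float(arr.std(ddof=1)) if n_agents > 1 else 0.0
    return BaselineResult(mean=float(arr.mean()), sd=sd, rewards=tuple(rewards))


def run_immortal_agent(
    net: TaskNetwork,
    total_rounds: int,
    record_every: int,
    rng: np.random.Generator,
    params: "LearningParams | None" = None,
) -> np.ndarray:
    """No-information-loss reference: one agent learning for its whole life.

    The agent's memory is never reset; its reward is recorded at rounds
    ``record_every, 2*record_every, ...`` (matching one sample per
    generation of a lineage when ``record_every == R``).  Returns the
    recorded reward series.
    """
    params = params or LearningParams()
    memory = AgentMemory.zeros(net, params)
    out = np.zeros(total_rounds // record_every, dtype=np.int64)
    for r in range(1, total_rounds + 1):
        traj = run_individual_round(memory, rng)
        if r % record_every == 0:
            out[r // record_every - 1] = traj.reward
    return out
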