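"""Conditioned-reinforcement learning of action sequences.

An agent holds two value tables: a stimulus value ``v(s)`` per state
and a state–action value ``w(s, a)`` per directed edge.  After moving
``s -> s'`` and collecting utility ``u`` (the goal reward if ``s'`` is
a goal, else 0) both tables are nudged toward ``u + v(s')``:

    w(s, s') <- w(s, s') + alpha_w * (u + v(s') - w(s, s'))
    v(s)     <- v(s)     + alpha_v * (u + v(s') - v(s))

Because a state's value feeds the update of its predecessors, reward
creeps backward along a traversed path one state per traversal — the
chaining mechanism that makes step-by-step teaching effective.  Actions
are chosen with the SoftMax rule, ``P(a) ∝ exp(beta * w(s, a))``; a
zero-knowledge agent therefore moves uniformly at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from . import _kernels
from .network import NetworkValidationError, TaskNetwork

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "DEFAULT_MAX_STEPS",
    "LearningParams",
    "AgentMemory",
    "Trajectory",
    "action_probabilities",
    "apply_update",
    "run_individual_round",
]

DEFAULT_ALPHA = 0.9
DEFAULT_BETA = 0.5
DEFAULT_MAX_STEPS = 1000

_SEED_BOUND = 2**31  # numba's np.random.seed takes a 32-bit seed


@dataclass(frozen=True)
class LearningParams:
    """Learning-rule constants shared by a batch of agents.

    ``alpha`` is the learning rate of the state–action table; ``alpha_v``
    (defaulting to ``alpha``) that of the stimulus-value table; ``beta``
    the SoftMax inverse temperature; ``max_steps`` the per-round step cap
    after which a round counts as a failure (goal 0, reward 0).
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    alpha_v: "float | None" = None
    max_steps: int = DEFAULT_MAX_STEPS

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.alpha_v is not None and not 0.0 <= self.alpha_v <= 1.0:
            raise ValueError(f"alpha_v must be in [0, 1], got {self.alpha_v}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")

    @property
    def alpha_w_value(self) -> float:
        return self.alpha

    @property
    def alpha_v_value(self) -> float:
        return self.alpha if self.alpha_v is None else self.alpha_v


@dataclass
class AgentMemory:
    """One agent's value tables, laid out over a task network's CSR view."""

    net: TaskNetwork
    v: np.ndarray
    w: np.ndarray
    params: LearningParams = field(default_factory=LearningParams)

    @classmethod
    def zeros(cls, net: TaskNetwork, params: "LearningParams | None" = None) -> "AgentMemory":
        """A naive agent: all values zero, so its policy is uniform."""
        indptr, indices = net.csr
        return cls(
            net=net,
            v=np.zeros(net.n_nodes, dtype=np.float64),
            w=np.zeros(len(indices), dtype=np.float64),
            params=params or LearningParams(),
        )

    @property
    def alpha(self) -> float:
        return self.params.alpha_w_value

    @property
    def beta(self) -> float:
        return self.params.beta

    def w_of(self, s: int, s_next: int) -> float:
        """State–action value of the move ``s -> s_next``."""
        return float(self.w[self.net.edge_slot(s, s_next)])

    def v_of(self, s: int) -> float:
        return float(self.v[s])

    # snapshot format: {"v": {state: value}, "w": {"s->s'": value}},
    # zero entries omitted (unvisited entries read as 0)
    def to_json(self) -> str:
        indptr, indices = self.net.csr
        wmap: dict[str, float] = {}
        for s in range(self.net.n_nodes):
            for e in range(int(indptr[s]), int(indptr[s + 1])):
                if self.w[e] != 0.0:
                    wmap[f"{s}->{int(indices[e])}"] = float(self.w[e])
        vmap = {str(s): float(x) for s, x in enumerate(self.v) if x != 0.0}
        return json.dumps({"v": vmap, "w": wmap}, sort_keys=True)

    @classmethod
    def from_json(cls, net: TaskNetwork, text: str,
                  params: "LearningParams | None" = None) -> "AgentMemory":
        snap = json.loads(text)
        mem = cls.zeros(net, params)
        for s, x in snap.get("v", {}).items():
            mem.v[int(s)] = float(x)
        for key, x in snap.get("w", {}).items():
            s, s_next = key.split("->")
            mem.w[net.edge_slot(int(s), int(s_next))] = float(x)
        return mem


@dataclass(frozen=True)
class Trajectory:
    """One round's visited states and its outcome.

    ``terminal_goal`` is the goal index reached (0 if the step cap was
    hit first, in which case ``reward`` is 0).  ``states`` includes the
    start node, so ``n_steps == len(states) - 1``.
    """

    states: tuple[int, ...]
    terminal_goal: int
    reward: int

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1

    @property
    def actions(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.states[:-1], self.states[1:]))

    def validate(self, net: TaskNetwork) -> None:
        if self.states[0] != net.start:
            raise NetworkValidationError("trajectory must begin at the start node")
        goal_of = net.goal_of_node
        for s, s_next in self.actions:
            net.edge_slot(s, s_next)  # raises if not adjacent
        for s in self.states[:-1]:
            if goal_of[s] > 0:
                raise NetworkValidationError("goal node visited before the final state")
        last_goal = int(goal_of[self.states[-1]])
        if last_goal != self.terminal_goal:
            raise NetworkValidationError(
                f"terminal_goal {self.terminal_goal} does not match final state (goal {last_goal})"
            )
        if self.reward != self.terminal_goal**2:
            raise NetworkValidationError("reward must equal terminal_goal squared")


def action_probabilities(memory: AgentMemory, state: int) -> dict[int, float]:
    """SoftMax action distribution at ``state``: P(s') ∝ exp(beta·w(s,s'))."""
    indptr, indices = memory.net.csr
    lo, hi = int(indptr[state]), int(indptr[state + 1])
    if hi == lo:
        raise NetworkValidationError(f"state {state} has no neighbors")
    probs = softmax(memory.beta * memory.w[lo:hi])
    return {int(indices[e]): float(p) for e, p in zip(range(lo, hi), probs)}


def apply_update(memory: AgentMemory, s: int, s_next: int, utility: float) -> None:
    """Apply one conditioned-reinforcement update for the move ``s -> s_next``.

    ``utility`` is the reward collected on entering ``s_next`` (k² if it
    is goal k, else 0).  The stimulus value of a goal state is never
    updated — goals are terminal, so their v stays 0.
    """
    slot = memory.net.edge_slot(s, s_next)
    target = utility + memory.v[s_next]
    memory.w[slot] += memory.params.alpha_w_value * (target - memory.w[slot])
    if memory.net.goal_of_node[s] == 0:
        memory.v[s] += memory.params.alpha_v_value * (target - memory.v[s])


def run_individual_round(
    memory: AgentMemory,
    rng: np.random.Generator,
    max_steps: "int | None" = None,
) -> Trajectory:
    """One SoftMax exploration round; the memory is updated in place.

    Starts at the network's start node, samples actions from the agent's
    SoftMax policy, applies the value updates at every step, and stops
    on entering any goal node or after ``max_steps`` transitions
    (default: the agent's ``params.max_steps``).
    """
    net = memory.net
    if max_steps is None:
        max_steps = memory.params.max_steps
    indptr, indices = net.csr
    path_buf = np.empty(max_steps + 1, dtype=np.int64)
    _kernels.seed_rng(int(rng.integers(_SEED_BOUND)))
    n_steps, goal = _kernels.run_round(
        indptr, indices, memory.w, memory.v,
        net.goal_of_node, net.node_utility,
        net.start,
        memory.params.alpha_w_value, memory.params.alpha_v_value,
        memory.params.beta, max_steps, path_buf,
    )
    goal = int(goal)
    return Trajectory(
        states=tuple(int(x) for x in path_buf[: n_steps + 1]),
        terminal_goal=goal,
        reward=goal * goal,
    )
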