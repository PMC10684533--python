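"""Step-by-step teaching by forced path replay.

A teacher demonstrates the path it took in its own final round (a
quasi-optimal path, sampled under SoftMax and possibly full of
detours), and the student is walked along it action by action.  The
student's value tables are updated at every forced step exactly as in
individual learning, so each replay pushes the goal's value one state
further back along the path — teaching a length-L path to criterion
takes on the order of L replays, which is what creates the time
trade-off with individual exploration.

Teaching is not copying: after a single replay only the last transition
of the path carries value, and the student's subsequent SoftMax
exploration reproduces the full path with small probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _kernels
from .learning import AgentMemory, Trajectory
from .network import NetworkValidationError, TaskNetwork

__all__ = [
    "TaughtPath",
    "extract_taught_path",
    "extract_greedy_path",
    "run_teaching_round",
    "shortest_taught_path",
]


@dataclass(frozen=True)
class TaughtPath:
    """The demonstrated state sequence, with its outcome.

    ``terminal_goal == 0`` marks a failed demonstration (the teacher's
    final round hit the step cap); such a path is still replayable but
    delivers zero utility throughout.
    """

    states: tuple[int, ...]
    terminal_goal: int
    reward: int

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1

    def validate(self, net: TaskNetwork) -> None:
        if self.states[0] != net.start:
            raise NetworkValidationError("taught path must begin at the start node")
        goal_of = net.goal_of_node
        for s, s_next in zip(self.states[:-1], self.states[1:]):
            net.edge_slot(s, s_next)
        for s in self.states[:-1]:
            if goal_of[s] > 0:
                raise NetworkValidationError("taught path visits a goal before its end")
        if int(goal_of[self.states[-1]]) != self.terminal_goal:
            raise NetworkValidationError("terminal_goal does not match the final state")
        if self.reward != self.terminal_goal**2:
            raise NetworkValidationError("reward must equal terminal_goal squared")

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": list(self.states),
                "terminal_goal": self.terminal_goal,
                "reward": self.reward,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TaughtPath":
        d = json.loads(text)
        return cls(
            states=tuple(int(s) for s in d["states"]),
            terminal_goal=int(d["terminal_goal"]),
            reward=int(d["reward"]),
        )


def shortest_taught_path(net: TaskNetwork, goal_index: int) -> TaughtPath:
    """The shortest demonstrable path from start to goal ``goal_index``.

    Because a round ends at the first goal entered, a teachable path may
    not pass through any other goal; the path is therefore the shortest
    one in the network with all other goal nodes removed.  Raises
    ``NetworkValidationError`` if no such path exists.
    """
    if goal_index not in net.goals:
        raise NetworkValidationError(f"no goal with index {goal_index}")
    target = net.goals[goal_index]
    blocked = {v for k, v in net.goals.items() if k != goal_index}
    sub = net.graph.subgraph(set(net.graph.nodes) - blocked)
    try:
        states = nx.shortest_path(sub, net.start, target)
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise NetworkValidationError(
            f"goal {goal_index} unreachable without crossing another goal"
        ) from exc
    return TaughtPath(
        states=tuple(int(s) for s in states),
        terminal_goal=goal_index,
        reward=goal_index**2,
    )


def extract_taught_path(teacher_final_round: Trajectory) -> TaughtPath:
    """The probabilistic teacher's demonstration: its final round, verbatim.

    Redundant detours are kept, and a failed final round yields a
    goalless path that is taught as-is.
    """
    return TaughtPath(
        states=teacher_final_round.states,
        terminal_goal=teacher_final_round.terminal_goal,
        reward=teacher_final_round.reward,
    )


def extract_greedy_path(
    teacher_memory: AgentMemory, max_steps: "int | None" = None
) -> TaughtPath:
    """The greedy teacher's demonstration: an argmax walk over its w table.

    Equivalent to sampling with infinite inverse temperature.  Ties are
    broken toward the smallest neighbor id, so the walk is deterministic;
    it is cut at ``max_steps`` (terminal goal 0) if it never reaches a
    goal — e.g. when the largest values form a cycle.
    """
    net = teacher_memory.net
    if max_steps is None:
        max_steps = teacher_memory.params.max_steps
    indptr, indices = net.csr
    goal_of = net.goal_of_node
    w = teacher_memory.w
    s = net.start
    states = [s]
    goal = 0
    for _ in range(max_steps):
        lo, hi = int(indptr[s]), int(indptr[s + 1])
        best = lo
        for e in range(lo + 1, hi):
            if w[e] > w[best]:  # strict: first (smallest-id) neighbor wins ties
                best = e
        s = int(indices[best])
        states.append(s)
        if goal_of[s] > 0:
            goal = int(goal_of[s])
            break
    return TaughtPath(states=tuple(states), terminal_goal=goal, reward=goal * goal)


def run_teaching_round(
    student_memory: AgentMemory, path: TaughtPath, validate: bool = True
) -> Trajectory:
    """Force the student along ``path``, updating its values at every step.

    The student's own policy is never consulted and no randomness is
    involved; the returned trajectory is the path itself with the
    teacher's outcome.  The step cap does not apply — the path already
    respects it by construction.
    """
    net = student_memory.net
    if validate:
        path.validate(net)
    state_arr = np.asarray(path.states, dtype=np.int64)
    status = _kernels.replay_path(
        *net.csr,
        student_memory.w,
        student_memory.v,
        net.goal_of_node,
        net.node_utility,
        state_arr,
        len(state_arr),
        student_memory.params.alpha_w_value,
        student_memory.params.alpha_v_value,
    )
    if status != 0:
        raise NetworkValidationError("taught path is inconsistent with the network")
    return Trajectory(
        states=path.states, terminal_goal=path.terminal_goal, reward=path.reward
    )
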