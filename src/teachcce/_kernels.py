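"""Compiled inner loops for round simulation and forced path replay.

Kernels operate on the CSR adjacency view of a task network (see
``TaskNetwork.csr``): one state–action value per directed edge slot,
one stimulus value per node.  Randomness uses numba's MT19937; callers
seed it through :func:`seed_rng` before sampling kernels run.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def seed_rng(seed):
    # Seeds numba's own global generator (distinct from numpy's).
    np.random.seed(seed)


@njit(cache=False)
def run_round(indptr, indices, w, v, goal_of, utility,
              start, alpha_w, alpha_v, beta, max_steps, path_buf):
    """One exploration round from ``start`` under the SoftMax policy.

    Moves until any goal node is entered or ``max_steps`` transitions
    have been made; updates ``w`` and ``v`` in place at every step.
    Visited states are written to ``path_buf`` (length >= max_steps+1).
    Returns ``(n_steps, terminal_goal)`` with ``terminal_goal == 0``
    on step-cap failure.
    """
    s = start
    path_buf[0] = s
    n_steps = 0
    for _ in range(max_steps):
        lo = indptr[s]
        hi = indptr[s + 1]
        # SoftMax over w[s, ·], max-shifted for numerical safety.
        m = w[lo]
        for e in range(lo + 1, hi):
            if w[e] > m:
                m = w[e]
        total = 0.0
        for e in range(lo, hi):
            total += math.exp(beta * (w[e] - m))
        r = np.random.random() * total
        acc = 0.0
        chosen = hi - 1
        for e in range(lo, hi):
            acc += math.exp(beta * (w[e] - m))
            if r <= acc:
                chosen = e
                break
        s_next = indices[chosen]
        target = utility[s_next] + v[s_next]
        w[chosen] += alpha_w * (target - w[chosen])
        v[s] += alpha_v * (target - v[s])
        n_steps += 1
        path_buf[n_steps] = s_next
        if goal_of[s_next] > 0:
            return n_steps, goal_of[s_next]
        s = s_next
    return n_steps, 0


@njit(cache=False)
def replay_path(indptr, indices, w, v, goal_of, utility,
                path, path_len, alpha_w, alpha_v):
    """Force a learner along ``path[:path_len]``, updating values per step.

    Identical value updates to :func:`run_round`, but actions are
    dictated by the path instead of sampled — the student's own policy
    is never consulted and no random numbers are drawn.
    """
    for i in range(path_len - 1):
        s = path[i]
        s_next = path[i + 1]
        lo = indptr[s]
        hi = indptr[s + 1]
        chosen = -1
        for e in range(lo, hi):
            if indices[e] == s_next:
                chosen = e
                break
        if chosen < 0:
            return -1  # path inconsistent with the network
        target = utility[s_next] + v[s_next]
        w[chosen] += alpha_w * (target - w[chosen])
        if goal_of[s] == 0:  # goal states are terminal; their v stays 0
            v[s] += alpha_v * (target - v[s])
    return 0
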