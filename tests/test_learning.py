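import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teachcce.learning import (
    AgentMemory,
    LearningParams,
    Trajectory,
    action_probabilities,
    apply_update,
    run_individual_round,
)
from teachcce.network import NetworkValidationError, chain_network


class TestActionProbabilities:
    def test_zero_memory_is_uniform(self, chain3_far):
        mem = AgentMemory.zeros(chain3_far)
        probs = action_probabilities(mem, 1)  # neighbors 0 and 2
        assert probs == pytest.approx({0: 0.5, 2: 0.5})

    def test_beta_zero_is_uniform_whatever_w(self, chain3_far, rng):
        mem = AgentMemory.zeros(chain3_far, LearningParams(beta=0.0))
        mem.w[:] = rng.normal(scale=10, size=mem.w.shape)
        probs = action_probabilities(mem, 1)
        assert probs == pytest.approx({0: 0.5, 2: 0.5})

    def test_two_neighbor_closed_form(self, chain3_far):
        # P = e^{0.5*1} / (e^{0.5*1} + e^{0.5*0}) = 0.6225 for the valued move
        mem = AgentMemory.zeros(chain3_far, LearningParams(beta=0.5))
        mem.w[mem.net.edge_slot(1, 2)] = 1.0
        probs = action_probabilities(mem, 1)
        assert probs[2] == pytest.approx(math.exp(0.5) / (math.exp(0.5) + 1), abs=1e-4)
        assert probs[2] == pytest.approx(0.6225, abs=1e-4)
        assert probs[0] == pytest.approx(0.3775, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        w=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        beta=st.floats(0, 5),
        shift=st.floats(-30, 30),
    )
    def test_normalization_positivity_translation_invariance(self, w, beta, shift):
        # a star graph with len(w) leaves; center state 0
        import networkx as nx

        from teachcce.network import TaskNetwork

        g = nx.star_graph(len(w))
        net = TaskNetwork(graph=g, start=0, goals={1: 1})
        mem = AgentMemory.zeros(net, LearningParams(beta=beta))
        indptr, _ = net.csr
        lo, hi = int(indptr[0]), int(indptr[1])
        mem.w[lo:hi] = w
        probs = action_probabilities(mem, 0)
        vals = np.array(list(probs.values()))
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)
        assert (vals > 0).all()
        mem.w[lo:hi] += shift  # SoftMax is invariant to a constant shift
        shifted = action_probabilities(mem, 0)
        assert shifted == pytest.approx(probs)


class TestApplyUpdate:
    def test_transition_into_goal(self, chain2):
        mem = AgentMemory.zeros(chain2, LearningParams(alpha=0.9))
        apply_update(mem, 0, 1, utility=1.0)
        assert mem.w_of(0, 1) == pytest.approx(0.9)
        assert mem.v_of(0) == pytest.approx(0.9)

    def test_zero_utility_zero_values_is_noop(self, chain3_far):
        mem = AgentMemory.zeros(chain3_far)
        apply_update(mem, 0, 1, utility=0.0)
        assert not mem.w.any()
        assert not mem.v.any()

    def test_alpha_one_jumps_to_target(self):
        net = chain_network(7)  # goal 6 at node 6, reward 36
        mem = AgentMemory.zeros(net, LearningParams(alpha=1.0))
        apply_update(mem, 5, 6, utility=36.0)
        assert mem.w_of(5, 6) == 36.0

    def test_non_adjacent_rejected(self, chain3_far):
        mem = AgentMemory.zeros(chain3_far)
        with pytest.raises(NetworkValidationError):
            apply_update(mem, 0, 2, utility=0.0)

    def test_goal_state_value_never_updated(self, chain3_far):
        mem = AgentMemory.zeros(chain3_far)
        mem.v[1] = 3.0
        apply_update(mem, 2, 1, utility=0.0)  # from the goal node backwards
        assert mem.v_of(2) == 0.0  # v of goal 2 (node 2) untouched
        assert mem.w_of(2, 1) == pytest.approx(0.9 * 3.0)


class TestIndividualRound:
    def test_single_action_network_terminates_in_one_step(self, chain2, rng):
        mem = AgentMemory.zeros(chain2)
        traj = run_individual_round(mem, rng)
        assert traj.states == (0, 1)
        assert traj.terminal_goal == 1
        assert traj.reward == 1
        assert traj.n_steps == 1

    def test_chain_values_converge_to_goal_utility(self, chain3_far, rng):
        # fixed point of the update recursion on the chain: both path
        # values converge to the goal reward 4
        mem = AgentMemory.zeros(chain3_far)
        for _ in range(10_000):
            run_individual_round(mem, rng)
        assert mem.w_of(0, 1) == pytest.approx(4.0, abs=1e-3)
        assert mem.w_of(1, 2) == pytest.approx(4.0, abs=1e-3)

    def test_trajectory_contains_goal_only_in_last_position(self, three_cluster, rng):
        mem = AgentMemory.zeros(three_cluster)
        for _ in range(30):
            traj = run_individual_round(mem, rng)
            traj.validate(three_cluster)  # checks adjacency + goal placement
            if traj.terminal_goal > 0:
                assert three_cluster.goal_of_node[traj.states[-1]] == traj.terminal_goal

    def test_step_cap_yields_goal_zero_and_no_reward(self, chain3_far):
        # with max_steps=1 the agent cannot reach the distance-2 goal
        mem = AgentMemory.zeros(chain3_far)
        traj = run_individual_round(mem, np.random.default_rng(3), max_steps=1)
        assert traj.terminal_goal == 0
        assert traj.reward == 0
        assert traj.n_steps == 1

    def test_seeded_run_is_bit_reproducible(self, three_cluster):
        out = []
        for _ in range(2):
            mem = AgentMemory.zeros(three_cluster)
            rng = np.random.default_rng(77)
            trajs = [run_individual_round(mem, rng) for _ in range(20)]
            out.append(([t.states for t in trajs], mem.w.copy(), mem.v.copy()))
        assert out[0][0] == out[1][0]
        np.testing.assert_array_equal(out[0][1], out[1][1])
        np.testing.assert_array_equal(out[0][2], out[1][2])


class TestMemorySnapshot:
    def test_json_round_trip(self, chain3_far, rng):
        mem = AgentMemory.zeros(chain3_far)
        for _ in range(50):
            run_individual_round(mem, rng)
        clone = AgentMemory.from_json(chain3_far, mem.to_json())
        np.testing.assert_allclose(clone.w, mem.w)
        np.testing.assert_allclose(clone.v, mem.v)


class TestTrajectoryInvariants:
    def test_inconsistent_reward_rejected(self, chain2):
        traj = Trajectory(states=(0, 1), terminal_goal=1, reward=2)
        with pytest.raises(NetworkValidationError):
            traj.validate(chain2)

    def test_wrong_start_rejected(self, chain3_far):
        traj = Trajectory(states=(1, 2), terminal_goal=2, reward=4)
        with pytest.raises(NetworkValidationError):
            traj.validate(chain3_far)
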