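import numpy as np
import pytest

from teachcce.learning import AgentMemory, LearningParams, Trajectory, run_individual_round
from teachcce.network import NetworkValidationError, TaskNetwork, chain_network
from teachcce.teaching import (
    TaughtPath,
    extract_greedy_path,
    extract_taught_path,
    run_teaching_round,
    shortest_taught_path,
)


class TestExtractTaughtPath:
    def test_final_round_is_passed_through_verbatim(self, chain3_far, rng):
        mem = AgentMemory.zeros(chain3_far)
        traj = run_individual_round(mem, rng)
        path = extract_taught_path(traj)
        assert path.states == traj.states
        assert path.terminal_goal == traj.terminal_goal
        assert path.reward == traj.reward

    def test_failed_round_gives_goalless_path(self, chain3_far):
        traj = Trajectory(states=(0, 1, 0), terminal_goal=0, reward=0)
        path = extract_taught_path(traj)
        assert path.terminal_goal == 0
        assert path.reward == 0


class TestGreedyTeacher:
    def test_converged_chain_gives_unique_path(self, chain3_far):
        mem = AgentMemory.zeros(chain3_far)
        mem.w[mem.net.edge_slot(0, 1)] = 3.9
        mem.w[mem.net.edge_slot(1, 2)] = 4.0
        path = extract_greedy_path(mem)
        assert path.states == (0, 1, 2)
        assert path.terminal_goal == 2

    def test_zero_memory_walks_to_smallest_id(self):
        # tie-break contract: all-equal w -> smallest neighbor id
        import networkx as nx

        g = nx.Graph([(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)])
        net = TaskNetwork(graph=g, start=0, goals={2: 3})
        mem = AgentMemory.zeros(net)
        path = extract_greedy_path(mem, max_steps=6)
        # 0 -> 1 (smallest), 1 -> 0, oscillation, cut at cap
        assert path.states == (0, 1, 0, 1, 0, 1, 0)
        assert path.terminal_goal == 0

    def test_two_cycle_in_w_is_cut_at_cap(self):
        net = chain_network(4, goal_distances=[3])
        mem = AgentMemory.zeros(net)
        mem.w[net.edge_slot(0, 1)] = 5.0
        mem.w[net.edge_slot(1, 0)] = 5.0
        path = extract_greedy_path(mem, max_steps=9)
        assert path.terminal_goal == 0
        assert path.n_steps == 9
        assert set(path.states) == {0, 1}


class TestTeachingRound:
    def test_first_round_reinforces_only_last_transition(self):
        net = chain_network(4, goal_distances=[3])
        student = AgentMemory.zeros(net)
        path = TaughtPath(states=(0, 1, 2, 3), terminal_goal=3, reward=9)
        run_teaching_round(student, path)
        assert student.w_of(2, 3) != 0.0
        assert student.w_of(1, 2) == 0.0
        assert student.w_of(0, 1) == 0.0
        run_teaching_round(student, path)  # second replay reaches one state further back
        assert student.w_of(1, 2) != 0.0
        assert student.w_of(0, 1) == 0.0

    @pytest.mark.parametrize("L", [1, 2, 5, 10])
    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_backward_chaining_law(self, L, k):
        # after k replays of a simple length-L path, exactly the last
        # min(k, L) state-action pairs carry value
        net = chain_network(L + 1, goal_distances=[L])
        student = AgentMemory.zeros(net)
        path = TaughtPath(
            states=tuple(range(L + 1)), terminal_goal=L, reward=L * L
        )
        for _ in range(k):
            run_teaching_round(student, path)
        nonzero = [i for i in range(L) if student.w_of(i, i + 1) != 0.0]
        assert nonzero == list(range(L - min(k, L), L))

    def test_failed_path_leaves_zero_student_untouched(self, chain3_far):
        student = AgentMemory.zeros(chain3_far)
        path = TaughtPath(states=(0, 1, 0), terminal_goal=0, reward=0)
        run_teaching_round(student, path)
        assert not student.w.any()
        assert not student.v.any()

    def test_student_policy_is_never_consulted(self):
        # a student whose w strongly prefers other moves is still forced
        # along the path, with updates identical to a naive student's
        net = chain_network(4, goal_distances=[3])
        path = TaughtPath(states=(0, 1, 2, 3), terminal_goal=3, reward=9)
        naive = AgentMemory.zeros(net)
        biased = AgentMemory.zeros(net)
        biased.w[net.edge_slot(1, 0)] = 100.0
        biased.w[net.edge_slot(2, 1)] = 100.0
        for student in (naive, biased):
            traj = run_teaching_round(student, path)
            assert traj.states == path.states
        assert biased.w_of(2, 3) == naive.w_of(2, 3)
        assert biased.v_of(2) == naive.v_of(2)

    def test_path_inconsistent_with_network_rejected(self, chain3_far):
        bad = TaughtPath(states=(0, 2), terminal_goal=2, reward=4)
        with pytest.raises(NetworkValidationError):
            run_teaching_round(chain3_far and AgentMemory.zeros(chain3_far), bad)

    def test_replay_matches_scalar_recursion_oracle(self):
        # independent oracle: iterate the update recursion over plain
        # python floats along the path
        L, alpha, reps = 6, 0.9, 8
        net = chain_network(L + 1, goal_distances=[L])
        student = AgentMemory.zeros(net, LearningParams(alpha=alpha))
        path = TaughtPath(states=tuple(range(L + 1)), terminal_goal=L, reward=L * L)
        w = [0.0] * L  # w[i] = value of action i -> i+1
        v = [0.0] * (L + 1)
        for rep in range(reps):
            for i in range(L):
                u = float(L * L) if i == L - 1 else 0.0
                target = u + v[i + 1]
                w[i] += alpha * (target - w[i])
                v[i] += alpha * (target - v[i])
            run_teaching_round(student, path)
            for i in range(L):
                assert student.w_of(i, i + 1) == pytest.approx(w[i], rel=1e-12)
                assert student.v_of(i) == pytest.approx(v[i], rel=1e-12)


class TestShortestTaughtPath:
    def test_chain_path(self):
        net = chain_network(4, goal_distances=[3])
        path = shortest_taught_path(net, 3)
        assert path.states == (0, 1, 2, 3)

    def test_avoids_other_goals(self):
        net = chain_network(4)  # every node is a goal: goal 3 unreachable
        with pytest.raises(NetworkValidationError):
            shortest_taught_path(net, 3)


class TestTeachingFidelity:
    def test_single_replay_transmission_is_far_from_perfect(self, three_cluster):
        # teaching is not copying: one replay of a multi-step path gives
        # a success rate far below 1 on the next exploration round
        path = shortest_taught_path(three_cluster, 3)
        rng = np.random.default_rng(5)
        succ = 0
        n = 1500
        for _ in range(n):
            student = AgentMemory.zeros(three_cluster)
            run_teaching_round(student, path)
            if run_individual_round(student, rng).terminal_goal == 3:
                succ += 1
        assert 0 <= succ / n < 0.5

    def test_success_rate_non_decreasing_in_teaching_rounds(self, three_cluster):
        path = shortest_taught_path(three_cluster, 4)
        rng = np.random.default_rng(6)
        rates = []
        for T in (1, 9):
            succ = 0
            n = 1200
            for _ in range(n):
                student = AgentMemory.zeros(three_cluster)
                for _ in range(T):
                    run_teaching_round(student, path)
                if run_individual_round(student, rng).terminal_goal == 4:
                    succ += 1
            rates.append(succ / n)
        assert rates[1] >= rates[0]
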