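import numpy as np
import pytest

from teachcce.network import chain_network, generate_task_network

#: Seed of the canonical three-cluster task instance shared by the suite.
CANONICAL_SEED = 12345


@pytest.fixture(scope="session")
def three_cluster():
    """The suite's canonical 3x20 three-cluster task network."""
    return generate_task_network(np.random.default_rng(CANONICAL_SEED))


@pytest.fixture
def chain2():
    """start — goal1 (reward 1): the smallest task."""
    return chain_network(2)


@pytest.fixture
def chain3_far():
    """start — A — goal2 (only the far end is a goal, reward 4)."""
    return chain_network(3, goal_distances=[2])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
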