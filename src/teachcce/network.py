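"""Multi-goal task networks.

The task an agent must master is represented as an undirected graph:
nodes are states, edges are actions, and six of the nodes are absorbing
goal states.  Goal *k* sits at shortest-path distance *k* from a
designated start node and pays a reward of ``k**2`` — squaring the
distance widens the reward gaps between near and far goals, which is
what makes distant goals worth ratcheting toward.

The default topology chains three Erdős–Rényi clusters of 20 nodes with
single bridge edges, so that distant goals lie behind narrow bottlenecks
and random exploration rarely escapes the first cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "TaskNetwork",
    "NetworkGenerationError",
    "NetworkValidationError",
    "GoalAssignmentError",
    "generate_er_cluster",
    "build_multi_cluster_network",
    "assign_start_and_goals",
    "generate_task_network",
    "chain_network",
    "save_network",
    "load_network",
]

#: Number of goal nodes assigned by the standard generator.
N_GOALS = 6

#: Default Erdős–Rényi edge probability for generated clusters.  Not a
#: property of the task definition itself; chosen so that a 20-node
#: cluster is almost always connected, a 3-cluster chain still contains
#: nodes six hops from the start, and single-round random exploration
#: reproduces the canonical difficulty profile (nearly all agents end
#: at goal 1 or 2, essentially none beyond the second bottleneck).
DEFAULT_EDGE_PROB = 0.35


class NetworkGenerationError(RuntimeError):
    """Raised when a connected random graph cannot be produced."""


class GoalAssignmentError(RuntimeError):
    """Raised when some distance class 1..n_goals has no candidate node."""


class NetworkValidationError(ValueError):
    """Raised when a network violates the task-network invariants."""


@dataclass(eq=False)
class TaskNetwork:
    """An undirected multi-goal exploration task.

    Parameters
    ----------
    graph
        Undirected simple graph whose nodes are the contiguous integers
        ``0..n-1``.
    start
        The start state of every round.
    goals
        Mapping from goal index ``k`` (a positive integer) to the node
        that carries reward ``k**2``.  Goal ``k`` must lie at shortest
        distance exactly ``k`` from ``start``.
    cluster_of
        Mapping from node to the index of the cluster it was generated
        in (all zeros for single-component topologies such as chains).
    """

    graph: nx.Graph
    start: int
    goals: dict[int, int]
    cluster_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.goals = {int(k): int(v) for k, v in self.goals.items()}
        if not self.cluster_of:
            self.cluster_of = {int(v): 0 for v in self.graph.nodes}
        else:
            self.cluster_of = {int(k): int(v) for k, v in self.cluster_of.items()}
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        g = self.graph
        n = g.number_of_nodes()
        if sorted(g.nodes) != list(range(n)):
            raise NetworkValidationError("node ids must be contiguous 0..n-1")
        if nx.number_of_selfloops(g) > 0:
            raise NetworkValidationError("self-loops are not allowed")
        if not nx.is_connected(g):
            raise NetworkValidationError("graph must be connected")
        if self.start not in g:
            raise NetworkValidationError(f"start node {self.start} not in graph")
        dist = self.distances
        if dist[self.start] != 0:
            raise NetworkValidationError("start must be at distance 0 from itself")
        seen_nodes: set[int] = set()
        for k, node in self.goals.items():
            if k < 1:
                raise NetworkValidationError(f"goal index {k} must be >= 1")
            if node == self.start:
                raise NetworkValidationError("start node cannot be a goal")
            if node in seen_nodes:
                raise NetworkValidationError(f"node {node} assigned to two goals")
            seen_nodes.add(node)
            if dist[node] != k:
                raise NetworkValidationError(
                    f"goal {k} is node {node} at distance {dist[node]}, expected {k}"
                )
        if set(self.cluster_of) != set(g.nodes):
            raise NetworkValidationError("cluster_of must cover every node")

    # -- derived views ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @cached_property
    def rewards(self) -> dict[int, int]:
        """Reward of each goal index: the squared shortest distance."""
        return {k: k * k for k in self.goals}

    @cached_property
    def distances(self) -> dict[int, int]:
        """Shortest-path distance (hops) of every node from the start."""
        return dict(nx.single_source_shortest_path_length(self.graph, self.start))

    @cached_property
    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form ``(indptr, indices)``.

        Neighbour lists are sorted by node id; the directed-edge *slot*
        of action ``s -> s'`` is the position of ``s'`` in ``s``'s row,
        which is how state–action values are laid out in memory.
        """
        n = self.n_nodes
        indptr = np.zeros(n + 1, dtype=np.int64)
        neigh = [sorted(self.graph.neighbors(s)) for s in range(n)]
        for s in range(n):
            indptr[s + 1] = indptr[s] + len(neigh[s])
        indices = np.fromiter(
            (v for row in neigh for v in row), dtype=np.int64, count=int(indptr[-1])
        )
        return indptr, indices

    @cached_property
    def goal_of_node(self) -> np.ndarray:
        """Per-node goal index (0 for non-goal states)."""
        arr = np.zeros(self.n_nodes, dtype=np.int64)
        for k, node in self.goals.items():
            arr[node] = k
        return arr

    @cached_property
    def node_utility(self) -> np.ndarray:
        """Per-node reward collected on entering the node (k² at goal k)."""
        arr = np.zeros(self.n_nodes, dtype=np.float64)
        for k, node in self.goals.items():
            arr[node] = float(k * k)
        return arr

    def neighbors(self, state: int) -> np.ndarray:
        indptr, indices = self.csr
        return indices[indptr[state] : indptr[state + 1]]

    def edge_slot(self, s: int, s_next: int) -> int:
        """Directed-edge slot of the action ``s -> s_next``.

        Raises ``NetworkValidationError`` if the two states are not
        adjacent.
        """
        indptr, indices = self.csr
        lo, hi = int(indptr[s]), int(indptr[s + 1])
        pos = lo + int(np.searchsorted(indices[lo:hi], s_next))
        if pos >= hi or indices[pos] != s_next:
            raise NetworkValidationError(f"states {s} and {s_next} are not adjacent")
        return pos

    # -- equality (used for save/load round-trips) --------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaskNetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and set(map(frozenset, self.graph.edges)) == set(map(frozenset, other.graph.edges))
            and self.start == other.start
            and self.goals == other.goals
            and self.cluster_of == other.cluster_of
        )


# ---------------------------------------------------------------------
# generation


def generate_er_cluster(
    n_nodes: int,
    edge_prob: float,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> nx.Graph:
    """Draw a connected Erdős–Rényi graph ``G(n, p)``.

    Disconnected draws are rejected and redrawn; after ``max_retries``
    failures a :class:`NetworkGenerationError` is raised, which signals
    that ``edge_prob`` is too low for connectivity at this size.
    """
    if not 0.0 < edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in (0, 1], got {edge_prob}")
    if n_nodes < 2:
        raise ValueError("a cluster needs at least 2 nodes")
    for _ in range(max_retries):
        g = nx.gnp_random_graph(n_nodes, edge_prob, seed=rng)
        if nx.is_connected(g):
            return g
    raise NetworkGenerationError(
        f"no connected G({n_nodes}, {edge_prob}) in {max_retries} draws"
    )


def build_multi_cluster_network(
    n_clusters: int,
    n_per_cluster: int,
    edge_prob: float,
    rng: np.random.Generator,
) -> nx.Graph:
    """Chain ER clusters linearly with single bridge edges.

    Cluster ``c`` owns node ids ``[c*n_per_cluster, (c+1)*n_per_cluster)``;
    adjacent clusters are joined by exactly one edge between uniformly
    chosen endpoints, producing the bottleneck structure that makes
    distant goals hard to reach.  Each node's cluster index is stored in
    the ``"cluster"`` node attribute.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    g = nx.Graph()
    for c in range(n_clusters):
        cluster = generate_er_cluster(n_per_cluster, edge_prob, rng)
        offset = c * n_per_cluster
        g.add_nodes_from((offset + v, {"cluster": c}) for v in cluster.nodes)
        g.add_edges_from((offset + u, offset + v) for u, v in cluster.edges)
    for c in range(n_clusters - 1):
        u = int(rng.integers(c * n_per_cluster, (c + 1) * n_per_cluster))
        v = int(rng.integers((c + 1) * n_per_cluster, (c + 2) * n_per_cluster))
        g.add_edge(u, v)
    return g


def assign_start_and_goals(
    skeleton: nx.Graph,
    rng: np.random.Generator,
    n_goals: int = N_GOALS,
    goal_clusters: str = "spread",
) -> TaskNetwork:
    """Place the start node and the distance-1..n_goals goal nodes.

    The start is sampled uniformly from the first cluster; breadth-first
    distances are computed from it, and for each ``k`` one node at
    distance exactly ``k`` is sampled uniformly as goal ``k``.  With
    ``goal_clusters="spread"`` (default) goal ``k`` is additionally
    constrained to cluster ``(k-1)*C // n_goals``, ordering the goals
    outward through the cluster chain — goals 1–2 in the first cluster,
    3–4 in the second, 5–6 in the third for the standard layout — so
    that distant goals sit behind the bottleneck bridges.
    ``goal_clusters="any"`` lifts the constraint.

    Because a round terminates at the first goal entered, goal nodes are
    absorbing: an assignment in which some goal cannot be reached
    without first crossing another goal would make that goal literally
    unattainable and degenerate the multi-goal task.  Such assignments
    are rejected, as are draws where an eligible candidate set is empty
    (:class:`GoalAssignmentError`; callers regenerate the skeleton).
    """
    if goal_clusters not in ("spread", "any"):
        raise ValueError(f"goal_clusters must be 'spread' or 'any', got {goal_clusters!r}")
    cluster_of = {int(v): int(skeleton.nodes[v].get("cluster", 0)) for v in skeleton.nodes}
    n_clusters = max(cluster_of.values()) + 1
    first_cluster = sorted(v for v, c in cluster_of.items() if c == 0)
    start = int(first_cluster[rng.integers(len(first_cluster))])
    dist = nx.single_source_shortest_path_length(skeleton, start)
    goals: dict[int, int] = {}
    for k in range(1, n_goals + 1):
        candidates = sorted(v for v, d in dist.items() if d == k)
        if goal_clusters == "spread":
            want = (k - 1) * n_clusters // n_goals
            candidates = [v for v in candidates if cluster_of[v] == want]
        if not candidates:
            raise GoalAssignmentError(f"no eligible node at distance {k} from start {start}")
        goals[k] = int(candidates[rng.integers(len(candidates))])
    for k, node in goals.items():
        others = {v for j, v in goals.items() if j != k}
        sub = skeleton.subgraph(set(skeleton.nodes) - others)
        if node not in sub or start not in sub or not nx.has_path(sub, start, node):
            raise GoalAssignmentError(
                f"goal {k} unreachable without crossing another goal"
            )
    return TaskNetwork(graph=skeleton, start=start, goals=goals, cluster_of=cluster_of)


def generate_task_network(
    rng: np.random.Generator,
    n_clusters: int = 3,
    n_per_cluster: int = 20,
    edge_prob: float = DEFAULT_EDGE_PROB,
    n_goals: int = N_GOALS,
    goal_clusters: str = "spread",
    max_retries: int = 1000,
) -> TaskNetwork:
    """Generate a complete task network, retrying until goal assignment succeeds."""
    for _ in range(max_retries):
        skeleton = build_multi_cluster_network(n_clusters, n_per_cluster, edge_prob, rng)
        try:
            return assign_start_and_goals(skeleton, rng, n_goals=n_goals, goal_clusters=goal_clusters)
        except GoalAssignmentError:
            continue
    raise NetworkGenerationError(
        f"no valid goal assignment in {max_retries} network draws"
    )


def chain_network(
    n_nodes: int, goal_distances: "list[int] | None" = None
) -> TaskNetwork:
    """A path graph ``0 — 1 — ... — n-1`` with start at node 0.

    By default every node at distance 1..min(6, n-1) is a goal, following
    the distance rule; ``goal_distances`` restricts the goal set (e.g.
    ``[2]`` marks only the far end of a 3-node chain, reward 4).
    """
    if n_nodes < 2:
        raise ValueError("chain needs at least 2 nodes")
    if goal_distances is None:
        goal_distances = list(range(1, min(N_GOALS, n_nodes - 1) + 1))
    g = nx.path_graph(n_nodes)
    goals = {int(k): int(k) for k in goal_distances}
    return TaskNetwork(graph=g, start=0, goals=goals)


# ---------------------------------------------------------------------
# persistence


def save_network(net: TaskNetwork, basepath: "str | Path") -> tuple[Path, Path]:
    """Write ``<basepath>.edges`` (one "u v" per line) and ``<basepath>.json``.

    The JSON sidecar carries start, goals, rewards and cluster membership;
    distances are recomputed on load.
    """
    basepath = Path(basepath)
    edge_path = basepath.with_suffix(".edges")
    meta_path = basepath.with_suffix(".json")
    lines = [f"{u} {v}" for u, v in sorted(map(sorted, net.graph.edges))]
    edge_path.write_text("\n".join(lines) + "\n")
    meta = {
        "start": net.start,
        "goals": {str(k): v for k, v in net.goals.items()},
        "rewards": {str(k): r for k, r in net.rewards.items()},
        "cluster_of": {str(v): c for v, c in net.cluster_of.items()},
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return edge_path, meta_path


def load_network(basepath: "str | Path") -> TaskNetwork:
    """Load a network written by :func:`save_network`, re-validating invariants."""
    basepath = Path(basepath)
    g = nx.Graph()
    for lineno, line in enumerate(basepath.with_suffix(".edges").read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise NetworkValidationError(f"malformed edge on line {lineno}: {line!r}")
        u, v = int(parts[0]), int(parts[1])
        if u == v:
            raise NetworkValidationError(f"self-loop on line {lineno}: {line!r}")
        if g.has_edge(u, v):
            raise NetworkValidationError(f"duplicate edge on line {lineno}: {line!r}")
        g.add_edge(u, v)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    goals = {int(k): int(v) for k, v in meta["goals"].items()}
    for k, r in meta.get("rewards", {}).items():
        if int(r) != int(k) ** 2:
            raise NetworkValidationError(
                f"reward of goal {k} is {r}, must be {int(k) ** 2}"
            )
    cluster_of = {int(v): int(c) for v, c in meta.get("cluster_of", {}).items()}
    return TaskNetwork(graph=g, start=int(meta["start"]), goals=goals, cluster_of=cluster_of)
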