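# Methods

This note documents the model implemented by `teachcce`, the choices
made where the design was genuinely open, and what the synthetic task
generator does and does not capture.

## The task: a multi-goal exploration network

A technique is modelled as an undirected simple graph. Nodes are
states, edges are actions (traversable in both directions), one node is
the start of every round, and six nodes are absorbing goals. Goal *k*
lies at shortest-path distance *k* from the start (k = 1..6) and pays
reward *k*². Squaring the distance widens the utility gap between near
and far goals, which both speeds learning and makes the "ratchet"
worthwhile. A round is one episode: the agent moves from the start
until it enters *any* goal (collecting that goal's reward) or exhausts
the step cap of `max_steps = 1000` transitions (reward 0, bookkept as
"goal 0").

### Generator

`generate_task_network` draws three Erdős–Rényi clusters
G(20, p) (each redrawn until connected), chains them linearly with a
single bridge edge between uniformly chosen endpoints of adjacent
clusters, samples the start uniformly from the first cluster, and
samples goal *k* uniformly among the nodes at distance exactly *k*.

Two generator rules are our own resolution of under-determined design
space, fixed once against the published desk-scale observations
(single-round difficulty profile and fixed-budget baseline) and not
revisited:

- **Edge probability `edge_prob = 0.35`.** The cluster density is a
  free parameter of the ensemble. 0.35 keeps 20-node clusters
  connected with few retries, leaves distance-6 nodes attainable
  behind the second bridge, and yields the canonical difficulty
  profile: ~95% of naive single-round walkers end at goal 1 or 2, and
  essentially none cross both bottlenecks.
- **Outward goal placement (`goal_clusters="spread"`).** Goal *k* is
  confined to cluster ⌊(k−1)·C/6⌋ — goals 1–2 in the first cluster,
  3–4 in the second, 5–6 in the third. Unconstrained placement often
  drops distance-3..6 nodes into the first clusters, in front of the
  bottlenecks, which flattens the difficulty gradient the task is
  built around. `goal_clusters="any"` restores unconstrained
  placement.

One validity rule is structural rather than calibrational: because
goals absorb (a round ends at the first goal entered), an assignment in
which some goal cannot be reached without first crossing another goal
would make that goal literally unattainable in any round. Such
assignments are rejected and the network is regenerated.

Single-cluster variants (`n_clusters=1`) and arbitrary saved networks
(plain-text edge list + JSON sidecar with start/goals/rewards/clusters)
are supported; path-graph fixtures (`chain_network`) give exactly
solvable cases for tests.

## The learner: two-table conditioned reinforcement

Each agent holds a stimulus value v(s) per state and a state–action
value w(s, a) per directed edge, both zero at birth. After moving
s → s′ and collecting utility u (the goal reward if s′ is a goal, else
0), both tables move toward u + v(s′):

    w(s,s′) += α_w (u + v(s′) − w(s,s′))
    v(s)    += α_v (u + v(s′) − v(s))

Updates are applied online at every step — required for the
one-state-per-traversal backward creep of value that the teaching
mechanism exploits. Goal states are terminal, so their stimulus values
are never updated and stay 0. Actions are sampled by SoftMax,
P(a) ∝ exp(β·w(s,a)); a zero-knowledge agent therefore walks uniformly
at random.

Parameters (with the canonical values used throughout):

| parameter | default | meaning |
|---|---|---|
| `alpha` (α_w) | 0.9 | learning rate of the state–action table |
| `alpha_v` | = alpha | learning rate of the stimulus-value table; exposed separately because two-rate variants are common in this model family |
| `beta` (β) | 0.5 | SoftMax inverse temperature (0 = uniform; ∞ = greedy) |
| `max_steps` | 1000 | per-round step cap; hitting it scores 0 |

## Teaching, generations, and the CCE criterion

A generation is a single fresh (zero-memory) agent with a budget of R
rounds. Generation 1 explores individually for all R rounds. From
generation 2 on, the first T rounds (0 ≤ T < R) are *teaching rounds*:
the student is forced step by step along the taught path, with value
updates applied exactly as in individual learning, its own policy never
consulted, and no randomness involved. The remaining R − T rounds are
ordinary SoftMax exploration. The final (R-th) round's trajectory —
sampled under SoftMax, hence "quasi-optimal", detours included — is the
next generation's taught path.

Design points fixed here:

- A teacher whose final round failed (step cap) still teaches that
  truncated, goalless path as-is; all its updates carry zero utility.
  The `teach_last_success` flag substitutes the teacher's most recent
  successful round instead (off by default, since the base rule is the
  plain reading of "teach the final round").
- The same path object is replayed for all T rounds; no re-extraction
  between rounds. Teaching rounds are not subject to a separate step
  cap (the path respects it by construction).
- The *greedy teacher* variant (`teacher_mode="greedy"`) derives the
  taught path by an argmax walk over the teacher's end-of-life w table
  (β → ∞ limit), ties broken toward the smaller node id, cut at the
  step cap if it cycles.
- Teaching fractions given as percentages convert by
  T = ⌊fraction·R/100 + 0.5⌋ (round half up), so 10–90% of R=10 gives
  T = 1..9.

**CCE criterion.** For each teaching fraction, the mean final-round
reward per generation (across lineages, failures counting 0) is
compared with the *fixed-budget baseline*: the mean round-R reward of
independent agents who only ever learn individually. A generation mean
strictly above the baseline is CCE. The complementary reference is the
*immortal agent*: one never-resetting individual learner, i.e.
transmission with zero information loss, recorded every R rounds.

## Randomness and reproducibility

All public entry points take either a `numpy.random.Generator` or a
master seed. Batch drivers derive independent streams per
(fraction, lineage) via `SeedSequence(seed, spawn_key=...)`, so adding
lineages or fractions never perturbs existing ones. The compiled inner
loops draw from numba's MT19937, reseeded from the caller's generator
per round, making every simulation a pure function of (config, network,
seed). SoftMax sampling is max-shifted for numerical safety; ties in
the greedy walk break toward the smaller node id.

## Scale of the shipped experiments

The published grids (1000 lineages × 7000 generations per fraction, at
four budgets) are cluster-scale. The test suite and example scripts
run the same designs at desk scale — typically 20–50 lineages and
25–500 generations, with R = 500 standing in for the largest budget —
which is enough for the direction of every reported effect (stagnation
below 40% teaching at R = 10, CCE and a positive fraction/reward rank
correlation above it, and the negative correlation at large R). Full
scale remains reachable through configuration.

## What the generator does and does not emulate

Passing tests show that the *mechanism* — backward-chaining learning,
forced-replay teaching, the fidelity/innovation trade-off — behaves as
described on networks drawn from this ensemble. They do not certify
any single network instance, and several published point values are
properties of the original study's one fixed (not machine-readable)
instance. Ensemble averages reproduce the single-round difficulty
profile (~95% vs 96% printed) and the fixed-budget baseline (~3.0–3.2
vs 3.43 printed, within its stated ±0.6 instance spread). Two printed
values resist ensemble reproduction:

- "0% of 1000 single-round walkers reach goals 5–6" — valid instances
  leak ~0.1–0.9% of single-round walks past the bottlenecks, so a
  literal zero in 1000 is instance/sample luck.
- "~70% of agents end their round at goal 2 after >400 rounds" — a
  knife-edge property of the original instance's bridge-crossing rate.
  Instances here are bimodal (locked near goal 2, or escaped to goals
  3–4 by round 400), and the ensemble share is ~25–40%.

Other known limitations: one teacher and one student per generation
(no population structure, no oblique/horizontal transmission), a
finite goal set (cumulative optimisation rather than open-ended
evolution), undirected unweighted static networks, and no teaching
cost to the teacher.
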