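"""What can reinforcement learning alone achieve, given time?

Runs 300 agents through 600 rounds of individual learning on the
standard network and prints the goal profile at a few checkpoints,
plus the fixed-budget reference line (mean round-10 reward of fresh
agents) that later defines cumulative cultural evolution.  Values creep
backward one state per traversal, so agents first consolidate the
nearby goals; crossing a bridge to the richer clusters is slow and
often never happens within an individual's horizon.
"""

import collections

import numpy as np

from teachcce import AgentMemory, generate_task_network, run_individual_baseline, run_individual_round

net = generate_task_network(np.random.default_rng(12345))
rng = np.random.default_rng(1)

checkpoints = {1: None, 50: None, 200: None, 410: None, 600: None}
profiles = {r: collections.Counter() for r in checkpoints}
n_agents = 300
for _ in range(n_agents):
    memory = AgentMemory.zeros(net)
    for r in range(1, 601):
        traj = run_individual_round(memory, rng)
        if r in profiles:
            profiles[r][traj.terminal_goal] += 1

print(f"goal profile of {n_agents} individually learning agents (percent):")
print("round   " + "".join(f"g{g:<6}" for g in range(7)))
for r, counter in profiles.items():
    shares = "".join(f"{100 * counter[g] / n_agents:<7.1f}" for g in range(7))
    print(f"{r:<8}{shares}")

baseline = run_individual_baseline(net, R=10, n_agents=1000, rng=rng)
print(f"\nfixed-budget reference line (mean round-10 reward, 1000 agents): "
      f"{baseline.mean:.2f} (sd {baseline.sd:.2f})")
print("a lineage whose generation mean exceeds this line exhibits CCE.")
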