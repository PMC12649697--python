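"""Node centrality and bridge centrality.

Three indices per node: strength (sum of absolute edge weights),
one-step expected influence (signed sum, EI), and bridge expected
influence (signed sum over edges crossing the symptom/quality-of-life
community boundary, BEI).  High-EI nodes spread activation through the
network; high-BEI nodes connect the two instruments.
"""

from psynetkit import (
    centrality_table,
    default_scenario,
    rank_report,
    sample_dataset,
    select_network,
)

data = sample_dataset(default_scenario(n_per_group=766, seed=7))
net = select_network(data.group_scores(True))  # exposed group

table = centrality_table(
    net.weights, net.communities, net.node_names, net.predictability
)

print("top 5 by expected influence:")
print(rank_report(table, index="ei", top_k=5)
      [["node", "community", "strength", "ei", "ei_z"]].round(3)
      .to_string(index=False))

print("\ntop 5 bridge nodes (cross-community influence):")
print(rank_report(table, index="bei", top_k=5)
      [["node", "community", "bei", "bei_z"]].round(3)
      .to_string(index=False))
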