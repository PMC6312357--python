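"""Simulate a replicated Y2H screen and compute the network statistics.

Each of the 8 orientation-replicates per pair (4 for self pairs) is a
noisy read-out of a latent true edge; an edge is called at >= 3 positive
replicates.  The summary mirrors the headline counts of an interactome
screen: self-associations, heteromeric interactions and the nodes
involved, plus the set of ECCs preferring a partner over themselves.
"""

from ecckit import (
    build_network,
    call_interactions,
    higher_affinity_partners,
    network_summary,
)
from ecckit.simulate import PanelSpec, Y2HModel, gen_ecc_panel, gen_y2h_screen

records, truths = gen_ecc_panel(PanelSpec(seed=21))
groups = {t["id"]: t["group"] for t in truths}
matings, true_edges = gen_y2h_screen(groups, Y2HModel(seed=21))
print(f"{len(matings)} matings over {len(groups)} ECCs "
      f"({len(true_edges)} latent true edges)")

edges = call_interactions(matings, min_support=3)
net = build_network(sorted(groups), edges)
s = network_summary(net)
print(f"called edges: {s.n_self} homomeric, {s.n_hetero} heteromeric "
      f"involving {s.n_nodes_with_hetero} ECCs")
prefer = higher_affinity_partners(net)
print(f"{len(prefer)} ECCs show higher affinity toward a partner "
      f"other than themselves")
called = {(a, b) for a, b, _ in edges}
print(f"recovered {len(called & true_edges)}/{len(true_edges)} true edges, "
      f"{len(called - true_edges)} spurious")
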