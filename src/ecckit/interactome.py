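"""Yeast-two-hybrid interaction calling and network statistics.

Matings are scored for growth on media lacking His and adenine; each
bait-prey combination is mated four times, and both orientations (A as
bait vs B as prey and the reverse) are screened, giving up to 8
supporting replicates per unordered pair (4 for a self pair).  A pair is
called an interaction when its total positive replicates reach
``min_support`` (default 3) — strict enough to demand reproduction,
tolerant to a single replicate dropping out.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import math
import networkx as nx
import pandas as pd
from scipy import stats

from ecckit.seqio import PhenotypeRecord

#: minimum positive replicates (summed over both orientations) to call an edge
MIN_SUPPORT = 3
#: default response category counted as "active" (necrosis or stronger)
THETA_RESP = {"At": 4, "Nb": 2, "Ls": 2}


@dataclass(frozen=True)
class MatingResult:
    bait: str
    prey: str
    replicate: int
    growth: bool

    def __post_init__(self):
        if not 1 <= self.replicate <= 4:
            raise ValueError(f"replicate {self.replicate} outside 1..4")


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_self: int
    n_hetero: int
    n_nodes_with_hetero: int
    degree: dict


def read_matings(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"bait", "prey", "replicate", "growth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mating table missing columns: {sorted(missing)}")
    return [
        MatingResult(
            bait=str(r.bait), prey=str(r.prey), replicate=int(r.replicate),
            growth=bool(r.growth),
        )
        for r in df.itertuples()
    ]


def call_interactions(matings, min_support: int = MIN_SUPPORT):
    """Retain unordered pairs whose positive replicates across both
    orientations reach ``min_support``; returns [(a, b, support), ...]."""
    seen = set()
    support = defaultdict(int)
    for m in matings:
        key = (m.bait, m.prey, m.replicate)
        if key in seen:
            raise ValueError(f"duplicate mating {key}")
        seen.add(key)
        pair = tuple(sorted((m.bait, m.prey)))
        if m.growth:
            support[pair] += 1
    return [
        (a, b, s) for (a, b), s in sorted(support.items()) if s >= min_support
    ]


def build_network(nodes, edges) -> nx.Graph:
    """Undirected interaction graph (self loops allowed); edges carry
    ``support``."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, s in edges:
        if a not in g or b not in g:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
        g.add_edge(a, b, support=s)
    return g


def network_summary(net: nx.Graph) -> NetworkSummary:
    self_edges = [(u, v) for u, v in net.edges if u == v]
    hetero_edges = [(u, v) for u, v in net.edges if u != v]
    with_hetero = set()
    for u, v in hetero_edges:
        with_hetero.update((u, v))
    degree = {}
    for node in net.nodes:
        partners = sum(1 for nb in net.neighbors(node) if nb != node)
        degree[node] = partners + (1 if net.has_edge(node, node) else 0)
    return NetworkSummary(
        n_nodes=net.number_of_nodes(),
        n_self=len(self_edges),
        n_hetero=len(hetero_edges),
        n_nodes_with_hetero=len(with_hetero),
        degree=degree,
    )


def degree_phenotype_correlation(net: nx.Graph, phenotypes, species: str = "At"):
    """Pearson r between interaction count (self edge counts 1) and the
    ordinal response category, with a two-sided t-based p value."""
    cats = {p.ecc_id: p.category for p in phenotypes if p.species == species}
    missing = [n for n in net.nodes if n not in cats]
    if missing:
        raise ValueError(f"nodes without {species} phenotype: {sorted(missing)[:5]}")
    summary = network_summary(net)
    nodes = sorted(net.nodes)
    x = [summary.degree[n] for n in nodes]
    y = [cats[n] for n in nodes]
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise ValueError("correlation undefined: zero variance in degree or phenotype")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_pair_interaction_test(net: nx.Graph, groups: dict, pair):
    """Fisher's exact test comparing edge frequency between two dyad classes.

    ``pair`` is ((focal_groups_1, focal_groups_2), (ref_groups_1,
    ref_groups_2)); every unordered heteromeric dyad of the network's nodes
    is assigned to the focal class, the reference class, or neither, and a
    2x2 table (edge present/absent x focal/reference) is tested two-sided.
    """
    (f1, f2), (r1, r2) = pair
    f1, f2, r1, r2 = set(f1), set(f2), set(r1), set(r2)
    uncovered = [n for n in net.nodes if n not in groups]
    if uncovered:
        raise ValueError(f"nodes without group assignment: {sorted(uncovered)[:5]}")
    nodes = sorted(net.nodes)

    def dyad_class(a, b):
        ga, gb = groups[a], groups[b]
        if (ga in f1 and gb in f2) or (ga in f2 and gb in f1):
            return "focal"
        if (ga in r1 and gb in r2) or (ga in r2 and gb in r1):
            return "reference"
        return None

    table = {"focal": [0, 0], "reference": [0, 0]}  # [present, absent]
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            cls = dyad_class(a, b)
            if cls is None:
                continue
            table[cls][0 if net.has_edge(a, b) else 1] += 1
    if sum(table["focal"]) == 0 or sum(table["reference"]) == 0:
        raise ValueError("degenerate table: one dyad class is empty")
    contingency = [table["focal"], table["reference"]]
    odds, p = stats.fisher_exact(contingency, alternative="two-sided")
    if math.isnan(odds):  # 0/0 odds ratio on degenerate margins
        odds = 1.0
    return float(odds), float(p)


def higher_affinity_partners(net: nx.Graph):
    """Nodes whose best heteromeric edge support strictly exceeds their
    self-edge support (0 when no self edge): the "prefers a partner other
    than itself" set."""
    out = set()
    for node in net.nodes:
        self_support = (
            net.edges[node, node]["support"] if net.has_edge(node, node) else 0
        )
        hetero = [
            net.edges[node, nb]["support"] for nb in net.neighbors(node) if nb != node
        ]
        if hetero and max(hetero) > self_support:
            out.add(node)
    return out


def cross_species_persistence(phenotypes, theta_resp: dict | None = None):
    """Per-ECC count of species with an active response, plus per-species
    and per-combination aggregate tables.

    ``theta_resp`` maps species to the minimum category counted as active
    (default: necrosis-or-stronger per species scale).
    """
    theta = dict(THETA_RESP)
    if theta_resp:
        theta.update(theta_resp)
    active = defaultdict(set)
    scored = set()
    for p in phenotypes:
        scored.add(p.ecc_id)
        if p.category >= theta[p.species]:
            active[p.ecc_id].add(p.species)
    persistence = {ecc: len(active.get(ecc, ())) for ecc in scored}
    per_species = defaultdict(int)
    per_combo = defaultdict(int)
    for ecc in scored:
        for sp in active.get(ecc, ()):
            per_species[sp] += 1
        per_combo[tuple(sorted(active.get(ecc, ())))] += 1
    return persistence, dict(per_species), dict(per_combo)


def network_to_edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        {"a": u, "b": v, "support": data.get("support", 0)}
        for u, v, data in net.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["a", "b", "support"])


def write_graphml(net: nx.Graph, path) -> None:
    """Cytoscape-compatible GraphML export."""
    nx.write_graphml(net, path)
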