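"""Structure-word encoding, distances, NJ trees and group classification.

ECCs are compared not on raw residues but on "structure words": contiguous
k-tuples of per-residue symbols (hydropathy class, heptad letter, helix
state).  Words touching the a/d coiled-coil interface are up-weighted, so
two sequences sharing heptad architecture look close even when their
residues have diverged.  The resulting weighted-Jaccard distance feeds a
neighbour-joining tree; an independent rule cascade assigns each
annotation to one of the architectural groups:

* A — RPW8-like (CC_R) signature; the putative "actor/helper" receptors;
* B — canonical four-helix ECC without EDVID, usually N-terminally acylated;
* C — four helices plus the EDVID motif in helix H2a;
* D — C plus a conserved 10-residue polar stretch immediately before EDVID;
* E — no recognisable coiled-coil (the CC-NB truncation homologs).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

from ecckit.architecture import EccAnnotation, KYTE_DOOLITTLE
from ecckit.seqio import AlignedBlock, GAP

#: default threshold on identity to the CC_R consensus for a group A call
THETA_RPW8 = 0.7
#: default weight for structure words containing an a/d heptad symbol
W_AD = 2.0


@dataclass(frozen=True)
class StructWordProfile:
    """Per-residue (hydro, heptad, helix) symbol tuples plus word length k."""

    symbols: tuple  # tuple of (hydro_class, heptad, helix_class)
    k: int = 3

    def words(self) -> Counter:
        """Multiset of contiguous k-tuples of symbols."""
        n = len(self.symbols)
        return Counter(
            tuple(self.symbols[i : i + self.k]) for i in range(n - self.k + 1)
        )


@dataclass(frozen=True)
class GroupAssignment:
    group: str  # A..E
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape disagrees with ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")


class Tree:
    """Unrooted tree over leaf ids, backed by a networkx graph.

    Internal nodes are integers, leaves are their id strings; edges carry a
    ``length`` attribute.  ``clamped`` records whether any negative NJ
    branch estimate was clamped to zero.
    """

    def __init__(self, graph: nx.Graph, clamped: bool = False):
        self.graph = graph
        self.clamped = clamped

    @property
    def leaves(self):
        return frozenset(n for n in self.graph.nodes if isinstance(n, str))

    def bipartitions(self):
        """Non-trivial leaf bipartitions, each as the frozenset not larger
        than its complement (ties broken by sorted order)."""
        leaves = self.leaves
        splits = set()
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = frozenset(n for n in nx.node_connected_component(g, u) if isinstance(n, str))
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            other = frozenset(leaves - side)
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def to_newick(self) -> str:
        g = self.graph
        root = next(n for n in g.nodes if not isinstance(n, str))

        def fmt(node, parent):
            children = [n for n in g.neighbors(node) if n != parent]
            if not children:
                return node
            inner = ",".join(
                f"{fmt(c, node)}:{g.edges[node, c]['length']:.6g}" for c in children
            )
            return f"({inner})"

        return fmt(root, None) + ";"


def encode_structwords(annotation: EccAnnotation, k: int = 3) -> StructWordProfile:
    """Per-residue (hydro, heptad, helix) symbols from an annotation.

    hydro: 'H' where the Kyte-Doolittle value is positive, else 'P';
    heptad: the register letter (a-g) or '.'; helix: 'H' inside a predicted
    helix span, 'C' otherwise.
    """
    seq = annotation.record.residues
    register = annotation.heptad_register or "." * len(seq)
    in_helix = np.zeros(len(seq), dtype=bool)
    for h in annotation.helices:
        in_helix[h.start - 1 : h.end] = True
    symbols = tuple(
        (
            "H" if KYTE_DOOLITTLE[aa] > 0 else "P",
            register[i],
            "H" if in_helix[i] else "C",
        )
        for i, aa in enumerate(seq)
    )
    return StructWordProfile(symbols=symbols, k=k)


def _word_weight(word, w_ad: float) -> float:
    return w_ad if any(sym[1] in ("a", "d") for sym in word) else 1.0


def structword_distance(
    p1: StructWordProfile, p2: StructWordProfile, w_ad: float = W_AD
) -> float:
    """1 - weighted Jaccard similarity of the two word multisets.

    Words containing an a/d heptad symbol carry weight ``w_ad``; empty
    profiles are maximally distant (1.0).
    """
    if p1.k != p2.k:
        raise ValueError(f"profiles have different k: {p1.k} vs {p2.k}")
    w1, w2 = p1.words(), p2.words()
    if not w1 or not w2:
        return 1.0
    num = den = 0.0
    for word in set(w1) | set(w2):
        w = _word_weight(word, w_ad)
        c1, c2 = w1.get(word, 0), w2.get(word, 0)
        num += w * min(c1, c2)
        den += w * max(c1, c2)
    return 1.0 - (num / den if den else 1.0)


def structword_distance_matrix(profiles: dict, w_ad: float = W_AD) -> DistanceMatrix:
    ids = tuple(profiles)
    n = len(ids)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = structword_distance(profiles[ids[i]], profiles[ids[j]], w_ad=w_ad)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def build_nj_tree(d: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei neighbour joining.

    On an additive (tree-realisable) matrix this recovers the generating
    topology and branch lengths exactly; negative branch-length estimates
    are clamped to zero and flagged on the returned tree.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    # active nodes: leaf names initially, internal int ids as we join
    nodes = list(d.ids)
    dist = {(a, b): d.values[i, j] for i, a in enumerate(d.ids) for j, b in enumerate(d.ids)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    next_internal = 0
    clamped = False

    def get(a, b):
        return 0.0 if a == b else dist[(a, b)]

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(get(a, b) for b in nodes) for a in nodes}
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        u = next_internal
        next_internal += 1
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        g.add_edge(a, u, length=la)
        g.add_edge(b, u, length=lb)
        for c in nodes:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - dab)
            dist[(u, c)] = dist[(c, u)] = max(duc, 0.0)
        nodes = [c for c in nodes if c not in (a, b)] + [u]

    # final star join of the last three nodes
    a, b, c = nodes
    u = next_internal
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    if min(la, lb, lc) < 0:
        clamped = True
    g.add_edge(a, u, length=max(la, 0.0))
    g.add_edge(b, u, length=max(lb, 0.0))
    g.add_edge(c, u, length=max(lc, 0.0))
    return Tree(g, clamped=clamped)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if t1.leaves != t2.leaves:
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def classify_group(
    annotation: EccAnnotation,
    rpw8_profile: str | None = None,
    theta_rpw8: float = THETA_RPW8,
) -> GroupAssignment:
    """Decision cascade over the annotation's features.

    (1) no helix/heptad evidence -> E; (2) N-terminal identity to the
    CC_R/RPW8 consensus above ``theta_rpw8`` -> A; (3) EDVID + polar
    stretch -> D; (4) EDVID -> C; (5) otherwise -> B.  The evidence map
    records the outcome of every rule regardless of which one fired.
    """
    edvid = annotation.motif("EDVID")
    polar = annotation.motif("polar_stretch")
    cc_detected = bool(annotation.helices) and any(
        ch in "ad" for ch in annotation.heptad_register
    )
    rpw8_score = 0.0
    if rpw8_profile:
        rpw8_score = _consensus_identity(annotation.record.residues, rpw8_profile)
    evidence = {
        "cc_detected": cc_detected,
        "rpw8_signature": rpw8_score >= theta_rpw8,
        "edvid_present": edvid is not None,
        "polar_stretch": polar is not None,
        "acylation": annotation.myristoylation and annotation.palmitoylation,
        "rpw8_score": rpw8_score,
    }
    if not cc_detected:
        group = "E"
    elif evidence["rpw8_signature"]:
        group = "A"
    elif edvid is not None and polar is not None:
        group = "D"
    elif edvid is not None:
        group = "C"
    else:
        group = "B"
    assignment = GroupAssignment(group=group, evidence=evidence)
    annotation.group = assignment
    return assignment


def _consensus_identity(seq: str, consensus: str) -> float:
    """Best sliding-window fractional identity of ``consensus`` against the
    N-terminal region of ``seq`` (search window: first 2x consensus length)."""
    L = len(consensus)
    if L == 0 or len(seq) < L:
        return 0.0
    limit = min(len(seq) - L, L)
    best = 0.0
    for off in range(limit + 1):
        ident = sum(1 for a, b in zip(seq[off : off + L], consensus) if a == b) / L
        best = max(best, ident)
    return best


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pairwise_identity_similarity(row_a: str, row_b: str, matrix=None):
    """Percent identity and similarity between two aligned rows.

    Columns where both rows are gaps are excluded from the denominator;
    similarity additionally counts columns with a positive substitution
    score (BLOSUM62 by default).  Gap-vs-residue columns count as neither
    identical nor similar.
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"aligned rows differ in length: {len(row_a)} vs {len(row_b)}")
    matrix = matrix if matrix is not None else _BLOSUM62
    n = ident = simil = 0
    for a, b in zip(row_a, row_b):
        if a == GAP and b == GAP:
            continue
        n += 1
        if a == GAP or b == GAP:
            continue
        if a == b:
            ident += 1
            simil += 1
        elif matrix[a, b] > 0:
            simil += 1
    if n == 0:
        raise ValueError("alignment has no scored columns")
    return (100.0 * ident / n, 100.0 * simil / n)


def discriminative_conservation(block: AlignedBlock, frequent_ids, rare_ids):
    """Columns conserved in, and unique to, the ``frequent`` partition.

    A column qualifies when every frequent row carries the same residue
    (no gaps) and no rare row carries that residue there.  Returned as
    (alignment column, residue, ungapped position in the first frequent
    row), all 1-based.
    """
    frequent_ids, rare_ids = set(frequent_ids), set(rare_ids)
    if not frequent_ids or not rare_ids:
        raise ValueError("both partitions must be non-empty")
    if frequent_ids & rare_ids:
        raise ValueError("frequent and rare partitions overlap")
    missing = (frequent_ids | rare_ids) - set(block.ids)
    if missing:
        raise ValueError(f"ids not in alignment: {sorted(missing)}")
    freq_rows = [block.rows[block.ids.index(i)] for i in sorted(frequent_ids)]
    rare_rows = [block.rows[block.ids.index(i)] for i in sorted(rare_ids)]
    first = freq_rows[0]
    hits = []
    ungapped = 0
    for col in range(block.n_columns):
        if first[col] != GAP:
            ungapped += 1
        column = [r[col] for r in freq_rows]
        res = column[0]
        if res == GAP or any(c != res for c in column):
            continue
        if any(r[col] == res for r in rare_rows):
            continue
        hits.append((col + 1, res, ungapped))
    return hits
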