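import itertools
import random
from collections import Counter

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecckit.architecture import annotate_ecc
from ecckit.classify import (
    DistanceMatrix,
    StructWordProfile,
    Tree,
    build_nj_tree,
    classify_group,
    discriminative_conservation,
    encode_structwords,
    pairwise_identity_similarity,
    rf_distance,
    structword_distance,
)
from ecckit.seqio import AlignedBlock, SequenceRecord
from ecckit.simulate import RPW8_SIGNATURE, PanelSpec, gen_ecc_panel


def _profile(symbols, k=3):
    return StructWordProfile(symbols=tuple(symbols), k=k)


def _random_profile(rng, n, k=3):
    syms = [
        (rng.choice("HP"), rng.choice("abcdefg."), rng.choice("HC"))
        for _ in range(n)
    ]
    return _profile(syms, k)


class TestStructWords:
    def test_encoding_classes(self):
        rec = SequenceRecord(id="x", residues="LLLLLLLPPP")
        ann = annotate_ecc(rec, tracks=[True] * 7 + [False] * 3)
        prof = encode_structwords(ann)
        assert len(prof.symbols) == 10
        assert all(s == ("H", r, "H") for s, r in zip(prof.symbols[:7], ann.heptad_register))
        assert prof.symbols[7:] == (("P", ".", "C"),) * 3

    def test_distance_identity_and_disjoint(self):
        rng = random.Random(0)
        p = _random_profile(rng, 20)
        assert structword_distance(p, p) == 0.0
        a = _profile([("H", "a", "H")] * 10)
        b = _profile([("P", ".", "C")] * 10)
        assert structword_distance(a, b) == 1.0

    def test_distance_matches_brute_force_weighted_jaccard(self):
        rng = random.Random(42)
        for _ in range(20):
            p1 = _random_profile(rng, rng.randint(5, 30))
            p2 = _random_profile(rng, rng.randint(5, 30))
            w1 = Counter(tuple(p1.symbols[i : i + 3]) for i in range(len(p1.symbols) - 2))
            w2 = Counter(tuple(p2.symbols[i : i + 3]) for i in range(len(p2.symbols) - 2))
            num = den = 0.0
            for word in set(w1) | set(w2):
                w = 2.0 if any(s[1] in "ad" for s in word) else 1.0
                num += w * min(w1[word], w2[word])
                den += w * max(w1[word], w2[word])
            expected = 1.0 - num / den
            assert structword_distance(p1, p2) == pytest.approx(expected)

    def test_pseudometric_properties_on_random_triples(self):
        rng = random.Random(7)
        for _ in range(30):
            p1, p2, p3 = (_random_profile(rng, rng.randint(6, 25)) for _ in range(3))
            d12 = structword_distance(p1, p2)
            d21 = structword_distance(p2, p1)
            assert d12 == pytest.approx(d21)
            assert 0.0 <= d12 <= 1.0
            d13 = structword_distance(p1, p3)
            d23 = structword_distance(p2, p3)
            assert d12 <= d13 + d23 + 1e-12


def _random_additive_tree(rng, n_leaves):
    """Random binary tree as (networkx graph, leaf names); edge lengths > 0."""
    import networkx as nx

    leaves = [f"t{i}" for i in range(n_leaves)]
    g = nx.Graph()
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 2:
        a, b = rng.sample(nodes, 2)
        u = nxt
        nxt += 1
        g.add_edge(a, u, length=rng.uniform(0.5, 3.0))
        g.add_edge(b, u, length=rng.uniform(0.5, 3.0))
        nodes = [x for x in nodes if x not in (a, b)] + [u]
    a, b = nodes
    g.add_edge(a, b, length=rng.uniform(0.5, 3.0))
    return g, leaves


def _path_distance_matrix(g, leaves):
    import networkx as nx

    n = len(leaves)
    values = np.zeros((n, n))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = dist[leaves[i]][leaves[j]]
    return DistanceMatrix(ids=tuple(leaves), values=values)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ids=("a", "b", "c"),
            values=np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = build_nj_tree(dm)
        lengths = {
            leaf: tree.graph.edges[leaf, nb]["length"]
            for leaf in ("a", "b", "c")
            for nb in tree.graph.neighbors(leaf)
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_recovers_additive_topologies(self):
        rng = random.Random(5)
        for _ in range(15):
            n = rng.randint(5, 12)
            g, leaves = _random_additive_tree(rng, n)
            dm = _path_distance_matrix(g, leaves)
            nj = build_nj_tree(dm)
            truth = Tree(g)
            assert rf_distance(nj, truth) == 0
            assert not nj.clamped

    def test_duplicate_taxa_give_zero_length_cherry(self):
        values = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], dtype=float
        )
        tree = build_nj_tree(DistanceMatrix(ids=("a", "b", "c", "d"), values=values))
        parent_a = next(tree.graph.neighbors("a"))
        assert tree.graph.edges["a", parent_a]["length"] == pytest.approx(0.0)
        assert parent_a in tree.graph.neighbors("b")

    def test_rejects_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(ids=("a", "b"), values=np.zeros((2, 2))))


class TestRobinsonFoulds:
    def _from_newick(self, newick):
        """Parse a newick string into an ecckit Tree (test-local helper)."""
        import networkx as nx

        d = dendropy.Tree.get(data=newick, schema="newick")
        g = nx.Graph()
        counter = itertools.count()
        names = {}

        def name(node):
            if node not in names:
                names[node] = node.taxon.label if node.taxon else next(counter)
            return names[node]

        for edge in d.preorder_edge_iter():
            if edge.head_node and edge.tail_node:
                g.add_edge(name(edge.tail_node), name(edge.head_node),
                           length=edge.length or 1.0)
        return Tree(g)

    def test_identical_trees(self):
        t = self._from_newick("((a,b),(c,d),e);")
        assert rf_distance(t, t) == 0

    def test_distinct_quartets(self):
        t1 = self._from_newick("((a,b),(c,d));")
        t2 = self._from_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_matches_dendropy_on_random_trees(self):
        rng = random.Random(3)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        for _ in range(10):
            d1 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, taxon_namespace=taxa, num_extant_tips=8,
                rng=rng,
            )
            d2 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, taxon_namespace=taxa, num_extant_tips=8,
                rng=rng,
            )
            for d in (d1, d2):
                d.is_rooted = False
                d.update_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            t1 = self._from_newick(d1.as_string(schema="newick"))
            t2 = self._from_newick(d2.as_string(schema="newick"))
            assert rf_distance(t1, t2) == expected

    def test_leaf_set_mismatch(self):
        t1 = self._from_newick("((a,b),(c,d));")
        t2 = self._from_newick("((a,b),(c,e));")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestGroupClassification:
    @pytest.mark.parametrize("group", list("ABCDE"))
    def test_noise_free_fixtures_classified_exactly(self, group):
        counts = {g: (8 if g == group else 0) for g in "ABCDE"}
        records, truths = gen_ecc_panel(PanelSpec(seed=23, counts=counts))
        for r in records:
            ann = annotate_ecc(r)
            assignment = classify_group(ann, rpw8_profile=RPW8_SIGNATURE)
            assert assignment.group == group
            assert assignment.evidence["cc_detected"] == (group != "E")

    def test_evidence_map_consistency(self, group_d_fixture):
        _, _, ann = group_d_fixture
        g = classify_group(ann, rpw8_profile=RPW8_SIGNATURE)
        assert g.group == "D"
        assert g.evidence["edvid_present"] and g.evidence["polar_stretch"]
        assert not g.evidence["rpw8_signature"]


class TestIdentitySimilarity:
    def test_simple_identity(self):
        ident, simil = pairwise_identity_similarity("ACDE", "ACDF")
        assert ident == pytest.approx(75.0)
        assert simil >= ident

    def test_identical_rows(self):
        assert pairwise_identity_similarity("ACDE", "ACDE") == (100.0, 100.0)

    def test_dual_gap_columns_excluded(self):
        ident, _ = pairwise_identity_similarity("A-CD", "A-CE")
        assert ident == pytest.approx(200.0 / 3.0)

    def test_similarity_counts_positive_scores(self):
        # L/I score positive in BLOSUM62, L/D does not
        ident, simil = pairwise_identity_similarity("LL", "ID")
        assert (ident, simil) == (0.0, 50.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity_similarity("AC", "ACD")


class TestDiscriminativeConservation:
    def test_worked_example(self):
        block = AlignedBlock(
            ids=("f1", "f2", "r1", "r2"), rows=("ACD", "ACD", "GCD", "TCD")
        )
        hits = discriminative_conservation(block, {"f1", "f2"}, {"r1", "r2"})
        assert [(c, r) for c, r, _ in hits] == [(1, "A")]

    def test_identical_rows_everywhere_yield_nothing(self):
        block = AlignedBlock(ids=("f1", "r1"), rows=("ACD", "ACD"))
        assert discriminative_conservation(block, {"f1"}, {"r1"}) == []

    def test_matches_brute_force_on_random_alignments(self):
        rng = random.Random(9)
        for _ in range(25):
            ncol = rng.randint(4, 15)
            ids = tuple(f"s{i}" for i in range(6))
            rows = tuple(
                "".join(rng.choice("ACDG-") for _ in range(ncol)) for _ in ids
            )
            try:
                block = AlignedBlock(ids=ids, rows=rows)
            except ValueError:
                continue
            frequent, rare = set(ids[:3]), set(ids[3:])
            freq_rows, rare_rows = rows[:3], rows[3:]
            expected = []
            for col in range(ncol):
                vals = {r[col] for r in freq_rows}
                if len(vals) == 1 and "-" not in vals:
                    res = vals.pop()
                    if all(r[col] != res for r in rare_rows):
                        expected.append((col + 1, res))
            got = [(c, r) for c, r, _ in discriminative_conservation(block, frequent, rare)]
            assert got == expected

    def test_partition_validation(self):
        block = AlignedBlock(ids=("a", "b"), rows=("AC", "AC"))
        with pytest.raises(ValueError):
            discriminative_conservation(block, set(), {"b"})
        with pytest.raises(ValueError):
            discriminative_conservation(block, {"a"}, {"a"})
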