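"""Neighbor joining, rooting, and Fitch parsimony ancestral states."""

import dendropy
import numpy as np
import pytest

from _oracles import fitch_bruteforce_min
from conftest import make_alignment, random_rooted_tree
from cyp2bdiv.phylo import (
    fitch_ancestral,
    neighbor_joining,
    root_at_midpoint,
    root_with_outgroup,
    tree_from_alignment,
)
from cyp2bdiv.seqcore import CodonAlignment


def _terminal_lengths(tree):
    return {
        l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
    }


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ta = tree.taxon_namespace.get_taxon(a)
                tb = tree.taxon_namespace.get_taxon(b)
                out[i, j] = out[j, i] = pdm.distance(ta, tb)
    return labels, out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = _terminal_lengths(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_recovers_additive_tree(self):
        # distances generated on a known 4-taxon tree:
        # ((A:1,B:2):1.5,C:3,D:0.5) as unrooted additive metric
        d = np.array(
            [
                [0.0, 3.0, 5.5, 3.0],
                [3.0, 0.0, 6.5, 4.0],
                [5.5, 6.5, 0.0, 3.5],
                [3.0, 4.0, 3.5, 0.0],
            ]
        )
        tree = neighbor_joining(d, ["A", "B", "C", "D"])
        labels, recovered = _patristic(tree)
        assert labels == ["A", "B", "C", "D"]
        assert np.allclose(recovered, d, atol=1e-9)

    def test_random_additive_distances_reproduced(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            source = random_rooted_tree(rng, n)
            labels, d = _patristic(source)
            tree = neighbor_joining(d, labels)
            labels2, recovered = _patristic(tree)
            assert labels2 == labels
            assert np.allclose(recovered, d, atol=1e-8)

    def test_equal_distances_star_like(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(d, list("ABCD"))
        lengths = _terminal_lengths(tree)
        assert len(set(np.round(list(lengths.values()), 9))) == 1

    def test_rejects_asymmetric(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("ABC"))

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 6
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = neighbor_joining(d, [f"t{i}" for i in range(n)])
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


class TestRooting:
    def test_outgroup_root_bisects_branch(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        rooted = root_with_outgroup(tree, "C")
        root_children = rooted.seed_node.child_nodes()
        assert len(root_children) == 2
        out_leaf = [c for c in root_children if c.is_leaf()]
        assert out_leaf and out_leaf[0].taxon.label == "C"
        assert out_leaf[0].edge.length == pytest.approx(1.5)  # half of 3.0

    def test_rooting_preserves_leaves_and_is_idempotent(self):
        rng = np.random.default_rng(3)
        source = random_rooted_tree(rng, 7)
        labels, d = _patristic(source)
        tree = neighbor_joining(d, labels)
        r1 = root_with_outgroup(tree, labels[0])
        r2 = root_with_outgroup(r1, labels[0])
        assert {l.taxon.label for l in r1.leaf_node_iter()} == set(labels)

        def root_split(t):
            return frozenset(
                frozenset(l.taxon.label for l in c.leaf_iter())
                for c in t.seed_node.child_nodes()
            )

        assert root_split(r1) == root_split(r2)

    def test_unknown_outgroup_raises(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        with pytest.raises(KeyError):
            root_with_outgroup(tree, "nope")

    def test_distant_outgroup_leaves_ingroup_clade(self, default_family):
        # ingroup clones plus a very distant outgroup: after rooting, the
        # ingroup forms a single clade
        _, clones, _, _ = default_family
        sub = clones[:10]
        from cyp2bdiv.synthfamily import FamilyModel, evolve_locus, simulate_ancestor

        far_model = FamilyModel(locus_divergence=1.0, seed=99)
        anc = simulate_ancestor(491, 0)  # same ancestor as the family (seed 0)
        outgroup = evolve_locus(anc, far_model, 77)
        og = type(sub[0])(
            id="OUTGROUP", animal_id="-", population=sub[0].population,
            diet=sub[0].diet, nucleotides=outgroup.nucleotides,
        )
        aln = CodonAlignment(list(sub) + [og])
        tree = tree_from_alignment(aln)
        rooted = root_with_outgroup(tree, "OUTGROUP")
        ingroup = [c for c in rooted.seed_node.child_nodes()
                   if not (c.is_leaf() and c.taxon.label == "OUTGROUP")]
        assert len(ingroup) == 1
        below = {l.taxon.label for l in ingroup[0].leaf_iter()}
        assert below == {s.id for s in sub}


class TestFitch:
    def test_invariant_column_zero_changes(self):
        aln = make_alignment([["AAA"], ["AAA"], ["AAA"], ["AAA"]],
                             ids=list("ABCD"))
        rng = np.random.default_rng(0)
        tree = random_rooted_tree(rng, 4, labels=list("ABCD"))
        anc = fitch_ancestral(tree, aln)
        # column 1 is the shared ATG start codon; column 2 is the test column
        assert anc.changes[1] == 0
        states = set(anc.column(2).values())
        assert states == {"AAA"}

    def test_clean_split_one_change(self):
        # AABB split matching the topology ((A,B),(C,D)): one change
        tns = dendropy.TaxonNamespace(list("ABCD"))
        tree = dendropy.Tree.get(
            data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick",
            taxon_namespace=tns,
        )
        aln = make_alignment([["AAA"], ["AAA"], ["CCC"], ["CCC"]],
                             ids=list("ABCD"))
        anc = fitch_ancestral(tree, aln)
        assert anc.changes[1] == 1

    def test_matches_bruteforce_minimum(self):
        rng = np.random.default_rng(11)
        codons = ["AAA", "AAG", "CCC", "GGG"]
        for _ in range(25):
            n = int(rng.integers(3, 7))
            labels = [f"L{i}" for i in range(n)]
            tree = random_rooted_tree(rng, n, labels=labels)
            column = [codons[rng.integers(len(codons))] for _ in range(n)]
            aln = make_alignment([[c] for c in column], ids=labels)
            anc = fitch_ancestral(tree, aln)
            oracle = fitch_bruteforce_min(
                tree, dict(zip(labels, column))
            )
            assert anc.changes[1] == oracle
            # the explicit assignment achieves the minimum
            assigned = anc.column(2)
            realised = sum(
                assigned[n_] != assigned[n_.parent_node]
                for n_ in tree.preorder_node_iter()
                if n_.parent_node is not None
            )
            assert realised == oracle
            # parsimony lower bound: at least (distinct states - 1) changes
            assert anc.changes[1] >= len(set(column)) - 1

    def test_missing_leaf_rejected(self):
        rng = np.random.default_rng(0)
        tree = random_rooted_tree(rng, 3, labels=["A", "B", "X"])
        aln = make_alignment([["AAA"], ["AAA"]], ids=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            fitch_ancestral(tree, aln)
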