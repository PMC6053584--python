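"""Neighbor joining, bootstrap supports, rooting, clock dating."""

import dendropy
import numpy as np
import pytest

from mitophylogeo.alignment import SequenceAlignment
from mitophylogeo.distance import DistanceMatrix, difference_matrix
from mitophylogeo.phylogeny import (
    _bipartitions,
    bootstrap_support,
    clock_node_ages,
    nj_tree,
    root_with_outgroup,
    tree_to_newick,
    unroot,
)

from conftest import random_alignment


def random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (dendropy tree, DistanceMatrix of exact path distances)."""
    taxa = [f"t{i:02d}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.5, 5.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.5, 5.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(tns.get_taxon(taxa[a]), tns.get_taxon(taxa[b]))
            mat[a, b] = mat[b, a] = d
    return tree, DistanceMatrix(taxa, mat)


def patristic_matrix(tree, ids):
    tns = tree.taxon_namespace
    pdm = tree.phylogenetic_distance_matrix()
    n = len(ids)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = pdm.patristic_distance(
                tns.get_taxon(ids[a]), tns.get_taxon(ids[b])
            )
    return out


class TestDifferenceMatrix:
    def test_identical_and_simple_counts(self):
        aln = SequenceAlignment(["a", "b", "c"], ["AAAA", "AAAA", "TTAA"])
        d = difference_matrix(aln)
        assert d.values[0, 1] == 0
        assert d.values[0, 2] == 2

    def test_matches_brute_force(self, rng):
        aln = random_alignment(rng, 8, 60, alphabet="ACGT-N")
        d = difference_matrix(aln)
        for i in range(8):
            for j in range(8):
                expect = sum(
                    1
                    for x, y in zip(aln.sequences[i], aln.sequences[j])
                    if x in "ACGT" and y in "ACGT" and x != y
                )
                assert d.values[i, j] == expect

    def test_per_site_normalization(self):
        aln = SequenceAlignment(["a", "b"], ["AAAA-", "TAAAC"])
        d = difference_matrix(aln, per_site=True)
        assert d.values[0, 1] == pytest.approx(1 / 4)


class TestNeighborJoining:
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_additive_trees_exactly(self, rng, n):
        for _ in range(5):
            true_tree, dist = random_additive_tree(rng, n)
            est = nj_tree(dist)
            np.testing.assert_allclose(
                patristic_matrix(est, dist.ids), dist.values, atol=1e-9
            )
            # identical bipartitions (topology recovered)
            assert _bipartitions(est) == _bipartitions(true_tree)

    def test_star_distances_give_zero_internal_branches(self):
        ids = ["a", "b", "c", "d"]
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0)
        tree = nj_tree(DistanceMatrix(ids, D))
        internal = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert all(x == pytest.approx(0, abs=1e-12) for x in internal)

    def test_deterministic_newick(self, rng):
        aln = random_alignment(rng, 10, 50)
        d = difference_matrix(aln)
        assert tree_to_newick(nj_tree(d)) == tree_to_newick(nj_tree(d))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]])))

    def test_branch_lengths_non_negative(self, rng):
        # noisy matrices can produce negative NJ estimates; they are clamped
        for _ in range(10):
            D = rng.integers(0, 12, (7, 7)).astype(float)
            D = np.triu(D, 1)
            D = D + D.T
            tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(7)], D))
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    assert nd.edge.length >= 0


def two_clade_alignment(n_per=4, n_fixed=20, length=120, seed=5):
    """Two clades separated by many fixed differences."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), length)
    other = base.copy()
    other[:n_fixed] = np.where(other[:n_fixed] == "A", "G", "A")
    seqs, ids = [], []
    for k in range(n_per):
        for name, template in (("L", base), ("R", other)):
            s = template.copy()
            # one private mutation per sequence keeps sequences distinct
            pos = n_fixed + 5 * (2 * k + (name == "R"))
            s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            seqs.append("".join(s))
            ids.append(f"{name}{k}")
    return SequenceAlignment(ids, seqs)


class TestBootstrap:
    def test_clean_split_has_full_support(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        split = frozenset(i for i in aln.sample_ids if i.startswith("R"))
        supports = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.annotations[
                "support"
            ].value
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        }
        matches = [v for k, v in supports.items() if k == split or
                   k == frozenset(aln.sample_ids) - split]
        assert matches and matches[0] > 95

    def test_random_alignment_has_weak_internal_support(self, rng):
        aln = random_alignment(rng, 8, 30)
        tree = bootstrap_support(aln, n_reps=100, seed=2)
        vals = [
            nd.annotations["support"].value
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
            and nd.annotations["support"].value is not None
        ]
        assert min(vals) < 70

    def test_supports_bounded_and_reproducible(self, rng):
        aln = random_alignment(rng, 6, 40)
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        v1 = sorted(
            nd.annotations["support"].value
            for nd in t1.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        )
        v2 = sorted(
            nd.annotations["support"].value
            for nd in t2.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        )
        assert v1 == v2
        assert all(0 <= v <= 100 for v in v1)


class TestRootingAndClock:
    def test_root_unroot_round_trip(self, rng):
        _, dist = random_additive_tree(rng, 6)
        tree = nj_tree(dist)
        rooted = root_with_outgroup(tree, "t00")
        assert _bipartitions(unroot(rooted)) == _bipartitions(tree)

    def test_missing_outgroup_rejected(self, rng):
        _, dist = random_additive_tree(rng, 5)
        with pytest.raises(ValueError, match="outgroup"):
            root_with_outgroup(nj_tree(dist), "nope")

    def test_ultrametric_tree_ages_proportional_to_depth(self):
        nwk = "((a:1.0,b:1.0):1.0,(c:1.5,d:1.5):0.5):0.0;"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.is_rooted = True
        dated, table, root_age = clock_node_ages(tree, 200.0)
        assert root_age == pytest.approx(200.0)
        ages = sorted(table["age_years"])
        assert ages == pytest.approx([100.0, 150.0, 200.0])

    def test_ages_monotone_root_to_tip(self, rng):
        _, dist = random_additive_tree(rng, 8)
        rooted = root_with_outgroup(nj_tree(dist), "t00")
        dated, _, _ = clock_node_ages(rooted, 1e6)
        for nd in dated.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.age <= nd.parent_node.age + 1e-9
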