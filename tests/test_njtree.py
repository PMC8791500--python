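"""Neighbor joining: closed forms, additive recovery, newick, bootstrap."""

import io

import dendropy
import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix, build_matrix
from barcodegap.njtree import (
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    write_newick,
)
from barcodegap.simulate import SimConfig, simulate_dataset

from conftest import make_set


def dm(labels, d):
    return DistanceMatrix(list(labels), np.asarray(d, dtype=float))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = neighbor_joining(dm("ab", [[0, 0.04], [0.04, 0]]))
        assert t.path_length("a", "b") == pytest.approx(0.04)

    def test_three_taxa_closed_form(self):
        # d(a,b)=0.3, d(a,c)=0.5, d(b,c)=0.6 ->
        # la=(0.3+0.5-0.6)/2=0.1, lb=0.2, lc=0.4
        t = neighbor_joining(dm("abc", [[0, 0.3, 0.5], [0.3, 0, 0.6],
                                        [0.5, 0.6, 0]]))
        assert t.path_length("a", "b") == pytest.approx(0.3)
        assert t.path_length("a", "c") == pytest.approx(0.5)
        assert t.path_length("b", "c") == pytest.approx(0.6)
        lengths = sorted(c.length for c in t.root.children)
        assert lengths == pytest.approx([0.1, 0.2, 0.4])

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive path-length matrix
        d = {
            ("a", "b"): 3, ("a", "c"): 8, ("a", "d"): 9,
            ("b", "c"): 9, ("b", "d"): 10, ("c", "d"): 9,
        }
        labels = "abcd"
        mat = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    mat[i, j] = mat[j, i] = d[(x, y)]
        t = neighbor_joining(dm(labels, mat))
        for (x, y), v in d.items():
            assert t.path_length(x, y) == pytest.approx(v, abs=1e-9)
        assert bipartitions(t) == {frozenset("cd")}

    def test_additive_five_taxon_exact_recovery(self):
        # caterpillar (((a:1,b:1):1,c:2):1,(d:1,e:2):1) path lengths
        paths = {
            ("a", "b"): 2, ("a", "c"): 4, ("a", "d"): 5, ("a", "e"): 6,
            ("b", "c"): 4, ("b", "d"): 5, ("b", "e"): 6,
            ("c", "d"): 5, ("c", "e"): 6, ("d", "e"): 3,
        }
        labels = "abcde"
        mat = np.zeros((5, 5))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    mat[i, j] = mat[j, i] = paths[(x, y)]
        t = neighbor_joining(dm(labels, mat))
        for (x, y), v in paths.items():
            assert t.path_length(x, y) == pytest.approx(v, abs=1e-9)
        # splits {a,b}|{c,d,e} and {d,e}|{a,b,c}, canonicalized to the
        # side not containing the anchor leaf 'a'
        assert bipartitions(t) == {frozenset("cde"), frozenset("de")}

    def test_undefined_pairs_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(DistanceMatrix(["a", "b"], d))

    def test_negative_branch_lengths_clamped(self):
        # a strongly non-additive matrix induces a negative NJ estimate
        mat = np.array([
            [0.0, 0.1, 0.11, 0.6],
            [0.1, 0.0, 0.6, 0.11],
            [0.11, 0.6, 0.0, 0.1],
            [0.6, 0.11, 0.1, 0.0],
        ])
        t = neighbor_joining(dm("abcd", mat))
        for node in t.root.walk():
            if node.length is not None:
                assert node.length >= 0.0

    def test_matches_scikit_bio_on_random_additive_matrix(self, rng):
        """Cross-check against an independent NJ implementation."""
        import skbio

        n = 8
        # generic random symmetric matrix: tie-free, so both NJ
        # implementations must agglomerate identically
        base = rng.random((n, n)) * 0.2
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = neighbor_joining(dm(labels, d))
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(d, ids=labels)
        )
        their_splits = set()
        all_leaves = frozenset(labels)
        anchor = min(all_leaves)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                their_splits.add(side)
        assert bipartitions(ours) == their_splits

    def test_label_order_invariance(self, rng):
        sset, _ = simulate_dataset(SimConfig(n_groups=3, seqs_per_group=4, seed=7))
        m = build_matrix(sset)
        t1 = neighbor_joining(m)
        perm = list(rng.permutation(m.labels))
        t2 = neighbor_joining(m.submatrix(perm))
        assert bipartitions(t1) == bipartitions(t2)

    def test_zero_distance_samples_adjacent(self):
        sset, _ = simulate_dataset(SimConfig(
            n_groups=3, seqs_per_group=4, intra_div=0.0, seed=8,
        ))
        m = build_matrix(sset)
        t = neighbor_joining(m)
        for i, a in enumerate(m.labels):
            for b in m.labels[i + 1:]:
                if m.get(a, b) == 0.0:
                    assert t.path_length(a, b) == pytest.approx(0.0, abs=1e-9)


class TestNewick:
    def test_three_leaf_structure(self):
        t = neighbor_joining(dm("abc", [[0, 0.3, 0.5], [0.3, 0, 0.6],
                                        [0.5, 0.6, 0]]))
        nwk = write_newick(t)
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")")
        for leaf in "abc":
            assert leaf in nwk

    def test_round_trip_preserves_bipartitions_and_lengths(self, rng):
        sset, _ = simulate_dataset(SimConfig(n_groups=4, seqs_per_group=5, seed=9))
        t = neighbor_joining(build_matrix(sset))
        nwk = write_newick(t)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = frozenset(l.taxon.label for l in parsed.leaf_node_iter())
        anchor = min(taxa)
        their_splits = set()
        for node in parsed.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(
                l.taxon.label for l in node.leaf_iter()
            )
            if anchor in side:
                side = taxa - side
            if 2 <= len(side) <= len(taxa) - 2:
                their_splits.add(side)
        assert their_splits == bipartitions(t)
        # branch lengths preserved to 6 decimals: compare leaf-to-leaf paths
        pdm = parsed.phylogenetic_distance_matrix()
        taxon = {x.label: x for x in parsed.taxon_namespace}
        pairs = sorted(taxa)[:4]
        for i, a in enumerate(pairs):
            for b in pairs[i + 1:]:
                assert pdm.distance(taxon[a], taxon[b]) == pytest.approx(
                    t.path_length(a, b), abs=5e-6
                )

    def test_support_labels_after_internal_parens(self):
        sset, _ = simulate_dataset(SimConfig(n_groups=2, seqs_per_group=4, seed=10))
        t = bootstrap_support(sset, reps=10, seed=1)
        nwk = write_newick(t)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        internal_labels = [
            n.label for n in parsed.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert internal_labels  # supports present as internal-node labels


class TestBootstrapSupport:
    def test_deep_split_high_support(self):
        sset, _ = simulate_dataset(SimConfig(
            n_groups=2, seqs_per_group=5, intra_div=0.001, inter_div=0.15,
            length=624, seed=11,
        ))
        t = bootstrap_support(sset, reps=100, seed=2)
        groups = {}
        for rec in sset:
            groups.setdefault(rec.species_label, set()).add(rec.sample_id)
        split_sides = {frozenset(v) for v in groups.values()}
        all_leaves = frozenset(t.leaf_names())
        anchor = min(all_leaves)
        split_sides = {
            s if anchor not in s else all_leaves - s for s in split_sides
        }
        supports = {
            frozenset(n.leaf_names()) if anchor not in n.leaf_names()
            else all_leaves - frozenset(n.leaf_names()): n.support
            for n in t.root.walk()
            if n.support is not None
        }
        deep = [supports[s] for s in split_sides if s in supports]
        assert deep and all(s >= 95 for s in deep)

    def test_same_seed_identical_supports(self):
        sset, _ = simulate_dataset(SimConfig(n_groups=3, seqs_per_group=4, seed=12))
        def sups(seed):
            t = bootstrap_support(sset, reps=30, seed=seed)
            return sorted(n.support for n in t.root.walk() if n.support is not None)
        assert sups(5) == sups(5)

    def test_single_replicate_supports_binary(self):
        sset, _ = simulate_dataset(SimConfig(n_groups=3, seqs_per_group=4, seed=13))
        t = bootstrap_support(sset, reps=1, seed=3)
        for n in t.root.walk():
            if n.support is not None:
                assert n.support in (0.0, 100.0)
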