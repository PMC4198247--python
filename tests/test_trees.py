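"""Tree utilities: newick round-trip, rooting, MRCA, JC69, neighbor joining."""

import math

import dendropy
import numpy as np
import pytest

from premito import trees
from premito.simulate import random_tree


def _topology_key(tree):
    """Unrooted bipartition set + sorted leaf set, for topology comparison."""
    return (frozenset(trees.leaf_labels(tree)), frozenset(trees.unrooted_bipartitions(tree)))


class TestNewick:
    def test_minimal_two_leaf(self):
        t = trees.parse_newick("(A:1.0,B:2.0);")
        assert sorted(trees.leaf_labels(t)) == ["A", "B"]
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0}
        assert t.is_rooted

    def test_topology_only_dialect(self):
        t = trees.parse_newick("((A,B),C);")
        cherry = {frozenset(l.taxon.label for l in n.leaf_iter())
                  for n in t.preorder_internal_node_iter()}
        assert frozenset({"A", "B"}) in cherry

    @pytest.mark.parametrize("bad", [
        "((A,B),C;",          # unbalanced
        "(A:1.0,A:2.0);",     # duplicate leaf
        "(A:-1.0,B:2.0);",    # negative length
        "A:1.0,B);",
    ])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(trees.NewickError):
            trees.parse_newick(bad)

    def test_roundtrip_random_trees(self, rng):
        """parse(serialize(t)) preserves topology and lengths to 1e-9."""
        for i in range(100):
            n = int(rng.integers(3, 25))
            t = random_tree([f"x{j}" for j in range(n)], rng,
                            branch_min=0.001, branch_max=3.0)
            t2 = trees.parse_newick(trees.serialize_newick(t))
            assert _topology_key(t) == _topology_key(t2)
            l1, D1 = trees.path_length_matrix(t)
            l2, D2 = trees.path_length_matrix(t2)
            assert l1 == l2
            assert np.abs(D1 - D2).max() < 1e-9


class TestOutgroupRoot:
    def test_forced_by_topology(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r = trees.outgroup_root(t, {"C", "D"})
        sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                 for c in r.seed_node.child_nodes()]
        assert frozenset({"C", "D"}) in sides
        assert frozenset({"A", "B"}) in sides

    def test_all_leaves_outgroup_rejected(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(trees.OutgroupError):
            trees.outgroup_root(t, {"A", "B", "C", "D"})

    def test_absent_outgroup_rejected(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(trees.OutgroupError):
            trees.outgroup_root(t, {"Z"})

    def test_non_monophyletic_outgroup_rejected(self):
        t = trees.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(trees.OutgroupError, match="not separable"):
            trees.outgroup_root(t, {"A", "B"})

    def test_random_trees_root_bipartition(self, rng):
        """After rooting, the root bipartition is exactly {outgroup, rest}."""
        for _ in range(30):
            n = int(rng.integers(4, 15))
            t = random_tree([f"x{j}" for j in range(n)], rng)
            # pick a genuine clade of the tree as the outgroup
            internals = [nd for nd in t.preorder_internal_node_iter()
                         if nd is not t.seed_node]
            if not internals:
                continue
            node = internals[int(rng.integers(len(internals)))]
            out = {l.taxon.label for l in node.leaf_iter()}
            if out == set(trees.leaf_labels(t)):
                continue
            r = trees.outgroup_root(t, out)
            sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                     for c in r.seed_node.child_nodes()]
            assert frozenset(out) in sides
            assert _topology_key(r)[1] == _topology_key(t)[1]  # topology unchanged


class TestMidpointRoot:
    def test_two_leaf_symmetry(self):
        r = trees.midpoint_root(trees.parse_newick("(A:3.0,B:1.0);"))
        depths = {l.taxon.label: l.edge.length for l in r.leaf_node_iter()}
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_longest_path_arithmetic(self):
        t = trees.parse_newick("((A:4.0,B:1.0):2.0,(C:1.0,D:3.0):1.0);")
        # longest path A-D: 4+2+1+3 = 10 -> root 5.0 from A
        r = trees.midpoint_root(t)
        depth = _leaf_depths(r)
        assert depth["A"] == pytest.approx(5.0)
        assert depth["D"] == pytest.approx(5.0)

    def test_zero_length_tree_rejected(self):
        with pytest.raises(ValueError, match="midpoint undefined"):
            trees.midpoint_root(trees.parse_newick("(A:0.0,B:0.0);"))

    def test_matches_all_pairs_brute_force(self, rng):
        """Midpoint root halves the longest path found by O(n^2) enumeration."""
        for _ in range(25):
            n = int(rng.integers(4, 16))
            t = random_tree([f"x{j}" for j in range(n)], rng)
            pdm = t.phylogenetic_distance_matrix()
            longest = max(pdm.patristic_distance(a, b)
                          for a in t.taxon_namespace for b in t.taxon_namespace)
            r = trees.midpoint_root(t)
            depth = _leaf_depths(r)
            assert max(depth.values()) == pytest.approx(longest / 2, abs=1e-9)
            # both root subtrees reach depth longest/2
            per_side = []
            for c in r.seed_node.child_nodes():
                side = {l.taxon.label for l in c.leaf_iter()}
                per_side.append(max(depth[l] for l in side))
            assert max(per_side) == pytest.approx(longest / 2, abs=1e-9)
            assert sorted(per_side)[-2] == pytest.approx(longest / 2, abs=1e-9)


def _leaf_depths(rooted):
    out = {}
    def walk(node, d):
        for c in node.child_nodes():
            walk(c, d + (c.edge.length or 0.0))
        if node.is_leaf():
            out[node.taxon.label] = d
    walk(rooted.seed_node, 0.0)
    return out


class TestMrca:
    def test_single_label_is_leaf(self):
        t = trees.parse_newick("((A:1,B:1):1,C:1);")
        assert trees.mrca(t, {"A"}).taxon.label == "A"

    def test_all_labels_is_root(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert trees.mrca(t, {"A", "B", "C", "D"}) is t.seed_node

    def test_unknown_label_rejected(self):
        t = trees.parse_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            trees.mrca(t, {"A", "Z"})

    def test_path_intersection_oracle(self, rng):
        """MRCA equals the deepest node shared by all root-to-leaf paths."""
        for _ in range(25):
            n = int(rng.integers(3, 14))
            t = random_tree([f"x{j}" for j in range(n)], rng)
            labels = trees.leaf_labels(t)
            k = int(rng.integers(2, n + 1))
            chosen = set(np.array(labels)[rng.choice(n, size=k, replace=False)])
            paths = []
            for leaf in t.leaf_node_iter():
                if leaf.taxon.label in chosen:
                    path = [leaf] + list(leaf.ancestor_iter())
                    paths.append(path)
            shared = set(id(x) for x in paths[0])
            for p in paths[1:]:
                shared &= set(id(x) for x in p)
            # deepest shared node = first along any root-to-leaf path
            expected = next(x for x in paths[0] if id(x) in shared)
            assert trees.mrca(t, chosen) is expected


class TestJC69:
    def test_identical_sequences(self):
        assert trees.jc69_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_value(self):
        # p = 0.3 -> -(3/4) ln(1 - 0.4) = 0.38311845...
        a = "A" * 70 + "C" * 30
        b = "A" * 70 + "G" * 30
        expected = -0.75 * math.log(1 - (4.0 / 3.0) * 0.3)
        assert trees.jc69_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_saturation_boundary(self):
        a = "A" * 25 + "C" * 75
        b = "A" * 25 + "G" * 75
        with pytest.raises(trees.SaturationError):
            trees.jc69_distance(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            trees.jc69_distance("ACG", "ACGT")

    def test_non_acgt_sites_excluded_pairwise(self):
        # N-columns dropped: effective p = 1/4
        assert trees.jc69_distance("ANCGT", "ANCGA") == pytest.approx(
            -0.75 * math.log(1 - (4.0 / 3.0) * 0.25))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        t = trees.nj_tree(labels, D)
        # three-point formulas: a=(d_AB+d_AC-d_BC)/2=1, b=2, c=3
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_matrix_exact_recovery(self, rng):
        """NJ recovers topology and lengths exactly from an additive matrix."""
        src = trees.parse_newick(
            "((A:0.11,B:0.23):0.35,(C:0.41,(D:0.13,E:0.27):0.19):0.07);")
        labels, D = trees.path_length_matrix(src)
        t = trees.nj_tree(labels, D)
        assert _topology_key(t)[1] == _topology_key(src)[1]
        labels2, D2 = trees.path_length_matrix(t)
        assert labels == labels2
        assert np.abs(D - D2).max() < 1e-9

    def test_duplicate_rows_zero_cherry(self):
        labels = ["A", "B", "C", "D"]
        D = np.array([[0.0, 0.0, 2.0, 3.0],
                      [0.0, 0.0, 2.0, 3.0],
                      [2.0, 2.0, 0.0, 3.0],
                      [3.0, 3.0, 3.0, 0.0]])
        t = trees.nj_tree(labels, D)
        for n in t.preorder_internal_node_iter():
            leaves = {l.taxon.label for l in n.leaf_iter()}
            if leaves == {"A", "B"}:
                kids = {l.taxon.label: l.edge.length for l in n.child_nodes()}
                assert kids["A"] == pytest.approx(0.0, abs=1e-12)
                assert kids["B"] == pytest.approx(0.0, abs=1e-12)
                return
        pytest.fail("duplicate taxa were not joined in a cherry")

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 1.0], [1.0, 0.0]]),                       # too few taxa
        np.array([[0.0, 1.0, 2.0], [9.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),  # asymmetric
        np.array([[0.0, np.nan, 2.0], [np.nan, 0.0, 1.0], [2.0, 1.0, 0.0]]),
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            trees.nj_tree([f"x{i}" for i in range(bad.shape[0])], bad)
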