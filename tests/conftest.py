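"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from premito import trees
from premito.ancestral import transition_matrix
from premito.simulate import random_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def all_rooted_topologies(labels):
    """Every labeled rooted binary topology over ``labels`` (newick strings,
    no branch lengths).  1, 3, 15, 105 topologies for 2..5 labels."""
    labels = list(labels)
    if len(labels) == 1:
        return [labels[0]]
    out = []
    first, rest = labels[0], labels[1:]
    # left subtree contains the first label; enumerate its partners
    for k in range(len(rest) + 1):
        for combo in itertools.combinations(rest, k):
            left = [first] + list(combo)
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    out.append(f"({lt},{rt})")
    return out


def with_random_lengths(topology_newick, rng, lo=0.05, hi=1.0):
    """Attach uniform branch lengths to a length-free newick string."""
    t = trees.parse_newick(topology_newick + ";")
    for e in t.preorder_edge_iter():
        if e.head_node is not t.seed_node:
            e.length = float(rng.uniform(lo, hi))
    return t


def brute_force_loglik(tree, tip_states, q01, q10, root_prior=(0.5, 0.5)):
    """Likelihood by exhaustive summation over internal-node states."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        prob = root_prior[amap[id(tree.seed_node)]]
        for n in nodes:
            if n is tree.seed_node:
                continue
            s_par = amap[id(n.parent_node)]
            if n.is_leaf():
                s = tip_states.get(n.taxon.label)
                if s is None:
                    continue  # missing tip: both states allowed, factor 1
            else:
                s = amap[id(n)]
            P = transition_matrix(q01, q10, float(n.edge.length or 0.0))
            prob *= P[s_par, s]
        total += prob
    return -np.inf if total == 0 else float(np.log(total))


def brute_force_scan(rooted, taxonomy, min_euk=2, min_alpha=2):
    """Independent clade-rule oracle: apply the rule to every clade's leaf set,
    then keep clades without a qualifying superset.  Returns leaf-label
    frozensets."""
    from premito.taxonomy import ALPHA, EUKARYOTE, CLADE_PARTNER_CLASSES

    clades = []
    for node in rooted.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        clades.append(leaves)
    qualifying = []
    for leaves in clades:
        classes = [taxonomy.class_of(l) for l in leaves]
        if any(c not in CLADE_PARTNER_CLASSES for c in classes):
            continue
        euk = {taxonomy.lineage_of(l) for l in leaves
               if taxonomy.class_of(l) == EUKARYOTE}
        alpha = {taxonomy.lineage_of(l) for l in leaves
                 if taxonomy.class_of(l) == ALPHA}
        if len(euk) >= min_euk and len(alpha) >= min_alpha:
            qualifying.append(leaves)
    return {q for q in qualifying
            if not any(q < other for other in qualifying)}


def random_class_labels(n, rng, classes=None):
    """Random leaf labels with taxon-class prefixes for scan tests."""
    from premito.taxonomy import (ALPHA, ARCHAEAL, DEINOCOCCUS, EUKARYOTE,
                                  MITOCHONDRIAL, OTHER_BACTERIAL, TaxonomyMap)

    if classes is None:
        classes = [EUKARYOTE, MITOCHONDRIAL, ALPHA, OTHER_BACTERIAL,
                   ARCHAEAL, DEINOCOCCUS]
    labels, cls_map, lin_map = [], {}, {}
    for i in range(n):
        cls = classes[int(rng.integers(len(classes)))]
        lab = f"L{i}"
        labels.append(lab)
        cls_map[lab] = cls
        # a couple of lineages per class so lineage-counting is exercised
        lin_map[lab] = f"{cls[:3]}{int(rng.integers(3))}"
    return labels, TaxonomyMap(classes=cls_map, lineages=lin_map)
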