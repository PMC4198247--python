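"""Phylogenetic tree utilities: newick I/O, rooting, MRCA, JC69 distances, neighbor joining.

Trees are represented as :class:`dendropy.Tree` objects throughout the package.
This module wraps parsing/serialization with stricter validation (unique leaf
labels, non-negative branch lengths) and implements the rooting operations and
the distance-based tree builder used by the synthetic-data path.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "OutgroupError",
    "SaturationError",
    "parse_newick",
    "serialize_newick",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "outgroup_root",
    "midpoint_root",
    "mrca",
    "unrooted_bipartitions",
    "path_length_matrix",
    "jc69_distance",
    "nj_tree",
]


class NewickError(ValueError):
    """Raised for malformed newick input (syntax, duplicate labels, negative lengths)."""


class OutgroupError(ValueError):
    """Raised when a requested outgroup cannot define a root."""


class SaturationError(ValueError):
    """Raised when a pairwise mismatch proportion is at or beyond the JC69 domain limit."""


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string into a tree.

    Branch lengths are optional; quoted labels and unquoted underscores are
    preserved verbatim.  A tree whose seed node has exactly two children is
    flagged rooted; a basal polytomy yields an unrooted tree.

    Raises
    ------
    NewickError
        On syntax errors, duplicate leaf labels, or negative branch lengths;
        the message names the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise NewickError(f"duplicate leaf label: {e}") from e
    except Exception as e:  # dendropy raises several reader error classes
        raise NewickError(f"malformed newick: {e}") from e
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise NewickError("leaf without a label")
        if leaf.taxon.label in seen:
            raise NewickError(f"duplicate leaf label: {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            node = edge.head_node
            tok = node.taxon.label if node.taxon else (node.label or "<internal>")
            raise NewickError(f"negative branch length {edge.length} on edge to {tok}")
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def serialize_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line newick string (no rooting token)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def read_newick(path) -> list[dendropy.Tree]:
    """Read one or more newick trees from a file (one tree per line/statement)."""
    with open(path) as fh:
        text = fh.read()
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";"))
    return trees


def write_newick(trees, path) -> None:
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(serialize_newick(t) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _leafset_below(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def unrooted_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each encoded as the side not containing
    the lexicographically smallest leaf label."""
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = _leafset_below(node)
        side = all_leaves - below if anchor in below else below
        if 1 < len(side) < len(all_leaves) - 1 or True:
            if 0 < len(side) < len(all_leaves):
                bips.add(side)
    # drop trivial (single-leaf complements are fine to keep out)
    return {b for b in bips if 1 < len(b) < len(all_leaves) - 1}


def outgroup_root(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the edge separating ``outgroup`` from all other leaves.

    The root is placed at the middle of that edge.  The input tree is not
    modified.

    Raises
    ------
    OutgroupError
        If outgroup labels are missing, the outgroup is empty or covers all
        leaves, or no edge separates the outgroup from the rest under any
        rooting ("outgroup not separable").
    """
    outgroup = frozenset(outgroup)
    work = tree.clone(depth=1)
    labels = frozenset(leaf_labels(work))
    if not outgroup:
        raise OutgroupError("empty outgroup")
    missing = outgroup - labels
    if missing:
        raise OutgroupError(f"outgroup labels absent from tree: {sorted(missing)}")
    if outgroup == labels:
        raise OutgroupError("outgroup covers every leaf; no ingroup remains")
    target = None
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        below = _leafset_below(node)
        if below == outgroup or labels - below == outgroup:
            target = node
            break
    if target is None:
        raise OutgroupError("outgroup not separable: no edge splits outgroup from ingroup")
    L = target.edge.length
    if L is None:
        work.reroot_at_edge(target.edge, update_bipartitions=False)
    else:
        work.reroot_at_edge(target.edge, length1=L / 2.0, length2=L / 2.0,
                            update_bipartitions=False)
    work.is_rooted = True
    return work


def _leaf_depths(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node] = depth[node]
    return out


def path_length_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All-pairs leaf-to-leaf path lengths, labels sorted lexicographically."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return labels, D


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf pair, so the operation is deterministic.  The input
    tree is not modified.

    Raises
    ------
    ValueError
        If every leaf-to-leaf path has zero length ("midpoint undefined").
    """
    work = tree.clone(depth=1)
    labels, D = path_length_matrix(work)
    n = len(labels)
    if n < 2:
        raise ValueError("midpoint undefined: fewer than two leaves")
    best = None  # (-(length), label_a, label_b)
    for i in range(n):
        for j in range(i + 1, n):
            key = (-D[i, j], labels[i], labels[j])
            if best is None or key < best:
                best = key
    length = -best[0]
    if length <= 0:
        raise ValueError("midpoint undefined: all branch lengths zero")
    a_label, b_label = best[1], best[2]
    leaves = {l.taxon.label: l for l in work.leaf_node_iter()}
    a, b = leaves[a_label], leaves[b_label]
    # walk the a->b path; find the edge containing the point length/2 from a
    anc_a = [a] + [x for x in a.ancestor_iter()]
    anc_b = [b] + [x for x in b.ancestor_iter()]
    common = next(x for x in anc_a if x in set(anc_b))
    path = anc_a[: anc_a.index(common)] + list(reversed(anc_b[: anc_b.index(common)]))
    # path nodes listed child-side; consecutive edges: a..common..b
    half = length / 2.0
    acc = 0.0
    # edges along a -> common
    for node in anc_a[: anc_a.index(common)]:
        el = node.edge.length or 0.0
        if acc + el >= half - 1e-15:
            offset = half - acc  # distance from head (child) end
            work.reroot_at_edge(node.edge, length2=offset, length1=el - offset,
                                update_bipartitions=False)
            work.is_rooted = True
            return work
        acc += el
    # continue down common -> b: traverse anc_b reversed
    rest = list(reversed(anc_b[: anc_b.index(common)]))
    for node in rest:
        el = node.edge.length or 0.0
        if acc + el >= half - 1e-15:
            offset = half - acc  # measured from the tail (parent) end now
            work.reroot_at_edge(node.edge, length1=offset, length2=el - offset,
                                update_bipartitions=False)
            work.is_rooted = True
            return work
        acc += el
    raise AssertionError("midpoint not located on the longest path")  # pragma: no cover


def mrca(tree: dendropy.Tree, labels: Iterable[str]):
    """Most recent common ancestor node of ``labels`` in a rooted tree."""
    labels = set(labels)
    if not labels:
        raise ValueError("empty label set")
    present = set(leaf_labels(tree))
    unknown = labels - present
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if len(labels) == 1:
        (lab,) = labels
        return next(l for l in tree.leaf_node_iter() if l.taxon.label == lab)
    node = tree.mrca(taxon_labels=list(labels))
    if node is None:  # pragma: no cover - dendropy returns seed node at worst
        raise ValueError("MRCA not found")
    return node


# ---------------------------------------------------------------------------
# JC69 distance and neighbor joining
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def jc69_distance(seq_a: str, seq_b: str) -> float:
    """Jukes–Cantor distance d = -(3/4)·ln(1 - (4/3)·p) in substitutions/site.

    Sites where either sequence carries a non-ACGT symbol are excluded
    pairwise.  Raises :class:`SaturationError` when the mismatch proportion
    p >= 3/4 (the formula's domain boundary), and ValueError on length
    mismatch or when no comparable site remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    used = mism = 0
    for x, y in zip(seq_a, seq_b):
        if x in _ACGT and y in _ACGT:
            used += 1
            if x != y:
                mism += 1
    if used == 0:
        raise ValueError("no comparable ACGT sites")
    p = mism / used
    if p >= 0.75:
        raise SaturationError(f"saturated pair: mismatch proportion {p:.4f} >= 0.75")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def nj_tree(labels: Sequence[str], dist) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a symmetric distance matrix.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.  Negative branch-length estimates arising from noisy
    matrices are clamped to zero.

    Raises
    ------
    ValueError
        Fewer than 3 labels, non-symmetric matrix, nonzero diagonal, or NaN
        entries.
    """
    D = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal is not zero")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    taxon_ns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        taxon = dendropy.Taxon(label=str(lab))
        taxon_ns.add_taxon(taxon)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = dendropy.Node()
        new.add_child(nodes[i])
        nodes[i].edge.length = li
        new.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to the remaining taxa
        k_new = len(nodes)
        newrow = np.full(k_new + 1, 0.0)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]

    # join the last three nodes at an unrooted trifurcation
    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, L in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(L, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = False
    return tree
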