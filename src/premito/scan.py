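"""Gene-tree scanning for mitochondria-derived families.

A gene family is classified as mitochondria-derived when, in a rooted gene
tree, its eukaryotic sequences form part of a clade containing only
eukaryote-nuclear, mitochondrial and alphaproteobacterial leaves, with at
least two distinct eukaryotic lineages and at least two distinct
alphaproteobacterial species.  Each tree is rooted up to three ways (archaeal
outgroup, Deinococcus–Thermus outgroup, midpoint) and the scan results are
merged across rootings.  Paralogous eukaryotic blocks inside one clade are
split into separate families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import dendropy

from . import trees
from .taxonomy import (
    ALPHA,
    ARCHAEAL,
    CLADE_PARTNER_CLASSES,
    DEINOCOCCUS,
    EUKARYOTE,
    MITOCHONDRIAL,
    TaxonomyMap,
)

__all__ = [
    "MitoDerivedFamily",
    "BenchmarkResult",
    "rooting_cascade",
    "scan_tree",
    "split_paralogs",
    "merge_across_rootings",
    "benchmark_rates",
    "annotation_overlap",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the displayed precision (0.075 -> 0.08)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MitoDerivedFamily:
    """A detected mitochondria-derived gene family.

    ``members`` maps each member gene id to its taxon class; ``clade_leaves``
    is the full leaf set of the supporting clade (a superset of the members
    when a paralog split assigned some eukaryotic leaves elsewhere).
    """

    family_id: str
    members: Mapping[str, str]
    tree_id: str
    clade_leaves: frozenset
    n_euk_lineages: int
    n_alpha_species: int
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_euk_lineages < 2 or self.n_alpha_species < 2:
            raise ValueError(
                "a mitochondria-derived family needs >= 2 eukaryotic lineages "
                "and >= 2 alphaproteobacterial species")
        if not set(self.members) <= set(self.clade_leaves):
            raise ValueError("family members must lie inside the supporting clade")

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass(frozen=True)
class BenchmarkResult:
    """Specificity/sensitivity benchmark: rates in percent with their counts."""

    false_positive_rate: float
    false_negative_rate: float
    n_negative_screened: int
    n_negative_flagged: int
    n_positive_total: int
    n_positive_recovered: int

    @property
    def false_positive_rate_display(self) -> float:
        return round_half_up(self.false_positive_rate, 2)

    @property
    def false_negative_rate_display(self) -> float:
        return round_half_up(self.false_negative_rate, 0)


# ---------------------------------------------------------------------------
# rooting cascade
# ---------------------------------------------------------------------------

def rooting_cascade(tree: dendropy.Tree, taxonomy: TaxonomyMap) -> list[dendropy.Tree]:
    """Root a gene tree up to three ways, in priority order.

    1. archaeal outgroup, if archaeal leaves are present and separable;
    2. Deinococcus–Thermus outgroup, likewise;
    3. midpoint (always attempted; the guaranteed fallback).

    Returns at least one rooted tree; raises ValueError on an empty tree or
    when no rooting at all is possible.
    """
    labels = trees.leaf_labels(tree)
    if not labels:
        raise ValueError("empty tree")
    taxonomy.resolve_all(labels)
    rooted: list[dendropy.Tree] = []
    for cls in (ARCHAEAL, DEINOCOCCUS):
        out = {l for l in labels if taxonomy.class_of(l) == cls}
        if out and out != set(labels):
            try:
                rooted.append(trees.outgroup_root(tree, out))
            except trees.OutgroupError:
                pass  # not separable under any rooting: skip this method
    try:
        rooted.append(trees.midpoint_root(tree))
    except ValueError:
        if not rooted:
            raise ValueError("no rooting possible (midpoint undefined, no outgroup)")
    return rooted


# ---------------------------------------------------------------------------
# bipartition scan
# ---------------------------------------------------------------------------

def _node_stats(node, taxonomy: TaxonomyMap):
    leaves = [l.taxon.label for l in node.leaf_iter()]
    classes = [taxonomy.class_of(l) for l in leaves]
    euk_lin = {taxonomy.lineage_of(l) for l, c in zip(leaves, classes) if c == EUKARYOTE}
    alpha_sp = {taxonomy.lineage_of(l) for l, c in zip(leaves, classes) if c == ALPHA}
    intruders = sum(1 for c in classes if c not in CLADE_PARTNER_CLASSES)
    return leaves, euk_lin, alpha_sp, intruders


def scan_tree(
    rooted: dendropy.Tree,
    taxonomy: TaxonomyMap,
    min_euk: int = 2,
    min_alpha: int = 2,
    max_intruders: int = 0,
) -> list:
    """Find maximal clades where eukaryotic genes cluster with
    alphaproteobacterial/mitochondrial homologs.

    A clade qualifies when its leaves carry only the classes
    {eukaryote-nuclear, mitochondrial, alphaproteobacterial} (at most
    ``max_intruders`` leaves of other classes are tolerated, default none),
    with >= ``min_euk`` distinct eukaryotic lineages and >= ``min_alpha``
    distinct alphaproteobacterial species.  Nested qualifying clades are
    subsumed by their maximal ancestor; the returned nodes are therefore
    pairwise disjoint.
    """
    taxonomy.resolve_all(trees.leaf_labels(rooted))
    qualifying = []
    for node in rooted.preorder_node_iter():
        _, euk_lin, alpha_sp, intruders = _node_stats(node, taxonomy)
        if intruders <= max_intruders and len(euk_lin) >= min_euk and len(alpha_sp) >= min_alpha:
            qualifying.append(node)
    maximal = []
    qset = set(id(n) for n in qualifying)
    for node in qualifying:
        if not any(id(a) in qset for a in node.ancestor_iter()):
            maximal.append(node)
    return maximal


def _maximal_euk_blocks(clade, taxonomy: TaxonomyMap):
    """Maximal sub-clades of ``clade`` whose leaves are all eukaryote-nuclear."""
    blocks = []

    def visit(node):
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if all(taxonomy.class_of(l) == EUKARYOTE for l in leaves):
            blocks.append(node)
            return
        for child in node.child_nodes():
            visit(child)

    visit(clade)
    return blocks


def split_paralogs(
    tree: dendropy.Tree,
    clades: Sequence,
    taxonomy: TaxonomyMap,
    tree_id: str = "tree",
    min_euk: int = 2,
) -> list[MitoDerivedFamily]:
    """Turn qualifying clades into families, separating paralogous blocks.

    Each disjoint qualifying clade founds its own family.  Within one clade,
    if two or more maximal eukaryotic sub-clades each span >= ``min_euk``
    distinct lineages (they are necessarily separated by alphaproteobacterial
    or mitochondrial leaves, otherwise they would merge into one block), each
    block founds a separate family sharing the clade's bacterial leaves.
    """
    families: list[MitoDerivedFamily] = []
    for k, clade in enumerate(clades):
        leaves, euk_lin, alpha_sp, _ = _node_stats(clade, taxonomy)
        clade_set = frozenset(leaves)
        non_euk = {l: taxonomy.class_of(l) for l in leaves
                   if taxonomy.class_of(l) != EUKARYOTE}
        blocks = _maximal_euk_blocks(clade, taxonomy)
        rich = []
        for b in blocks:
            b_leaves = [l.taxon.label for l in b.leaf_iter()]
            if len({taxonomy.lineage_of(l) for l in b_leaves}) >= min_euk:
                rich.append(b_leaves)
        if len(rich) >= 2:  # paralogous: one family per qualifying eukaryotic block
            for p, b_leaves in enumerate(rich):
                members = {l: EUKARYOTE for l in b_leaves}
                members.update(non_euk)
                lin = {taxonomy.lineage_of(l) for l in b_leaves}
                families.append(MitoDerivedFamily(
                    family_id=f"{tree_id}.c{k}.p{p}",
                    members=members,
                    tree_id=tree_id,
                    clade_leaves=clade_set,
                    n_euk_lineages=len(lin),
                    n_alpha_species=len(alpha_sp),
                ))
        else:
            members = {l: taxonomy.class_of(l) for l in leaves}
            families.append(MitoDerivedFamily(
                family_id=f"{tree_id}.c{k}",
                members=members,
                tree_id=tree_id,
                clade_leaves=clade_set,
                n_euk_lineages=len(euk_lin),
                n_alpha_species=len(alpha_sp),
            ))
    return families


def merge_across_rootings(
    per_rooting: Sequence[Sequence[MitoDerivedFamily]],
) -> list[MitoDerivedFamily]:
    """Union the families found under each rooting of one gene tree.

    Families with identical member sets are deduplicated.  When one family's
    member set contains another's, the larger is kept and flagged; overlapping
    but non-nested member sets are both kept and flagged.
    """
    seen: dict[frozenset, MitoDerivedFamily] = {}
    for fams in per_rooting:
        for f in fams:
            if f.member_set not in seen:
                seen[f.member_set] = f
    pool = list(seen.values())
    keep: list[MitoDerivedFamily] = []
    for f in pool:
        if any(g is not f and f.member_set < g.member_set for g in pool):
            continue
        contains = any(g is not f and g.member_set < f.member_set for g in pool)
        overlaps = any(
            g is not f
            and g.member_set & f.member_set
            and not (g.member_set <= f.member_set or f.member_set <= g.member_set)
            for g in pool)
        if contains or overlaps:
            note = "merged containment" if contains else "conflicting overlap across rootings"
            f = MitoDerivedFamily(
                family_id=f.family_id, members=f.members, tree_id=f.tree_id,
                clade_leaves=f.clade_leaves, n_euk_lineages=f.n_euk_lineages,
                n_alpha_species=f.n_alpha_species, flagged=True, note=note)
        keep.append(f)
    return sorted(keep, key=lambda f: sorted(f.member_set))


# ---------------------------------------------------------------------------
# benchmark arithmetic and annotation overlap
# ---------------------------------------------------------------------------

def benchmark_rates(
    n_negative_screened: int,
    n_negative_flagged: int,
    n_positive_total: int,
    n_positive_recovered: int,
) -> BenchmarkResult:
    """False-positive and false-negative percentages from benchmark counts.

    FP% = 100 * flagged / screened (negatives wrongly called mito-derived);
    FN% = 100 * (total - recovered) / total (positive controls missed).
    """
    for name, v in (("n_negative_screened", n_negative_screened),
                    ("n_negative_flagged", n_negative_flagged),
                    ("n_positive_total", n_positive_total),
                    ("n_positive_recovered", n_positive_recovered)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_negative_screened == 0 or n_positive_total == 0:
        raise ValueError("zero denominator in benchmark counts")
    if n_negative_flagged > n_negative_screened:
        raise ValueError("flagged exceeds screened")
    if n_positive_recovered > n_positive_total:
        raise ValueError("recovered exceeds total")
    fp = 100.0 * n_negative_flagged / n_negative_screened
    fn = 100.0 * (n_positive_total - n_positive_recovered) / n_positive_total
    return BenchmarkResult(fp, fn, n_negative_screened, n_negative_flagged,
                           n_positive_total, n_positive_recovered)


def annotation_overlap(
    family_ids: Sequence[str],
    annotation: Mapping[str, bool],
) -> tuple[float, int, int]:
    """Percentage (1 decimal, half-up) of families whose annotation flag is
    true, with the raw counts.  Families missing from the annotation count as
    false."""
    if len(family_ids) == 0:
        raise ValueError("empty family list")
    n_flagged = sum(1 for f in family_ids if annotation.get(f, False))
    pct = round_half_up(100.0 * n_flagged / len(family_ids), 1)
    return pct, n_flagged, len(family_ids)
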