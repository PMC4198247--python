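"""Synthetic-data generators for every stage of the pipeline.

The generators emit exactly the formats the real-data path consumes (newick
trees, FASTA alignments, BLAST-tabular hit tables, taxonomy TSVs,
presence/absence matrices) together with the generating truth, so each
decision rule can be scored against a known answer:

* a Yule species tree with class-labelled leaves;
* gene-family presence/absence histories under the two-rate gain/loss chain,
  with the true state recorded at every internal node;
* gene trees of four kinds — mitochondria-derived (a multi-lineage eukaryotic
  clade nested among alphaproteobacteria), lineage-specific transfer (a
  single eukaryotic lineage inside the alphaproteobacteria, which the scan
  must reject), other-bacterial origin, and vertically inherited eukaryotic
  families;
* JC69 sequence alignments evolved on those gene trees;
* emulated homology hit tables whose e-value ranking follows sequence
  similarity.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from . import trees
from .ancestral import transition_matrix
from .screen import HitRecord
from .taxonomy import (
    ALPHA,
    ARCHAEAL,
    DEINOCOCCUS,
    EUKARYOTE,
    MITOCHONDRIAL,
    OTHER_BACTERIAL,
    TaxonomyMap,
)

__all__ = [
    "SimScenario",
    "GeneHistory",
    "BenchmarkSet",
    "simulate_species_tree",
    "simulate_presence_absence",
    "simulate_gene_history",
    "simulate_sequences",
    "emulate_hit_table",
    "simulate_benchmark_set",
    "random_tree",
    "nni_moves",
]

KINDS = ("mito-derived", "lineage-specific-transfer", "other-bacterial",
         "vertical-eukaryotic")


@dataclass
class SimScenario:
    """Study-design parameters of a synthetic benchmark.

    The class counts keep every decision rule exercisable: at least two
    eukaryotic lineages and two alphaproteobacterial species are required for
    a detectable family.  ``kind_fractions`` fixes the composition of the
    family mix; ``branch_min``/``branch_max`` bound the per-branch lengths
    (substitutions/site) of the synthetic gene trees, chosen so that pairwise
    distances stay comfortably below JC69 saturation at the default sequence
    length.
    """

    seed: int = 0
    n_euk_lineages: int = 6
    n_alpha: int = 8
    n_other_bacteria: int = 6
    n_archaea: int = 3
    n_deinococcus: int = 2
    n_families: int = 200
    q01: float = 0.2
    q10: float = 0.8
    kind_fractions: dict = field(default_factory=lambda: {
        "mito-derived": 0.4,
        "lineage-specific-transfer": 0.2,
        "other-bacterial": 0.2,
        "vertical-eukaryotic": 0.2,
    })
    seq_length: int = 500
    branch_min: float = 0.01
    branch_max: float = 0.08
    nni_noise: int = 0
    evalue_slope: float = 60.0       # -log10 e per unit identity above baseline
    evalue_baseline: float = 0.35    # identity of an unrelated pair
    evalue_jitter_sd: float = 0.5    # log10-scale jitter

    def __post_init__(self) -> None:
        total = sum(self.kind_fractions.get(k, 0.0) for k in KINDS)
        if total > 1.0 + 1e-9:
            raise ValueError("kind fractions sum to more than 1")
        unknown = set(self.kind_fractions) - set(KINDS)
        if unknown:
            raise ValueError(f"unknown family kinds: {sorted(unknown)}")
        if self.n_euk_lineages < 2 or self.n_alpha < 2:
            raise ValueError(
                "need >= 2 eukaryotic lineages and >= 2 alphaproteobacteria "
                "for the scan rule to be exercisable")


@dataclass
class GeneHistory:
    """One simulated gene family: its tree, leaf classes, and the truth label."""

    family_id: str
    kind: str
    tree: dendropy.Tree
    leaf_classes: dict
    leaf_lineages: dict

    @property
    def is_mito_derived(self) -> bool:
        return self.kind == "mito-derived"


# ---------------------------------------------------------------------------
# species tree (Yule)
# ---------------------------------------------------------------------------

def simulate_species_tree(n_taxa: int, seed=None, labels: Optional[Sequence[str]] = None,
                          rng: Optional[np.random.Generator] = None) -> dendropy.Tree:
    """Pure-birth (Yule) tree, made ultrametric and scaled to unit height.

    Lineages split at exponential waiting times (rate proportional to the
    number of extant lineages) until ``n_taxa`` is reached; tips are then
    extended to the present.  Deterministic under a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i+1}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    # the root splits at time 0; each active lineage records its start time
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    t = 0.0
    active = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, start = active.pop(i)
        node.edge.length = t - start
        d1, d2 = dendropy.Node(), dendropy.Node()
        node.add_child(d1)
        node.add_child(d2)
        active.append((d1, t))
        active.append((d2, t))
    height = t + rng.exponential(1.0 / n_taxa)
    for (leaf, start), lab in zip(active, labels):
        leaf.edge.length = height - start
        taxon = dendropy.Taxon(label=lab)
        ns.add_taxon(taxon)
        leaf.taxon = taxon
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = True
    if height > 0:  # rescale to unit height
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length /= height
    return tree


# ---------------------------------------------------------------------------
# presence/absence histories
# ---------------------------------------------------------------------------

def simulate_presence_absence(
    tree: dendropy.Tree,
    q01: float,
    q10: float,
    n_families: int,
    root_prior=(0.5, 0.5),
    seed=None,
    rng: Optional[np.random.Generator] = None,
):
    """Forward-simulate binary gain/loss histories on a rooted species tree.

    Returns ``(matrix, truth)`` as pandas DataFrames: tip states (families x
    taxa) and the true states at every internal node (families x node
    labels).  Internal nodes without labels are named ``N0, N1, ...`` in
    preorder (the root is always ``N0``).
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(seed)
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"N{counter}"
            counter += 1
        elif not node.is_leaf():
            counter += 1
    prior1 = float(root_prior[1])
    states: dict = {}
    root = tree.seed_node
    states[id(root)] = (rng.uniform(size=n_families) < prior1).astype(np.int8)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = states[id(node.parent_node)]
        t = float(node.edge.length or 0.0)
        P = transition_matrix(q01, q10, t)
        u = rng.uniform(size=n_families)
        # P[state, 1] is the probability of being present after time t
        p_present = np.where(parent == 1, P[1, 1], P[0, 1])
        states[id(node)] = (u < p_present).astype(np.int8)
    fam_ids = [f"fam{i:04d}" for i in range(n_families)]
    tip_cols, tip_labs = [], []
    int_cols, int_labs = [], []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            tip_labs.append(node.taxon.label)
            tip_cols.append(states[id(node)])
        else:
            int_labs.append(node.label)
            int_cols.append(states[id(node)])
    matrix = pd.DataFrame(np.column_stack(tip_cols).astype(float),
                          index=fam_ids, columns=tip_labs)
    truth = pd.DataFrame(np.column_stack(int_cols).astype(int),
                         index=fam_ids, columns=int_labs)
    return matrix, truth


# ---------------------------------------------------------------------------
# gene histories
# ---------------------------------------------------------------------------

def random_tree(labels: Sequence[str], rng: np.random.Generator,
                branch_min: float = 0.01, branch_max: float = 0.1) -> dendropy.Tree:
    """Random rooted binary topology over ``labels`` with i.i.d. uniform
    branch lengths; used both by the generators and as a test-case factory."""
    if len(labels) < 1:
        raise ValueError("need at least one label")
    newick = _random_subtree_newick(list(labels), rng, branch_min, branch_max)
    return trees.parse_newick(newick + ";")


def _bl(rng, lo, hi) -> str:
    return f"{rng.uniform(lo, hi):.6f}"


def _random_subtree_newick(labels, rng, lo, hi) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:{_bl(rng, lo, hi)}"
    k = int(rng.integers(1, len(labels)))
    idx = rng.permutation(len(labels))
    left = [labels[i] for i in idx[:k]]
    right = [labels[i] for i in idx[k:]]
    return (f"({_random_subtree_newick(left, rng, lo, hi)},"
            f"{_random_subtree_newick(right, rng, lo, hi)}):{_bl(rng, lo, hi)}")


def nni_moves(tree: dendropy.Tree, n_moves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Apply ``n_moves`` random nearest-neighbour interchanges (topology noise)."""
    work = tree.clone(depth=1)
    for _ in range(n_moves):
        internal = [e for e in work.preorder_edge_iter()
                    if e.head_node and e.tail_node
                    and not e.head_node.is_leaf()
                    and e.tail_node.parent_node is not None]
        if not internal:
            break
        edge = internal[int(rng.integers(len(internal)))]
        child = edge.head_node
        parent = edge.tail_node
        a = child.child_nodes()[int(rng.integers(len(child.child_nodes())))]
        sibs = [c for c in parent.child_nodes() if c is not child]
        if not sibs:
            continue
        b = sibs[int(rng.integers(len(sibs)))]
        child.remove_child(a)
        parent.remove_child(b)
        child.add_child(b)
        parent.add_child(a)
    return work


def _class_labels(scenario: SimScenario):
    euks = [f"E{i+1}" for i in range(scenario.n_euk_lineages)]
    alphas = [f"A{i+1}" for i in range(scenario.n_alpha)]
    others = [f"B{i+1}" for i in range(scenario.n_other_bacteria)]
    archs = [f"R{i+1}" for i in range(scenario.n_archaea)]
    deinos = [f"D{i+1}" for i in range(scenario.n_deinococcus)]
    return euks, alphas, others, archs, deinos


def scenario_taxonomy(scenario: SimScenario) -> TaxonomyMap:
    """Taxonomy of the scenario's organisms (lineage = organism label)."""
    euks, alphas, others, archs, deinos = _class_labels(scenario)
    classes, lineages = {}, {}
    for group, cls in ((euks, EUKARYOTE), (alphas, ALPHA), (others, OTHER_BACTERIAL),
                       (archs, ARCHAEAL), (deinos, DEINOCOCCUS)):
        for org in group:
            classes[org] = cls
            lineages[org] = org
    return TaxonomyMap(classes=classes, lineages=lineages)


def simulate_gene_history(scenario: SimScenario, kind: str,
                          family_id: str = "g0000",
                          rng: Optional[np.random.Generator] = None) -> GeneHistory:
    """Build one gene tree of the requested kind with class-labelled leaves.

    Leaf labels are ``<organism>.<family>`` (e.g. ``E2.g0007``); the organism
    prefix carries the taxon class and lineage.  Branch lengths are uniform
    draws from the scenario's range.  ``scenario.nni_noise`` random NNI moves
    are applied afterwards to emulate phylogenetic error.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    euks, alphas, others, archs, deinos = _class_labels(scenario)
    lo, hi = scenario.branch_min, scenario.branch_max
    tag = lambda orgs: [f"{o}.{family_id}" for o in orgs]

    n_euk_in_family = int(rng.integers(2, min(4, scenario.n_euk_lineages) + 1))
    euk_orgs = [euks[i] for i in sorted(rng.choice(scenario.n_euk_lineages,
                                                   n_euk_in_family, replace=False))]
    if kind == "lineage-specific-transfer":
        euk_orgs = [euk_orgs[0]]
    n_alpha_in_family = int(rng.integers(4, scenario.n_alpha + 1))
    alpha_orgs = [alphas[i] for i in sorted(rng.choice(scenario.n_alpha,
                                                       n_alpha_in_family, replace=False))]
    n_other = int(rng.integers(2, scenario.n_other_bacteria + 1))
    other_orgs = [others[i] for i in sorted(rng.choice(scenario.n_other_bacteria,
                                                       n_other, replace=False))]
    arch_orgs = archs[: max(1, scenario.n_archaea - 1)]
    deino_orgs = deinos[:]

    sub = lambda orgs: _random_subtree_newick(tag(orgs), rng, lo, hi)
    euk_block = sub(euk_orgs)
    out_block = (f"({sub(arch_orgs)},{sub(deino_orgs)}):{_bl(rng, lo, hi)}")

    if kind in ("mito-derived", "lineage-specific-transfer"):
        # eukaryotic block nested inside the alphaproteobacterial clade:
        # ((alpha_inner, euks), alpha_outer) keeps the euk+alpha region pure
        half = max(2, len(alpha_orgs) // 2)
        inner, outer = alpha_orgs[:half], alpha_orgs[half:]
        alpha_part = (f"(({sub(inner)},{euk_block}):{_bl(rng, lo, hi)},"
                      f"{sub(outer)}):{_bl(rng, lo, hi)}")
        ingroup = f"({alpha_part},{sub(other_orgs)}):{_bl(rng, lo, hi)}"
    elif kind == "other-bacterial":
        # eukaryotes nested among the other bacteria instead
        half = max(1, len(other_orgs) // 2)
        inner, outer = other_orgs[:half], other_orgs[half:]
        if outer:
            other_part = (f"(({sub(inner)},{euk_block}):{_bl(rng, lo, hi)},"
                          f"{sub(outer)}):{_bl(rng, lo, hi)}")
        else:
            other_part = f"({sub(inner)},{euk_block}):{_bl(rng, lo, hi)}"
        ingroup = f"({sub(alpha_orgs)},{other_part}):{_bl(rng, lo, hi)}"
    else:  # vertical-eukaryotic: eukaryotes sister to all bacteria
        bact = f"({sub(alpha_orgs)},{sub(other_orgs)}):{_bl(rng, lo, hi)}"
        ingroup = f"({euk_block},{bact}):{_bl(rng, lo, hi)}"

    tree = trees.parse_newick(f"({out_block},{ingroup});")
    if scenario.nni_noise > 0:
        tree = nni_moves(tree, scenario.nni_noise, rng)
    orgs = euk_orgs + alpha_orgs + other_orgs + arch_orgs + deino_orgs
    base = scenario_taxonomy(scenario)
    leaf_classes = {f"{o}.{family_id}": base.class_of(o) for o in orgs}
    leaf_lineages = {f"{o}.{family_id}": o for o in orgs}
    return GeneHistory(family_id=family_id, kind=kind, tree=tree,
                       leaf_classes=leaf_classes, leaf_lineages=leaf_lineages)


# ---------------------------------------------------------------------------
# sequences and hit tables
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_sequences(tree: dendropy.Tree, length: int, seed=None,
                       rng: Optional[np.random.Generator] = None) -> dict:
    """Evolve a JC69 alignment along a tree (branch lengths in subs/site).

    The root sequence is uniform over ACGT; each site evolves independently.
    Returns ``{leaf label: sequence}`` in the tree's leaf order.
    """
    if length <= 0:
        raise ValueError("sequence length must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    seqs = {id(tree.seed_node): root_seq}
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent = seqs[id(node.parent_node)]
            d = float(node.edge.length or 0.0)
            p_change = 0.75 * (-math.expm1(-4.0 * d / 3.0))
            hit = rng.uniform(size=length) < p_change
            shift = rng.integers(1, 4, size=length, dtype=np.uint8)
            child = parent.copy()
            child[hit] = (child[hit] + shift[hit]) % 4
            seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = bytes(_BASES[seqs[id(node)]]).decode()
    return out


def _identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def emulate_hit_table(
    histories: Sequence[GeneHistory],
    sequences: Optional[Mapping] = None,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    slope: float = 60.0,
    baseline: float = 0.35,
    jitter_sd: float = 0.5,
) -> list[HitRecord]:
    """Emulate an all-vs-all homology search restricted to family members.

    Each gene hits every member of its own family (including itself) with
    e-value 10^(-slope*(identity - baseline) + jitter), floored at 1e-180,
    so the e-value ranking is monotone in sequence similarity up to seeded
    jitter.  ``sequences`` maps family_id -> {leaf: seq}.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records: list[HitRecord] = []
    for h in histories:
        seqs = sequences[h.family_id]
        members = sorted(seqs)
        for q in members:
            for s in members:
                if q == s:
                    e, bits = 1e-180, 2.0 * slope
                else:
                    ident = _identity(seqs[q], seqs[s])
                    log10e = -slope * (ident - baseline) + rng.normal(0.0, jitter_sd)
                    e = 10.0 ** max(min(log10e, 10.0), -180.0)
                    bits = max(2.0 * slope * (ident - baseline), 0.0)
                records.append(HitRecord(query=q, subject=s, evalue=e, bitscore=bits))
    return records


# ---------------------------------------------------------------------------
# full benchmark scenario
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkSet:
    """A complete synthetic benchmark: histories, alignments, hits, taxonomy."""

    scenario: SimScenario
    histories: list
    sequences: dict            # family_id -> {leaf: seq}
    hits: list
    taxonomy: TaxonomyMap      # over gene ids (leaf labels)
    truth: dict                # family_id -> kind

    def to_dir(self, path) -> None:
        """Write the set in the formats the real-data path consumes."""
        import os

        from .screen import write_hit_table

        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "gene_trees.nwk"), "w") as fh:
            for h in self.histories:
                fh.write(trees.serialize_newick(h.tree) + "\n")
        with open(os.path.join(path, "alignments.fasta"), "w") as fh:
            for fam, seqs in self.sequences.items():
                for lab, s in sorted(seqs.items()):
                    fh.write(f">{lab}\n{s}\n")
        write_hit_table(self.hits, os.path.join(path, "hits.tsv"))
        self.taxonomy.to_tsv(os.path.join(path, "taxonomy.tsv"))
        with open(os.path.join(path, "truth.json"), "w") as fh:
            json.dump({"scenario": asdict(self.scenario), "kinds": self.truth},
                      fh, indent=1, sort_keys=True)


def simulate_benchmark_set(scenario: SimScenario) -> BenchmarkSet:
    """Generate the full mixed-family benchmark for the screen+scan pipeline."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_families
    kinds: list[str] = []
    for k in KINDS:
        kinds += [k] * int(round(scenario.kind_fractions.get(k, 0.0) * n))
    while len(kinds) < n:
        kinds.append("vertical-eukaryotic")
    kinds = kinds[:n]
    histories, sequences, truth = [], {}, {}
    classes, lineages = {}, {}
    for i, kind in enumerate(kinds):
        fam = f"g{i:04d}"
        h = simulate_gene_history(scenario, kind, family_id=fam, rng=rng)
        histories.append(h)
        truth[fam] = kind
        sequences[fam] = simulate_sequences(h.tree, scenario.seq_length, rng=rng)
        classes.update(h.leaf_classes)
        lineages.update(h.leaf_lineages)
    hits = emulate_hit_table(histories, sequences, rng=rng,
                             slope=scenario.evalue_slope,
                             baseline=scenario.evalue_baseline,
                             jitter_sd=scenario.evalue_jitter_sd)
    taxonomy = TaxonomyMap(classes=classes, lineages=lineages)
    return BenchmarkSet(scenario=scenario, histories=histories, sequences=sequences,
                        hits=hits, taxonomy=taxonomy, truth=truth)
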