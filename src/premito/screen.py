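"""Candidate screening from homology hit tables and Markov clustering into families.

The screen retains a eukaryotic query gene when at least one of its top-ranked
homology hits (default: top 5 at e-value <= 1e-4, self-hits removed) is
alphaproteobacterial or mitochondrial.  Retained genes are clustered into
families with the Markov Cluster Algorithm (MCL) on a similarity graph whose
edge weights are capped -log10 e-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .taxonomy import ALPHA, EUKARYOTE, MITOCHONDRIAL, OTHER_BACTERIAL, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "read_hit_table",
    "write_hit_table",
    "filter_candidates",
    "build_family_graph",
    "mcl_cluster",
    "retain_families",
    "write_clusters",
]


@dataclass(frozen=True)
class HitRecord:
    """One ranked homology hit (BLAST tabular dialect, columns we consume)."""

    query: str
    subject: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for {self.query}->{self.subject}")


def read_hit_table(path) -> list[HitRecord]:
    """Read an outfmt-6-like TSV.  Only query, subject, evalue, bitscore are used;
    12-column tables take columns 0/1/10/11, narrower tables 0/1/2/3."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("hit table %s is empty", path)
        return []
    if df.empty:
        logger.warning("hit table %s has no records", path)
        return []
    if df.shape[1] >= 12:
        q, s, e, b = df[0], df[1], df[10], df[11]
    elif df.shape[1] >= 4:
        q, s, e, b = df[0], df[1], df[2], df[3]
    else:
        raise ValueError("hit table needs at least 4 columns (query, subject, evalue, bitscore)")
    return [HitRecord(str(qq), str(ss), float(ee), float(bb))
            for qq, ss, ee, bb in zip(q, s, e, b)]


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.evalue:.6g}\t{h.bitscore:.2f}\n")


def _ranked(hits: Sequence[HitRecord]) -> list[HitRecord]:
    # best first: smallest e-value, then largest bit score, then subject id
    return sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject))


def filter_candidates(
    hits: Iterable[HitRecord],
    taxonomy: TaxonomyMap,
    e_cutoff: float = 1e-4,
    top_n: int = 5,
    unresolved_class: str = OTHER_BACTERIAL,
) -> set[str]:
    """Return query ids whose top ``top_n`` hits (after discarding self-hits and
    hits above ``e_cutoff``) include an alphaproteobacterial or mitochondrial
    subject.

    Subjects without a taxonomy entry are treated as ``unresolved_class``
    (default other-bacterial) and a warning is logged.
    """
    by_query: dict[str, list[HitRecord]] = {}
    unresolved = 0
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    retained: set[str] = set()
    for query, qhits in by_query.items():
        usable = [h for h in qhits if h.subject != query and h.evalue <= e_cutoff]
        for h in _ranked(usable)[:top_n]:
            if taxonomy.has(h.subject):
                cls = taxonomy.class_of(h.subject)
            else:
                cls = unresolved_class
                unresolved += 1
            if cls in (ALPHA, MITOCHONDRIAL):
                retained.add(query)
                break
    if unresolved:
        logger.warning("%d hits had unresolvable subject taxa; treated as %s",
                       unresolved, unresolved_class)
    return retained


def build_family_graph(
    candidates: Iterable[str],
    homolog_hits: Iterable[HitRecord],
    e_cutoff: float = 1e-15,
    weight_cap: float = 200.0,
) -> nx.Graph:
    """Similarity graph over candidate genes and their homologs.

    An undirected edge joins two genes when either direction has a hit at
    e-value <= ``e_cutoff``; the weight is min(cap, -log10 e) using the best
    (smallest) e-value seen in either direction; e = 0 maps to the cap.
    Self-hits are ignored.  Candidate genes are always present as nodes, even
    when isolated.
    """
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for h in homolog_hits:
        if h.query == h.subject or h.evalue > e_cutoff:
            continue
        w = weight_cap if h.evalue == 0 else min(weight_cap, -math.log10(h.evalue))
        if w <= 0:
            continue
        if g.has_edge(h.query, h.subject):
            g[h.query][h.subject]["weight"] = max(g[h.query][h.subject]["weight"], w)
        else:
            g.add_edge(h.query, h.subject, weight=w)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> list[frozenset]:
    """Markov clustering of a weighted similarity graph.

    Alternates expansion (squaring of the column-stochastic transition matrix,
    after adding a self-loop to each node equal to its maximum incident edge
    weight) with inflation (entry-wise power then column renormalization)
    until the matrix changes by less than ``tol``.  Clusters are read off the
    attractor rows of the limit matrix; nodes claimed by several attractors go
    to the larger cluster, ties broken lexicographically.  The partition is
    deterministic and independent of node insertion order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u},{v})")
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    # self-loops: max incident weight (1.0 for isolated nodes)
    for i in range(n):
        mx = M[i].max()
        M[i, i] = mx if mx > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.abs(M - prev).max():.3g})")
    eps = 1e-6
    attractors = [i for i in range(n) if M[i, i] > eps]
    # group attractors with identical support into one cluster
    clusters: list[set] = []
    support = {}
    for i in attractors:
        sup = frozenset(np.nonzero(M[i] > eps)[0].tolist()) | {i}
        support[i] = sup
    merged: list[set] = []
    for i in attractors:
        placed = False
        for c in merged:
            if support[i] & c:
                c |= support[i]
                placed = True
                break
        if not placed:
            merged.append(set(support[i]))
    # a column may still sit in several merged clusters; assign deterministically
    assignment: dict[int, int] = {}
    order = sorted(range(len(merged)),
                   key=lambda k: (-len(merged[k]), sorted(nodes[i] for i in merged[k])))
    for rank in order:
        for j in merged[rank]:
            assignment.setdefault(j, rank)
    for j in range(n):  # unclaimed nodes: strongest column entry, else singleton
        if j not in assignment:
            i_best = int(np.argmax(M[:, j]))
            if M[i_best, j] > eps and i_best in assignment:
                assignment[j] = assignment[i_best]
            else:
                merged.append({j})
                assignment[j] = len(merged) - 1
    out: dict[int, set] = {}
    for j, c in assignment.items():
        out.setdefault(c, set()).add(nodes[j])
    return sorted((frozenset(v) for v in out.values()), key=lambda s: sorted(s))


def retain_families(
    clusters: Iterable[frozenset],
    taxonomy: TaxonomyMap,
    min_euk_lineages: int = 2,
) -> list[frozenset]:
    """Keep clusters whose eukaryote-nuclear members span at least
    ``min_euk_lineages`` distinct lineages."""
    kept = []
    for cluster in clusters:
        lineages = {taxonomy.lineage_of(g) for g in cluster
                    if taxonomy.has(g) and taxonomy.class_of(g) == EUKARYOTE}
        if len(lineages) >= min_euk_lineages:
            kept.append(cluster)
    return kept


def write_clusters(clusters: Iterable[frozenset], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgene_id\n")
        for k, cluster in enumerate(clusters):
            for gene in sorted(cluster):
                fh.write(f"fam{k:04d}\t{gene}\n")
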