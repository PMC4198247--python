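"""End-to-end screen + scan pipeline and its benchmark scoring.

Chains the stages the way the real analysis does: candidate screening from a
hit table, Markov clustering into families, gene-tree construction (neighbor
joining on JC69 distances for the synthetic path), the rooting cascade, the
bipartition scan with paralog splitting, and cross-rooting merging.  When the
generating truth is available the result is scored as a confusion matrix and
false-positive / false-negative percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import screen as screen_mod
from . import trees
from .scan import (
    BenchmarkResult,
    benchmark_rates,
    merge_across_rootings,
    rooting_cascade,
    scan_tree,
    split_paralogs,
)
from .simulate import BenchmarkSet
from .taxonomy import EUKARYOTE, TaxonomyMap
from .trees import SaturationError, jc69_distance, nj_tree

__all__ = ["PipelineResult", "screen_and_scan", "score_against_truth"]

#: distance assigned to JC69-saturated pairs when building synthetic gene trees
SATURATION_DISTANCE = 5.0


@dataclass
class PipelineResult:
    """Outputs of one screen+scan run over a benchmark set."""

    candidates: set
    clusters: list
    detected: list                      # MitoDerivedFamily objects
    counts: dict = field(default_factory=dict)
    benchmark: Optional[BenchmarkResult] = None
    confusion: Optional[dict] = None


def _distance_matrix(seqs: dict):
    labels = sorted(seqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = jc69_distance(seqs[labels[i]], seqs[labels[j]])
            except SaturationError:
                d = SATURATION_DISTANCE
            D[i, j] = D[j, i] = d
    return labels, D


def screen_and_scan(
    bench: BenchmarkSet,
    e_cutoff_screen: float = 1e-4,
    top_n: int = 5,
    e_cutoff_family: float = 1e-15,
    min_euk: int = 2,
    min_alpha: int = 2,
) -> PipelineResult:
    """Run the full candidate-to-family pipeline on a synthetic benchmark set.

    Gene trees for the scan are rebuilt from the simulated alignments
    (neighbor joining on JC69 distances), so the whole decision chain —
    screening, clustering, tree building, rooting, scanning — is exercised,
    not just the scan.  Clusters with fewer than 3 members are skipped (no
    tree can be built).
    """
    taxonomy = bench.taxonomy
    candidates = screen_mod.filter_candidates(
        bench.hits, taxonomy, e_cutoff=e_cutoff_screen, top_n=top_n)
    counts = {"genes_with_hits": len({h.query for h in bench.hits}),
              "candidates": len(candidates)}
    detected = []
    clusters = []
    if candidates:
        graph = screen_mod.build_family_graph(candidates, bench.hits,
                                              e_cutoff=e_cutoff_family)
        clusters = screen_mod.mcl_cluster(graph)
        clusters = screen_mod.retain_families(clusters, taxonomy,
                                              min_euk_lineages=min_euk)
        counts["families_clustered"] = len(clusters)
        all_seqs = {}
        for fam_seqs in bench.sequences.values():
            all_seqs.update(fam_seqs)
        for k, cluster in enumerate(clusters):
            members = sorted(cluster)
            if len(members) < 3:
                continue
            labels, D = _distance_matrix({m: all_seqs[m] for m in members})
            gtree = nj_tree(labels, D)
            rootings = rooting_cascade(gtree, taxonomy)
            per_rooting = []
            for r, rooted in enumerate(rootings):
                clades = scan_tree(rooted, taxonomy, min_euk=min_euk,
                                   min_alpha=min_alpha)
                per_rooting.append(split_paralogs(rooted, clades, taxonomy,
                                                  tree_id=f"cl{k:04d}.r{r}",
                                                  min_euk=min_euk))
            detected.extend(merge_across_rootings(per_rooting))
    counts["families_detected"] = len(detected)
    return PipelineResult(candidates=candidates, clusters=clusters,
                          detected=detected, counts=counts)


def score_against_truth(result: PipelineResult, bench: BenchmarkSet) -> PipelineResult:
    """Score detected families against the generator truth.

    An input family counts as recovered when some detected family contains at
    least two of its eukaryotic genes inside a qualifying clade; a negative
    input family is flagged when any of its eukaryotic genes appears in a
    detected family's members.  FP% and FN% follow the benchmark convention
    (percent of negatives flagged, percent of positives missed).
    """
    fam_of_gene = {}
    for fam_id, seqs in bench.sequences.items():
        for g in seqs:
            fam_of_gene[g] = fam_id
    detected_euk_by_input: dict[str, int] = {}
    for det in result.detected:
        for g, cls in det.members.items():
            if cls == EUKARYOTE:
                src = fam_of_gene.get(g)
                if src is not None:
                    detected_euk_by_input[src] = detected_euk_by_input.get(src, 0) + 1
    positives = [f for f, k in bench.truth.items() if k == "mito-derived"]
    negatives = [f for f, k in bench.truth.items() if k != "mito-derived"]
    recovered = [f for f in positives if detected_euk_by_input.get(f, 0) >= 2]
    flagged = [f for f in negatives if detected_euk_by_input.get(f, 0) >= 1]
    confusion = {
        "true_positive": len(recovered),
        "false_negative": len(positives) - len(recovered),
        "false_positive": len(flagged),
        "true_negative": len(negatives) - len(flagged),
        "by_kind": {},
    }
    for kind in sorted(set(bench.truth.values())):
        fams = [f for f, k in bench.truth.items() if k == kind]
        det = [f for f in fams if detected_euk_by_input.get(f, 0) >=
               (2 if kind == "mito-derived" else 1)]
        confusion["by_kind"][kind] = {"total": len(fams), "detected": len(det)}
    result.benchmark = benchmark_rates(
        n_negative_screened=len(negatives),
        n_negative_flagged=len(flagged),
        n_positive_total=len(positives),
        n_positive_recovered=len(recovered),
    )
    result.confusion = confusion
    return result
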