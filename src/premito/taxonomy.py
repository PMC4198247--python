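"""Taxon classification of tree leaves.

Every leaf of a gene tree is assigned to one of a small set of disjoint taxon
classes (eukaryote-nuclear, mitochondrial, alphaproteobacterial, other
bacteria, archaeal, Deinococcus–Thermus, outgroup) and, optionally, a lineage
identifier (the eukaryotic phylum or the bacterial species) used by the
"at least two lineages / two species" counting rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

EUKARYOTE = "eukaryote-nuclear"
MITOCHONDRIAL = "mitochondrial"
ALPHA = "alphaproteobacterial"
OTHER_BACTERIAL = "other-bacterial"
ARCHAEAL = "archaeal"
DEINOCOCCUS = "deinococcus-thermus"
OUTGROUP = "outgroup"

CLASSES = frozenset({
    EUKARYOTE, MITOCHONDRIAL, ALPHA, OTHER_BACTERIAL, ARCHAEAL, DEINOCOCCUS, OUTGROUP,
})

#: classes counted as "mitochondria-like" partners of eukaryotic genes in a clade
CLADE_PARTNER_CLASSES = frozenset({EUKARYOTE, MITOCHONDRIAL, ALPHA})


@dataclass
class TaxonomyMap:
    """Mapping leaf label -> taxon class, with optional lineage labels.

    ``lineages`` defaults to the leaf label itself, which makes every sequence
    its own lineage; callers that need phylum/species-level counting supply an
    explicit mapping.
    """

    classes: dict[str, str]
    lineages: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in CLASSES}
        if bad:
            raise ValueError(f"unknown taxon classes: {sorted(bad)}")

    def class_of(self, label: str) -> str:
        try:
            return self.classes[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} has no taxonomy entry") from None

    def lineage_of(self, label: str) -> str:
        return self.lineages.get(label, label)

    def has(self, label: str) -> bool:
        return label in self.classes

    def labels_of_class(self, cls: str) -> set[str]:
        return {k for k, v in self.classes.items() if v == cls}

    def resolve_all(self, labels: Iterable[str]) -> None:
        missing = [l for l in labels if l not in self.classes]
        if missing:
            raise KeyError(f"leaves without taxonomy entries: {sorted(missing)[:10]}")

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        """Read a 2- or 3-column TSV: leaf_label, class[, lineage]."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        classes = dict(zip(df[0], df[1]))
        lineages = dict(zip(df[0], df[2])) if df.shape[1] > 2 else {}
        return cls(classes=classes, lineages=lineages)

    def to_tsv(self, path) -> None:
        rows = [(k, v, self.lineage_of(k)) for k, v in sorted(self.classes.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
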