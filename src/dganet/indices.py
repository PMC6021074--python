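"""Set-overlap association indices used as edge-level disease relationships.

Each index compares the disease sets Dg1 and Dg2 of two interacting genes
and returns a value in [0, 1]:

    jaccard   |Dg1 n Dg2| / |Dg1 u Dg2|
    simpson   |Dg1 n Dg2| / min(|Dg1|, |Dg2|)
    geometric |Dg1 n Dg2|^2 / (|Dg1| * |Dg2|)
    cosine    |Dg1 n Dg2| / sqrt(|Dg1| * |Dg2|)

Any index involving an empty disease set returns 0: the analysis set
normally excludes unannotated genes, but cross-validation folds can
transiently empty a training-fold disease set, and "no known disease"
carries no evidence of relatedness.  For all inputs the chain
jaccard <= cosine <= simpson holds, and geometric == cosine**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Callable, Iterator

from .network_io import AnnotationMap, WeightedNetwork

__all__ = [
    "jaccard",
    "simpson",
    "geometric",
    "cosine",
    "INDICES",
    "RelationshipTable",
    "compute_relationships",
]

DiseaseSet = AbstractSet[str]


def jaccard(d1: DiseaseSet, d2: DiseaseSet) -> float:
    """Shared diseases over the union of both disease sets."""
    union = len(d1 | d2)
    if union == 0:
        return 0.0
    return len(d1 & d2) / union


def simpson(d1: DiseaseSet, d2: DiseaseSet) -> float:
    """Shared diseases over the smaller disease set."""
    if not d1 or not d2:
        return 0.0
    return len(d1 & d2) / min(len(d1), len(d2))


def geometric(d1: DiseaseSet, d2: DiseaseSet) -> float:
    """Squared shared-disease count over the product of set sizes."""
    if not d1 or not d2:
        return 0.0
    inter = len(d1 & d2)
    return inter * inter / (len(d1) * len(d2))


def cosine(d1: DiseaseSet, d2: DiseaseSet) -> float:
    """Shared diseases over the geometric mean of set sizes (Ochiai)."""
    if not d1 or not d2:
        return 0.0
    return len(d1 & d2) / math.sqrt(len(d1) * len(d2))


INDICES: dict[str, Callable[[DiseaseSet, DiseaseSet], float]] = {
    "jaccard": jaccard,
    "simpson": simpson,
    "geometric": geometric,
    "cosine": cosine,
}


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


@dataclass
class RelationshipTable:
    """Per-edge disease-relationship value in [0, 1], symmetric in the genes."""

    values: dict[tuple[str, str], float]
    index_name: str

    def get(self, u: str, v: str) -> float:
        try:
            return self.values[_edge_key(u, v)]
        except KeyError:
            raise KeyError(
                f"no relationship value for edge ({u}, {v}); the relationship "
                "table does not cover this network edge"
            ) from None

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self.values.items())

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"# index_name: {self.index_name}\n")
            fh.write("gene1\tgene2\trelationship\n")
            for (u, v), r in sorted(self.values.items()):
                fh.write(f"{u}\t{v}\t{r:.6f}\n")


def compute_relationships(
    net: WeightedNetwork, ann: AnnotationMap, index_name: str = "jaccard"
) -> RelationshipTable:
    """Compute the disease relationship of every network edge.

    Genes absent from the annotation map contribute the empty disease set
    (relationship 0 on their edges).
    """
    try:
        fn = INDICES[index_name]
    except KeyError:
        raise ValueError(
            f"unknown association index {index_name!r}; choose from "
            f"{sorted(INDICES)}"
        ) from None
    values = {
        _edge_key(u, v): fn(ann.diseases_of(u), ann.diseases_of(v))
        for u, v, _ in net.edges()
    }
    return RelationshipTable(values, index_name)
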