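"""Core association scoring: k nearest neighbors and score aggregation.

For a query gene g the scorer selects the k nearest direct interactors by
ascending edge weight (ties broken lexicographically by gene symbol), takes
the union D of the neighbors' disease sets as the candidate diseases, and
for each candidate d aggregates the disease relationship r(g, g_nn) over the
neighbors annotated with d:

    score(g, d) = 100 * sum_{g_nn : d in Dg_nn} r(g, g_nn) / n_nbr

The denominator ``n_nbr`` is the number of selected neighbors, i.e.
min(k, degree(g)) in the default "effective" mode; the "literal_k" mode
divides by k itself.  Scores therefore lie in [0, 100], and only the
neighbors' annotations — never the query's own — enter the aggregation.

In complex mode the neighborhood of a gene is the union of its co-members
over all protein complexes containing it, and k plays no role.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .indices import INDICES, RelationshipTable
from .network_io import AnnotationMap, ComplexTable, WeightedNetwork

__all__ = [
    "NeighborSet",
    "ScoreTable",
    "nearest_neighbors",
    "candidate_diseases",
    "score_pair",
    "score_all",
    "score_all_complex",
]

DENOMINATOR_MODES = ("effective", "literal_k")


@dataclass(frozen=True)
class NeighborSet:
    """The selected nearest neighbors of a query gene, ascending by weight."""

    query: str
    members: tuple[tuple[str, float], ...]
    k_requested: int


def nearest_neighbors(net: WeightedNetwork, query: str, k: int) -> NeighborSet:
    """Select the min(k, degree) nearest direct interactors of ``query``."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    if query not in net:
        raise KeyError(f"gene {query!r} is not a network node")
    ranked = sorted(
        ((net.weight(query, n), n) for n in net.neighbors(query))
    )
    members = tuple((n, w) for w, n in ranked[:k])
    return NeighborSet(query, members, k)


def candidate_diseases(nn: NeighborSet, ann: AnnotationMap) -> frozenset[str]:
    """Union of the neighbors' disease sets (Dg of the query is not used)."""
    out: set[str] = set()
    for gene, _ in nn.members:
        out |= ann.diseases_of(gene)
    return frozenset(out)


def _denominator(nn: NeighborSet, mode: str) -> int:
    if mode not in DENOMINATOR_MODES:
        raise ValueError(
            f"unknown denominator mode {mode!r}; choose from {DENOMINATOR_MODES}"
        )
    return len(nn.members) if mode == "effective" else nn.k_requested


def score_pair(
    nn: NeighborSet,
    rel: RelationshipTable,
    ann: AnnotationMap,
    disease: str,
    denominator_mode: str = "effective",
) -> float:
    """Association score of (query, disease) from one neighbor set."""
    denom = _denominator(nn, denominator_mode)
    if denom == 0:
        return 0.0
    total = 0.0
    for gene, _ in nn.members:
        if disease in ann.diseases_of(gene):
            total += rel.get(nn.query, gene)
    return 100.0 * total / denom


@dataclass
class ScoreTable:
    """(gene, disease) -> association score in [0, 100], plus run parameters."""

    scores: dict[tuple[str, str], float]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (g, d), s in self.scores.items():
            yield g, d, s

    def get(self, gene: str, disease: str, default: float = 0.0) -> float:
        return self.scores.get((gene, disease), default)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.scores.items())
        return pd.DataFrame(
            [(g, d, s) for (g, d), s in rows],
            columns=["gene", "diseaseId", "score"],
        )

    def to_tsv(self, path, gold: AnnotationMap | None = None) -> None:
        """Write records as TSV; gold membership flagged when gold is given."""
        with open(path, "wt") as fh:
            for key, value in sorted(self.params.items()):
                fh.write(f"# {key}: {value}\n")
            fh.write("gene\tdiseaseId\tdiseaseName\tscore\tknown_in_gold\n")
            for (g, d), s in sorted(self.scores.items()):
                name = gold.name_of(d) if gold is not None else ""
                known = int(gold is not None and (g, d) in gold)
                fh.write(f"{g}\t{d}\t{name}\t{s:.4f}\t{known}\n")


def score_all(
    net: WeightedNetwork,
    rel: RelationshipTable,
    ann: AnnotationMap,
    k: int,
    denominator_mode: str = "effective",
) -> ScoreTable:
    """Score every (gene, candidate disease) pair over the whole network.

    Candidates whose aggregated relationship is zero are still recorded
    (with score 0): they were proposed by the neighborhood even though no
    evidence accumulated.
    """
    scores: dict[tuple[str, str], float] = {}
    for gene in sorted(net.nodes()):
        nn = nearest_neighbors(net, gene, k)
        if not nn.members:
            continue
        denom = _denominator(nn, denominator_mode)
        acc: dict[str, float] = defaultdict(float)
        for nbr, _ in nn.members:
            diseases = ann.diseases_of(nbr)
            if not diseases:
                continue
            r = rel.get(gene, nbr)
            for d in diseases:
                acc[d] += r
        for d, total in acc.items():
            scores[(gene, d)] = 100.0 * total / denom
    return ScoreTable(
        scores,
        params={
            "k": k,
            "index_name": rel.index_name,
            "neighborhood_mode": "knn",
            "denominator_mode": denominator_mode,
        },
    )


def score_all_complex(
    complexes: ComplexTable,
    ann: AnnotationMap,
    index_name: str = "jaccard",
) -> ScoreTable:
    """Score with complex co-membership as the neighborhood (no k).

    The neighborhood of a gene is the union of its co-members over all
    complexes containing it; the denominator is the size of that set, and
    relationships are computed by the chosen index on the implied
    co-membership pairs.
    """
    try:
        fn = INDICES[index_name]
    except KeyError:
        raise ValueError(
            f"unknown association index {index_name!r}; choose from "
            f"{sorted(INDICES)}"
        ) from None
    scores: dict[tuple[str, str], float] = {}
    for gene in sorted(complexes.genes()):
        nbrs = complexes.neighbors_of(gene)
        if not nbrs:
            continue
        dq = ann.diseases_of(gene)
        acc: dict[str, float] = defaultdict(float)
        for nbr in nbrs:
            diseases = ann.diseases_of(nbr)
            if not diseases:
                continue
            r = fn(dq, diseases)
            for d in diseases:
                acc[d] += r
        for d, total in acc.items():
            scores[(gene, d)] = 100.0 * total / len(nbrs)
    return ScoreTable(
        scores,
        params={"index_name": index_name, "neighborhood_mode": "complex"},
    )
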