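"""Readers and containers for the three tabular dialects the pipeline consumes.

The protein interaction network arrives as a STRING-style edge list
(``protein1  protein2  combined_score`` with scores on an integer 0-1000
scale), the gene-disease gold standard as a DisGeNET-style table
(``geneSymbol  diseaseId  [diseaseName]``), and optional protein-complex
membership as a CORUM-style table (``complexId  members`` with a
semicolon-separated member list).  All readers accept plain or
gzip-compressed files.

Edges are kept only when their confidence strictly exceeds a threshold
(default 900), and each retained edge carries a distance-like weight
obtained by a strictly decreasing transform of the confidence, so that
"nearest" neighbor means "highest confidence" interactor.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "AnnotationMap",
    "ComplexTable",
    "NetworkFormatError",
    "EmptyNetworkError",
    "SchemaError",
    "WEIGHT_TRANSFORMS",
    "read_string_edges",
    "write_string_edges",
    "read_annotations",
    "read_aliases",
    "read_complexes",
    "restrict_to_annotated",
]


class NetworkFormatError(ValueError):
    """A row of an input file could not be parsed."""


class EmptyNetworkError(ValueError):
    """No edges survived the confidence filter."""


class SchemaError(ValueError):
    """An input table lacks a required column."""


#: Strictly decreasing confidence -> weight transforms.  k-NN search only
#: uses the induced ranking, which all three share; the default keeps
#: weights inside (0, 1).
WEIGHT_TRANSFORMS = {
    "one_minus": lambda c: 1.0 - c / 1000.0,
    "complement": lambda c: 1000.0 - float(c),
    "reciprocal": lambda c: 1.0 / c,
}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class WeightedNetwork:
    """Undirected protein interaction network with per-edge confidence.

    Thin wrapper around :class:`networkx.Graph`; every edge carries an
    integer ``confidence`` in (0, 1000] and a derived real ``weight`` > 0.
    """

    graph: nx.Graph
    transform: str = "one_minus"

    @classmethod
    def from_confidences(
        cls, confidences: Mapping[tuple[str, str], int], transform: str = "one_minus"
    ) -> "WeightedNetwork":
        if transform not in WEIGHT_TRANSFORMS:
            raise ValueError(
                f"unknown weight transform {transform!r}; "
                f"choose from {sorted(WEIGHT_TRANSFORMS)}"
            )
        f = WEIGHT_TRANSFORMS[transform]
        g = nx.Graph()
        for (a, b), c in confidences.items():
            if a == b:
                continue
            g.add_edge(a, b, confidence=int(c), weight=float(f(int(c))))
        return cls(g, transform)

    # -- node/edge access -------------------------------------------------
    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def nodes(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    def neighbors(self, gene: str) -> Iterator[str]:
        return self.graph.neighbors(gene)

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def confidence(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["confidence"]

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Yield (gene1, gene2, confidence) triples."""
        for u, v, data in self.graph.edges(data=True):
            yield u, v, data["confidence"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- derived networks -------------------------------------------------
    def induced(self, genes: Iterable[str], drop_isolated: bool = True):
        """Subgraph on ``genes``; returns (network, n_isolated_dropped)."""
        sub = self.graph.subgraph(set(genes)).copy()
        n_dropped = 0
        if drop_isolated:
            isolated = [n for n in sub.nodes if sub.degree(n) == 0]
            n_dropped = len(isolated)
            sub.remove_nodes_from(isolated)
        return WeightedNetwork(sub, self.transform), n_dropped

    def without_nodes(self, genes: Iterable[str]) -> "WeightedNetwork":
        sub = self.graph.copy()
        sub.remove_nodes_from(list(genes))
        return WeightedNetwork(sub, self.transform)


class AnnotationMap:
    """Bipartite gene <-> disease association map (the gold standard).

    Supports lookup in both directions: ``diseases_of(gene)`` returns the
    disease set Dg of a gene, ``genes_of(disease)`` the annotated gene set.
    Genes absent from the map have an empty disease set.
    """

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        disease_names: Mapping[str, str] | None = None,
    ):
        self._pairs: set[tuple[str, str]] = set()
        self._by_gene: dict[str, set[str]] = {}
        self._by_disease: dict[str, set[str]] = {}
        for gene, disease in pairs:
            if (gene, disease) in self._pairs:
                continue
            self._pairs.add((gene, disease))
            self._by_gene.setdefault(gene, set()).add(disease)
            self._by_disease.setdefault(disease, set()).add(gene)
        self.disease_names: dict[str, str] = dict(disease_names or {})

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._by_gene)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(self._by_disease)

    def diseases_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._by_gene.get(gene, ()))

    def genes_of(self, disease: str) -> frozenset[str]:
        return frozenset(self._by_disease.get(disease, ()))

    def name_of(self, disease: str) -> str:
        return self.disease_names.get(disease, "")

    # -- derived maps -----------------------------------------------------
    def without_pairs(self, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        drop = set(pairs)
        return AnnotationMap(
            (p for p in self._pairs if p not in drop), self.disease_names
        )

    def restricted_to_genes(self, genes: Iterable[str]) -> "AnnotationMap":
        keep = set(genes)
        return AnnotationMap(
            (p for p in self._pairs if p[0] in keep), self.disease_names
        )


@dataclass
class ComplexTable:
    """Protein-complex membership; co-members act as mutual neighbors."""

    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return out

    def neighbors_of(self, gene: str) -> frozenset[str]:
        """Union of co-members over every complex containing ``gene``."""
        out: set[str] = set()
        for members in self.complexes.values():
            if gene in members:
                out |= members
        out.discard(gene)
        return frozenset(out)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_aliases(path) -> dict[str, str]:
    """Two-column TSV mapping external protein IDs to gene symbols."""
    aliases: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected two columns, got {len(parts)}"
                )
            aliases[parts[0]] = parts[1]
    return aliases


def read_string_edges(
    path,
    confidence_threshold: int = 900,
    transform: str = "one_minus",
    aliases: Mapping[str, str] | None = None,
) -> WeightedNetwork:
    """Read a STRING-dialect edge list, keeping edges with score > threshold.

    The inequality is strict: a row with ``combined_score`` exactly equal to
    the threshold is dropped.  Duplicate unordered pairs keep the maximum
    confidence; self-loops are discarded.
    """
    if not 0 <= confidence_threshold < 1000:
        raise ValueError("confidence_threshold must be in [0, 1000)")
    best: dict[tuple[str, str], int] = {}
    with _open_text(path) as fh:
        header = fh.readline().split()
        if not header:
            raise NetworkFormatError(f"{path}: empty file")
        try:
            i1 = header.index("protein1")
            i2 = header.index("protein2")
            ic = header.index("combined_score")
        except ValueError:
            raise SchemaError(
                f"{path}: expected columns protein1/protein2/combined_score, "
                f"found {header}"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            try:
                a, b, score = parts[i1], parts[i2], int(parts[ic])
            except (IndexError, ValueError) as exc:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: malformed row {line.strip()!r}"
                ) from exc
            if not 0 <= score <= 1000:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: combined_score {score} outside [0, 1000]"
                )
            if aliases is not None:
                a = aliases.get(a, a)
                b = aliases.get(b, b)
            if a == b or score <= confidence_threshold:
                continue
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, -1):
                best[key] = score
    if not best:
        raise EmptyNetworkError(
            f"{path}: empty network after filtering at confidence > "
            f"{confidence_threshold}"
        )
    return WeightedNetwork.from_confidences(best, transform)


def write_string_edges(net: WeightedNetwork, path) -> None:
    """Write the network back out in the edge-list dialect (sorted rows)."""
    rows = sorted(
        (min(u, v), max(u, v), c) for u, v, c in net.edges()
    )
    with open(path, "wt") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, c in rows:
            fh.write(f"{a}\t{b}\t{c}\n")


def read_annotations(path) -> AnnotationMap:
    """Read a DisGeNET-dialect gene-disease table into an AnnotationMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"geneSymbol", "diseaseId"}
    if not required <= set(df.columns):
        raise SchemaError(
            f"{path}: required columns {sorted(required)}, found {list(df.columns)}"
        )
    df = df.dropna(subset=["geneSymbol", "diseaseId"])
    names: dict[str, str] = {}
    if "diseaseName" in df.columns:
        named = df.dropna(subset=["diseaseName"])
        names = dict(zip(named["diseaseId"], named["diseaseName"]))
    ann = AnnotationMap(zip(df["geneSymbol"], df["diseaseId"]), names)
    if len(ann) == 0:
        logger.warning("%s: no annotation pairs read", path)
    return ann


def read_complexes(path) -> ComplexTable:
    """Read a CORUM-dialect complex table; singleton complexes are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"complexId", "members"}
    if not required <= set(df.columns):
        raise SchemaError(
            f"{path}: required columns {sorted(required)}, found {list(df.columns)}"
        )
    merged: dict[str, set[str]] = {}
    for i, row in df.iterrows():
        raw = row["members"]
        if pd.isna(raw) or not str(raw).strip():
            raise NetworkFormatError(
                f"{path}: line {i + 2}: unparsable member list {raw!r}"
            )
        members = {m.strip() for m in str(raw).split(";") if m.strip()}
        if not members:
            raise NetworkFormatError(
                f"{path}: line {i + 2}: unparsable member list {raw!r}"
            )
        merged.setdefault(row["complexId"], set()).update(members)
    complexes: dict[str, frozenset[str]] = {}
    for cid, members in merged.items():
        if len(members) < 2:
            logger.warning("complex %s has a single member; dropped", cid)
            continue
        complexes[cid] = frozenset(members)
    return ComplexTable(complexes)


def restrict_to_annotated(
    net: WeightedNetwork, ann: AnnotationMap
) -> tuple[WeightedNetwork, AnnotationMap]:
    """Induce the network on genes with at least one known disease.

    Genes that become isolated after induction are dropped (and counted in
    the log); the annotation map is restricted to the surviving network
    genes, so annotation pairs of genes absent from the network leave the
    analysis set.
    """
    annotated = {g for g in net.nodes() if ann.diseases_of(g)}
    sub, n_isolated = net.induced(annotated)
    if n_isolated:
        logger.info(
            "restrict_to_annotated: dropped %d isolated annotated genes",
            n_isolated,
        )
    kept_genes = set(sub.nodes())
    return sub, ann.restricted_to_genes(kept_genes)
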