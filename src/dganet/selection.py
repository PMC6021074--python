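"""Association coverage and post-hoc candidate selection.

The association coverage of a gene is the percentage of its predicted
(nonzero-score) disease pairs that are present in the gold standard; disease
coverage is defined the same way over a disease's predicted gene pairs.
High coverage means the neighborhood evidence for that entity is mostly
corroborated, so its remaining (novel) predictions are more credible.

Two selection filters are provided: gene selection keeps pairs whose gene
has coverage >= min_coverage and score >= min_score (defaults 70 and 40,
inclusive), disease selection keeps pairs whose disease has coverage >
min_coverage and score > min_score (defaults 40 and 20, strict).  Entities
with no nonzero-score predictions have no coverage entry and are treated as
coverage 0 by the filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .network_io import AnnotationMap
from .scoring import ScoreTable

__all__ = [
    "Coverage",
    "CoverageTable",
    "SelectedPair",
    "coverage",
    "select_by_gene",
    "select_by_disease",
    "novel_pairs",
    "selection_tsv",
]


@dataclass(frozen=True)
class Coverage:
    entity: str
    value: float  # percentage in [0, 100]
    n_gold: int
    n_predicted: int


@dataclass
class CoverageTable:
    kind: Literal["gene", "disease"]
    entries: dict[str, Coverage]

    def value_of(self, entity: str) -> float:
        cov = self.entries.get(entity)
        return cov.value if cov is not None else 0.0


@dataclass(frozen=True)
class SelectedPair:
    gene: str
    disease: str
    score: float
    coverage: float
    known: bool


def coverage(
    st: ScoreTable, gold: AnnotationMap, kind: Literal["gene", "disease"]
) -> CoverageTable:
    """Per-entity coverage over the entity's predicted (score > 0) pairs."""
    if kind not in ("gene", "disease"):
        raise ValueError(f"kind must be 'gene' or 'disease', got {kind!r}")
    n_pred: dict[str, int] = {}
    n_gold: dict[str, int] = {}
    for (g, d), s in st.scores.items():
        if s <= 0.0:
            continue
        entity = g if kind == "gene" else d
        n_pred[entity] = n_pred.get(entity, 0) + 1
        if (g, d) in gold:
            n_gold[entity] = n_gold.get(entity, 0) + 1
    entries = {
        e: Coverage(e, 100.0 * n_gold.get(e, 0) / n, n_gold.get(e, 0), n)
        for e, n in n_pred.items()
    }
    return CoverageTable(kind, entries)


def select_by_gene(
    st: ScoreTable,
    cov: CoverageTable,
    gold: AnnotationMap,
    min_coverage: float = 70.0,
    min_score: float = 40.0,
) -> list[SelectedPair]:
    """Pairs whose gene coverage and score meet the thresholds (inclusive)."""
    if cov.kind != "gene":
        raise ValueError("select_by_gene needs a gene-kind coverage table")
    out = [
        SelectedPair(g, d, s, cov.value_of(g), (g, d) in gold)
        for (g, d), s in st.scores.items()
        if cov.value_of(g) >= min_coverage and s >= min_score
    ]
    return sorted(out, key=lambda p: (-p.score, p.gene, p.disease))


def select_by_disease(
    st: ScoreTable,
    cov: CoverageTable,
    gold: AnnotationMap,
    min_coverage: float = 40.0,
    min_score: float = 20.0,
) -> list[SelectedPair]:
    """Pairs whose disease coverage and score exceed the thresholds (strict)."""
    if cov.kind != "disease":
        raise ValueError("select_by_disease needs a disease-kind coverage table")
    out = [
        SelectedPair(g, d, s, cov.value_of(d), (g, d) in gold)
        for (g, d), s in st.scores.items()
        if cov.value_of(d) > min_coverage and s > min_score
    ]
    return sorted(out, key=lambda p: (-p.score, p.gene, p.disease))


def novel_pairs(
    selected: Iterable[SelectedPair], gold: AnnotationMap
) -> list[SelectedPair]:
    """Selected pairs absent from the gold standard, highest score first."""
    out = [p for p in selected if (p.gene, p.disease) not in gold]
    return sorted(out, key=lambda p: (-p.score, p.gene, p.disease))


def selection_tsv(
    pairs: Iterable[SelectedPair], path, gold: AnnotationMap | None = None
) -> None:
    with open(path, "wt") as fh:
        fh.write("gene\tdiseaseId\tdiseaseName\tscore\tcoverage\tknown_in_gold\n")
        for p in pairs:
            name = gold.name_of(p.disease) if gold is not None else ""
            fh.write(
                f"{p.gene}\t{p.disease}\t{name}\t{p.score:.4f}\t"
                f"{p.coverage:.4f}\t{int(p.known)}\n"
            )
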