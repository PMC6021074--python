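"""Synthetic benchmark generator with planted disease modules.

The generator emulates the statistical structure the scorer assumes: genes
working in the same densely-wired network module tend to be annotated to
the same diseases.  It emits the three input dialects (edge list,
annotation table, complex table) plus a hidden-truth file of withheld
annotations, so the whole pipeline is testable without external downloads.

Layout: the first ``n_modules * module_size`` genes form contiguous modules
wired with probability ``p_intra`` (confidences from ``conf_intra``); every
other gene pair is wired with background probability ``p_inter``
(``conf_inter``).  Each module owns ``annot_per_module`` diseases, and its
genes are split into two subgroups, each annotated to half of the module's
diseases.  The split matters for honest null comparisons: a candidate from
the *other* subgroup has about as many annotated carrier neighbors as a
withheld true pair, so after relationship shuffling the two are
indistinguishable (baseline AUC near 0.5), while the true relationships —
high within a subgroup, zero across — separate them cleanly.

A ``dropout`` fraction of the true (gene, disease) pairs is withheld from
the emitted gold standard into the hidden-truth file; these are the
recoverable positives for evaluation.  All emitted confidences exceed the
default filter threshold of 900 so the generator composes with default
filtering; ``decoy_edges`` adds sub-threshold edges to exercise the filter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "worked_example"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 300
    n_modules: int = 10
    module_size: int = 12
    n_diseases: int = 60
    annot_per_module: int = 6
    p_intra: float = 0.6
    p_inter: float = 0.01
    conf_intra: tuple[int, int] = (950, 1000)
    conf_inter: tuple[int, int] = (901, 1000)
    dropout: float = 0.3
    seed: int = 1
    decoy_edges: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_inter < self.p_intra <= 1.0:
            raise ValueError("need 0 <= p_inter < p_intra <= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if self.annot_per_module < 2:
            raise ValueError("annot_per_module must be >= 2")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit into n_genes")
        if self.n_modules * self.annot_per_module > self.n_diseases:
            raise ValueError("module disease signatures do not fit into n_diseases")
        for lo, hi in (self.conf_intra, self.conf_inter):
            if not 900 < lo <= hi <= 1000:
                raise ValueError(
                    "confidence ranges must lie within (900, 1000] so emitted "
                    "edges survive the default filter"
                )
        if self.decoy_edges < 0:
            raise ValueError("decoy_edges must be >= 0")


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    network_path: Path
    annotation_path: Path
    hidden_path: Path
    complex_path: Path
    manifest_path: Path
    truth_pairs: frozenset[tuple[str, str]]
    emitted_pairs: frozenset[tuple[str, str]]
    hidden_pairs: frozenset[tuple[str, str]]


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _disease_name(i: int) -> str:
    return f"D{i:04d}"


def generate(spec: SyntheticSpec, out_dir) -> SyntheticBundle:
    """Write the four synthetic input files; fully deterministic per seed."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = [_gene_name(i) for i in range(spec.n_genes)]
    n_planted = spec.n_modules * spec.module_size

    def module_of(i: int) -> int | None:
        return i // spec.module_size if i < n_planted else None

    # ---- network -------------------------------------------------------
    edges: list[tuple[str, str, int]] = []
    lo_in, hi_in = spec.conf_intra
    lo_out, hi_out = spec.conf_inter
    for i, j in itertools.combinations(range(spec.n_genes), 2):
        intra = module_of(i) is not None and module_of(i) == module_of(j)
        p = spec.p_intra if intra else spec.p_inter
        if rng.random() < p:
            lo, hi = (lo_in, hi_in) if intra else (lo_out, hi_out)
            conf = int(rng.integers(lo, hi + 1))
            edges.append((genes[i], genes[j], conf))
    existing = {(a, b) for a, b, _ in edges}
    n_decoy = 0
    while n_decoy < spec.decoy_edges:
        i, j = sorted(rng.choice(spec.n_genes, 2, replace=False))
        key = (genes[i], genes[j])
        if key in existing:
            continue
        existing.add(key)
        edges.append((genes[i], genes[j], int(rng.integers(100, 901))))
        n_decoy += 1

    # ---- annotations with two disease-signature subgroups per module ---
    half = spec.annot_per_module // 2
    truth: list[tuple[str, str]] = []
    for m in range(spec.n_modules):
        base = m * spec.annot_per_module
        sig_a = [_disease_name(base + t) for t in range(half)]
        sig_b = [
            _disease_name(base + t) for t in range(half, spec.annot_per_module)
        ]
        member_idx = list(range(m * spec.module_size, (m + 1) * spec.module_size))
        order = rng.permutation(len(member_idx))
        split = len(member_idx) // 2
        group_a = {member_idx[t] for t in order[:split]}
        for i in member_idx:
            for d in (sig_a if i in group_a else sig_b):
                truth.append((genes[i], d))
    truth.sort()
    hidden_mask = rng.random(len(truth)) < spec.dropout
    hidden = frozenset(p for p, h in zip(truth, hidden_mask) if h)
    emitted = frozenset(p for p, h in zip(truth, hidden_mask) if not h)

    # ---- write files ---------------------------------------------------
    network_path = out_dir / "network.tsv"
    with open(network_path, "wt") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, c in sorted(edges):
            fh.write(f"{a}\t{b}\t{c}\n")

    def _write_pairs(path: Path, pairs) -> None:
        with open(path, "wt") as fh:
            fh.write("geneSymbol\tdiseaseId\tdiseaseName\n")
            for g, d in sorted(pairs):
                fh.write(f"{g}\t{d}\tsynthetic disease {d}\n")

    annotation_path = out_dir / "annotations.tsv"
    hidden_path = out_dir / "hidden_truth.tsv"
    _write_pairs(annotation_path, emitted)
    _write_pairs(hidden_path, hidden)

    complex_path = out_dir / "complexes.tsv"
    with open(complex_path, "wt") as fh:
        fh.write("complexId\tmembers\n")
        for m in range(spec.n_modules):
            members = ";".join(
                genes[i]
                for i in range(m * spec.module_size, (m + 1) * spec.module_size)
            )
            fh.write(f"C{m:03d}\t{members}\n")

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "wt") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "n_edges": len(edges),
                "n_truth_pairs": len(truth),
                "n_hidden_pairs": len(hidden),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return SyntheticBundle(
        spec=spec,
        network_path=network_path,
        annotation_path=annotation_path,
        hidden_path=hidden_path,
        complex_path=complex_path,
        manifest_path=manifest_path,
        truth_pairs=frozenset(truth),
        emitted_pairs=emitted,
        hidden_pairs=hidden,
    )


# ---------------------------------------------------------------------------
# hand-checked worked example
# ---------------------------------------------------------------------------

#: Expected association scores for the query gene of the worked example
#: (jaccard relationships, k = 4), computed by hand:
#: r(PQ,P1)=1/5, r(PQ,P2)=2/5, r(PQ,P3)=3/5, r(PQ,P4)=4/5; all four
#: neighbors carry DSH -> 100*(0.2+0.4+0.6+0.8)/4 = 50, DX1 is carried by
#: P2..P4 -> 45, DX2 by P3,P4 -> 35, DX3 by P4 -> 20.
WORKED_EXAMPLE_EXPECTED: dict[tuple[str, str], float] = {
    ("PQ", "DSH"): 50.0,
    ("PQ", "DX1"): 45.0,
    ("PQ", "DX2"): 35.0,
    ("PQ", "DX3"): 20.0,
}


def worked_example(out_dir) -> dict[str, Path]:
    """Emit a five-node star fixture with hand-computed expected scores.

    The query PQ interacts with four neighbors P1..P4 whose disease sets
    are nested so the Jaccard relationships come out as 0.2, 0.4, 0.6 and
    0.8 exactly; a sidecar TSV lists the expected scores for PQ at k = 4.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network_path = out_dir / "network.tsv"
    with open(network_path, "wt") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for nbr, conf in (("P1", 960), ("P2", 970), ("P3", 980), ("P4", 990)):
            fh.write(f"PQ\t{nbr}\t{conf}\n")

    sets = {
        "PQ": ["DSH", "DX1", "DX2", "DX3", "DX4"],
        "P1": ["DSH"],
        "P2": ["DSH", "DX1"],
        "P3": ["DSH", "DX1", "DX2"],
        "P4": ["DSH", "DX1", "DX2", "DX3"],
    }
    annotation_path = out_dir / "annotations.tsv"
    with open(annotation_path, "wt") as fh:
        fh.write("geneSymbol\tdiseaseId\tdiseaseName\n")
        for g in sorted(sets):
            for d in sets[g]:
                fh.write(f"{g}\t{d}\tworked example disease {d}\n")

    expected_path = out_dir / "expected_scores.tsv"
    with open(expected_path, "wt") as fh:
        fh.write("# query PQ, index jaccard, k 4\n")
        fh.write("gene\tdiseaseId\texpected_score\n")
        for (g, d), s in sorted(WORKED_EXAMPLE_EXPECTED.items()):
            fh.write(f"{g}\t{d}\t{s:.4f}\n")

    return {
        "network": network_path,
        "annotations": annotation_path,
        "expected": expected_path,
    }
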