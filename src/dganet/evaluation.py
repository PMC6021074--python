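"""Cross-validated evaluation: tenfold CV, threshold sweep, ROC/AUC, bootstrap.

The gold-standard (gene, disease) pairs are shuffled and partitioned into
ten near-equal folds.  For each fold, the held-out pairs are hidden from the
training annotation map, the edge-level disease relationships are recomputed
from the training pairs only, and the scorer is run; the held-out pairs thus
receive scores they never influenced.  Pooled across folds every gold pair
has exactly one held-out score; non-gold candidates are pooled by averaging
their per-fold scores.  Positives are the gold pairs, negatives the scored
non-gold pairs, and gold pairs that never become candidates score 0 (false
negatives at any positive threshold).

Precision/recall/F are swept over an integer threshold grid 0..100 with the
"predicted" set defined as pairs scoring strictly above the threshold; AUC
is the rank-based (Mann-Whitney) area.  Because known pairs are vastly
outnumbered by candidates, a balanced bootstrap (sample the minority count
from the majority class, five replicates, mean) is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .indices import RelationshipTable, compute_relationships
from .network_io import AnnotationMap, WeightedNetwork
from .scoring import ScoreTable, score_all

__all__ = [
    "DEFAULT_GRID",
    "FoldPlan",
    "ThresholdMetrics",
    "BootstrapResult",
    "EvalReport",
    "make_folds",
    "f_measure",
    "roc_auc",
    "threshold_sweep",
    "bootstrap_balanced",
    "evaluate_scores",
    "crossvalidate",
    "repeated_crossvalidate",
    "k_sweep",
    "recovery_report",
    "child_seed",
]

DEFAULT_GRID: tuple[int, ...] = tuple(range(0, 101))


def child_seed(seed: int, stream: int) -> int:
    """Deterministically derive a sub-seed below 2**31."""
    return (1_000_003 * (seed + 1) + 7919 * stream) % (2**31)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(scored: Iterable[tuple[float, int]]) -> float:
    """Rank-based AUC over (score, label) records; ties count one half."""
    data = list(scored)
    y = np.array([label for _, label in data], dtype=int)
    s = np.array([score for score, _ in data], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("AUC undefined: need at least one positive and one negative")
    return float(roc_auc_score(y, s))


@dataclass
class FoldPlan:
    """Disjoint partition of the gold pairs into near-equal folds."""

    seed: int
    folds: list[list[tuple[str, str]]]


def make_folds(ann: AnnotationMap, seed: int, n_folds: int = 10) -> FoldPlan:
    """Randomized partition of gold pairs; fold sizes differ by at most 1."""
    pairs = sorted(ann.pairs)
    if len(pairs) < n_folds:
        raise ValueError(
            f"need at least {n_folds} gold pairs to build {n_folds} folds, "
            f"got {len(pairs)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = [
        [pairs[i] for i in chunk] for chunk in np.array_split(order, n_folds)
    ]
    return FoldPlan(seed=seed, folds=folds)


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class BootstrapResult:
    replicates: list[dict]
    mean_best_f: float
    mean_auc: float


@dataclass
class EvalReport:
    """Per-threshold metrics, best-F operating point, AUC, and bootstrap."""

    per_threshold: list[ThresholdMetrics]
    best: ThresholdMetrics
    auc: float
    n_pos: int
    n_neg: int
    bootstrap: BootstrapResult | None = None

    @property
    def best_f(self) -> float:
        return self.best.f_measure

    @property
    def best_threshold(self) -> float:
        return self.best.threshold

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.best.tp, self.best.fp, self.best.fn, self.best.tn)

    def to_dict(self) -> dict:
        out = {
            "best_f": self.best_f,
            "best_threshold": self.best_threshold,
            "auc": self.auc,
            "confusion_at_best": {
                "tp": self.best.tp,
                "fp": self.best.fp,
                "fn": self.best.fn,
                "tn": self.best.tn,
            },
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "per_threshold": [
                {
                    "threshold": m.threshold,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                }
                for m in self.per_threshold
            ],
        }
        if self.bootstrap is not None:
            out["bootstrap"] = {
                "replicates": self.bootstrap.replicates,
                "mean_best_f": self.bootstrap.mean_best_f,
                "mean_auc": self.bootstrap.mean_auc,
            }
        return out

    def summary(self) -> str:
        lines = [
            f"positives: {self.n_pos}  negatives: {self.n_neg}",
            f"AUC: {self.auc:.4f}",
            f"best F: {self.best_f:.4f} at threshold {self.best_threshold:g}",
            "confusion at best threshold: "
            f"TP={self.best.tp} FP={self.best.fp} FN={self.best.fn} TN={self.best.tn}",
        ]
        if self.bootstrap is not None:
            lines.append(
                f"balanced bootstrap ({len(self.bootstrap.replicates)} reps): "
                f"mean F={self.bootstrap.mean_best_f:.4f} "
                f"mean AUC={self.bootstrap.mean_auc:.4f}"
            )
        return "\n".join(lines)

    def per_threshold_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("threshold\tprecision\trecall\tf_measure\ttp\tfp\tfn\ttn\n")
            for m in self.per_threshold:
                fh.write(
                    f"{m.threshold:g}\t{m.precision:.6f}\t{m.recall:.6f}\t"
                    f"{m.f_measure:.6f}\t{m.tp}\t{m.fp}\t{m.fn}\t{m.tn}\n"
                )


# ---------------------------------------------------------------------------
# metric internals over score/label arrays
# ---------------------------------------------------------------------------


def _universe(
    scores: Mapping[tuple[str, str], float], positives: set[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Score/label arrays over scored pairs plus unscored positives (at 0)."""
    pairs = sorted(set(scores) | positives)
    s = np.array([scores.get(p, 0.0) for p in pairs], dtype=float)
    y = np.array([p in positives for p in pairs], dtype=int)
    return s, y


def _sweep_arrays(
    s: np.ndarray, y: np.ndarray, grid: Sequence[float]
) -> tuple[list[ThresholdMetrics], ThresholdMetrics]:
    n_pos = int(y.sum())
    n_all = len(y)
    out: list[ThresholdMetrics] = []
    best: ThresholdMetrics | None = None
    for t in grid:
        pred = s > t
        tp = int((pred & (y == 1)).sum())
        fp = int(pred.sum()) - tp
        fn = n_pos - tp
        tn = n_all - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos if n_pos else 0.0
        m = ThresholdMetrics(
            float(t), precision, recall, f_measure(precision, recall), tp, fp, fn, tn
        )
        out.append(m)
        # ties on F break toward the higher threshold
        if best is None or m.f_measure >= best.f_measure:
            best = m
    assert best is not None
    return out, best


def threshold_sweep(
    st: ScoreTable,
    gold: AnnotationMap,
    grid: Sequence[float] = DEFAULT_GRID,
) -> tuple[list[ThresholdMetrics], ThresholdMetrics]:
    """Precision/recall/F per threshold; best F (ties -> higher threshold)."""
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    s, y = _universe(st.scores, set(gold.pairs))
    return _sweep_arrays(s, y, grid)


def _bootstrap_arrays(
    s: np.ndarray,
    y: np.ndarray,
    replicates: int,
    seed: int,
    grid: Sequence[float],
) -> BootstrapResult:
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("balanced bootstrap needs both classes nonempty")
    m = min(len(pos_idx), len(neg_idx))
    rng = np.random.default_rng(seed)
    reps: list[dict] = []
    for _ in range(replicates):
        take_pos = (
            pos_idx if len(pos_idx) == m else rng.choice(pos_idx, m, replace=False)
        )
        take_neg = (
            neg_idx if len(neg_idx) == m else rng.choice(neg_idx, m, replace=False)
        )
        idx = np.concatenate([take_pos, take_neg])
        _, best = _sweep_arrays(s[idx], y[idx], grid)
        auc = float(roc_auc_score(y[idx], s[idx]))
        reps.append(
            {
                "best_f": best.f_measure,
                "best_threshold": best.threshold,
                "auc": auc,
                "tp": best.tp,
                "fp": best.fp,
                "fn": best.fn,
                "tn": best.tn,
            }
        )
    return BootstrapResult(
        replicates=reps,
        mean_best_f=float(np.mean([r["best_f"] for r in reps])),
        mean_auc=float(np.mean([r["auc"] for r in reps])),
    )


def bootstrap_balanced(
    st: ScoreTable,
    gold: AnnotationMap,
    replicates: int = 5,
    seed: int = 0,
    grid: Sequence[float] = DEFAULT_GRID,
) -> BootstrapResult:
    """Class-balanced bootstrap metrics (minority count from each class)."""
    s, y = _universe(st.scores, set(gold.pairs))
    return _bootstrap_arrays(s, y, replicates, seed, grid)


def evaluate_scores(
    scores: Mapping[tuple[str, str], float],
    positives: set[tuple[str, str]],
    grid: Sequence[float] = DEFAULT_GRID,
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Full report (sweep, AUC, optional bootstrap) for a pooled score map."""
    s, y = _universe(scores, positives)
    per, best = _sweep_arrays(s, y, grid)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation needs at least one positive and one negative")
    auc = float(roc_auc_score(y, s))
    boot = (
        _bootstrap_arrays(s, y, bootstrap_replicates, seed, grid)
        if bootstrap_replicates > 0
        else None
    )
    return EvalReport(per, best, auc, n_pos, n_neg, bootstrap=boot)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def crossvalidate(
    net: WeightedNetwork,
    ann: AnnotationMap,
    index_name: str = "jaccard",
    k: int = 18,
    seed: int = 0,
    *,
    n_folds: int = 10,
    denominator_mode: str = "effective",
    grid: Sequence[float] = DEFAULT_GRID,
    bootstrap_replicates: int = 5,
    rel_hook: Callable[[RelationshipTable, int], RelationshipTable] | None = None,
) -> tuple[ScoreTable, EvalReport]:
    """Tenfold CV with per-fold recomputation of relationships.

    ``rel_hook(rel, fold_index)`` may transform each fold's relationship
    table before scoring (used for the shuffled-relationship null model).
    Returns the pooled score table and its evaluation against the gold
    standard.
    """
    plan = make_folds(ann, seed, n_folds)
    gold_pairs = set(ann.pairs)
    held_out: dict[tuple[str, str], float] = {}
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for i, fold in enumerate(plan.folds):
        fold_set = set(fold)
        train = ann.without_pairs(fold_set)
        leaked = fold_set & set(train.pairs)
        if leaked:  # no-leakage invariant, asserted at runtime
            raise AssertionError(
                f"fold {i}: {len(leaked)} held-out pairs leaked into training"
            )
        rel = compute_relationships(net, train, index_name)
        if rel_hook is not None:
            rel = rel_hook(rel, i)
        st = score_all(net, rel, train, k, denominator_mode)
        for (g, d), s in st.scores.items():
            if (g, d) in fold_set:
                held_out[(g, d)] = s
            elif (g, d) in gold_pairs:
                continue  # scored as held-out in its own fold
            else:
                sums[(g, d)] = sums.get((g, d), 0.0) + s
                counts[(g, d)] = counts.get((g, d), 0) + 1
    # gold pairs never proposed as candidates score 0 (false negatives)
    for p in gold_pairs:
        held_out.setdefault(p, 0.0)
    pooled = {p: sums[p] / counts[p] for p in sums}
    pooled.update(held_out)
    pooled_st = ScoreTable(
        pooled,
        params={
            "k": k,
            "index_name": index_name,
            "neighborhood_mode": "knn",
            "denominator_mode": denominator_mode,
            "cv_folds": n_folds,
            "cv_seed": seed,
            "shuffled": rel_hook is not None,
        },
    )
    report = evaluate_scores(
        pooled, gold_pairs, grid, bootstrap_replicates, child_seed(seed, 977)
    )
    return pooled_st, report


def repeated_crossvalidate(
    net: WeightedNetwork,
    ann: AnnotationMap,
    index_name: str = "jaccard",
    k: int = 18,
    seed: int = 0,
    repeats: int = 3,
    **kwargs,
) -> tuple[list[EvalReport], dict]:
    """Repeat the CV scenario with seeds seed, seed+1, ... and average.

    Returns the per-repeat reports and a dict with mean best-F and AUC.
    """
    reports = [
        crossvalidate(net, ann, index_name, k, seed + r, **kwargs)[1]
        for r in range(repeats)
    ]
    mean = {
        "mean_best_f": float(np.mean([r.best_f for r in reports])),
        "mean_auc": float(np.mean([r.auc for r in reports])),
    }
    return reports, mean


def k_sweep(
    net: WeightedNetwork,
    ann: AnnotationMap,
    index_name: str,
    k_values: Sequence[int],
    seed: int,
    **kwargs,
) -> tuple[dict[int, float], int]:
    """Best F per k over a k grid; returns (map, argmax k)."""
    if not k_values:
        raise ValueError("k_values must be nonempty")
    kwargs.setdefault("bootstrap_replicates", 0)
    per_k: dict[int, float] = {}
    for k in k_values:
        _, report = crossvalidate(net, ann, index_name, k, seed, **kwargs)
        per_k[k] = report.best_f
    best_k = max(per_k, key=lambda k: (per_k[k], -k))
    return per_k, best_k


def recovery_report(
    st: ScoreTable,
    known: AnnotationMap,
    hidden: set[tuple[str, str]],
    grid: Sequence[float] = DEFAULT_GRID,
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Evaluate recovery of a withheld truth set.

    Positives are the ``hidden`` pairs (never present in the ``known``
    annotations used for scoring); the known pairs themselves are excluded
    from the evaluation universe, so negatives are the remaining scored
    candidates.  Hidden pairs that were never scored count at score 0.
    """
    scores = {p: s for p, s in st.scores.items() if p not in known}
    return evaluate_scores(scores, set(hidden), grid, bootstrap_replicates, seed)
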