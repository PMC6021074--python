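# Methods

## Model and assumptions

The scorer operationalises guilt-by-association on a protein interaction
network: if a gene's closest interactors are annotated to a disease, and
those interactors otherwise share disease involvement with the gene, the
gene is a plausible candidate for that disease. Three assumptions are load
bearing:

1. high-confidence physical/functional interactions are enriched for shared
   disease involvement (hence the strict confidence filter);
2. the curated gene–disease gold standard, though incomplete, is accurate —
   missing annotations are treated as unknown, not false;
3. shared-disease evidence is local: only *direct* interactors are
   consulted, never multi-hop paths or diffusion.

The association score for a query gene g and candidate disease d is

    score(g, d) = 100 * sum_{g_nn in NN(g), d in Dg_nn} r(g, g_nn) / |NN(g)|

with NN(g) the k nearest neighbors by ascending edge weight and r the
edge-level disease relationship (a set-overlap index on the two genes'
disease sets). The query's own annotations never enter its aggregation;
known pairs are scored alongside novel ones, which is what makes
cross-validated evaluation possible.

## Tunable parameters

| parameter | default | units / range | why |
|---|---|---|---|
| confidence_threshold | 900 | STRING combined score, 0–1000 | keeps only high-confidence interactions; the filter is strict (score 900 is dropped) |
| weight transform | `1 − c/1000` | maps (900,1000] → [0,0.1) | any strictly decreasing transform yields identical rankings (a tested invariant); the default keeps weights in (0,1). `1000 − c` and `1/c` are available |
| index | jaccard | — | balances shared against total disease involvement; simpson saturates for nested sets, geometric = cosine² penalises small overlaps harder |
| k | 18 | neighbors | scores are stable over a broad k band; the k-sweep utility reports best-F per k so users can pick for their data |
| denominator | `effective` = min(k, degree) | — | dividing by k itself (`literal_k` mode) penalises genes with degree < k; on dense filtered networks the two coincide |
| threshold grid | integers 0–100 | score units | scores live in [0,100]; "predicted" means score strictly above the threshold |
| bootstrap replicates | 5 | — | balanced resampling of the majority class; mean reported |
| CV folds / repeats | 10 / 3 | — | near-equal random folds; `repeated_crossvalidate` averages over consecutive seeds |

Tie-breaks are deterministic everywhere: neighbor selection at equal weight
is lexicographic by gene symbol, best-F ties resolve to the higher
threshold, and all randomness (folds, bootstrap, shuffles, generator) flows
from explicit integer seeds.

## Cross-validation protocol

Gold pairs are randomized and split into ten near-equal folds. For each
fold, the held-out pairs are removed from the training annotation map, the
edge relationships are **recomputed from the training map** (hiding a pair
changes the disease sets on both sides of its edges), and the scorer runs
with training-map disease sets. A runtime assertion rejects any fold whose
training map still contains a held-out pair. Pooled across folds, every
gold pair carries exactly the score from the one fold that hid it; non-gold
candidates are pooled by averaging their per-fold scores. Gold pairs never
proposed by any neighborhood score 0 and are unrecoverable false negatives
— recall is measured against all true pairs, not just reachable ones.

The evaluation universe is the set of scored candidate pairs (plus unscored
gold pairs at 0), not the full gene × disease grid: the method only makes
claims about pairs its neighborhoods propose, and enumerating all pairs
would drown the metrics in structurally unreachable negatives.

## Synthetic benchmark

The generator plants disease modules: contiguous blocks of genes wired with
probability `p_intra = 0.6` (background `p_inter = 0.01`), confidences drawn
above the filter threshold, with `annot_per_module = 6` diseases per module
and a `dropout = 0.3` fraction of true annotations withheld into a
hidden-truth file. The defaults (300 genes, 10 modules of 12, seed-driven
and byte-reproducible) give an analysis network of ~120 annotated genes —
small enough that the full protocol runs in seconds, large enough that AUC
standard errors are a few percent.

Within each module the genes are split into two subgroups, each annotated
to half of the module's diseases. This detail is what makes the null
comparison honest: a candidate disease from a gene's *other* subgroup has
about as many annotated carrier neighbors as a withheld true pair, so a
score built on shuffled relationship values cannot tell them apart
(baseline AUC ≈ 0.5), whereas the true relationships — high within a
subgroup, zero across — separate them cleanly (recovery AUC ≈ 0.9). Had
every module gene carried every module disease, the mere *number* of
annotated neighbors would leak the answer and the shuffle control would
look spuriously strong.

What the benchmark does **not** emulate: the heavy-tailed degree
distribution of real interactomes, the extremely skewed disease-size
distribution of curated annotation databases, annotation noise (false
positives in the gold standard), and inter-module disease sharing
(comorbidity). Passing results therefore demonstrate that the
implementation recovers plantable local shared-disease signal and that its
controls behave; they do not by themselves predict performance on a
specific database release.

## Numerical and degenerate-input choices

- Any association index involving an empty disease set returns 0; CV folds
  can transiently empty a training-fold disease set, and "no known disease"
  is treated as no evidence, not as an error.
- The geometric index is implemented literally as the squared intersection
  over the size product, i.e. exactly cosine²; the identity is a named
  regression test.
- Duplicate edges keep the maximum confidence (deterministic and
  conservative toward retention); self-loops are discarded.
- Candidates whose aggregated relationship is 0 are recorded with score 0 —
  they were proposed, and they count as predictions that failed, not as
  absent rows.
- Coverage is computed over nonzero-score predictions only; entities with
  no nonzero predictions have undefined coverage and are treated as 0 by
  the selection filters.
- Gene-selection thresholds are inclusive (coverage ≥ 70, score ≥ 40 by
  default); disease-selection thresholds are strict (coverage > 40,
  score > 20), matching their respective conventions.
- Hub removal is single-pass: the removal set is fixed by degrees in the
  input network, not re-evaluated as removal thins the graph.
- The shuffle null permutes relationship values per CV fold over the same
  edge set (value multiset preserved exactly) and reuses the fold plan of
  the paired true run.

## Problem sizes

The test suite and the acceptance script run the default 300-gene synthetic
spec (ten-fold CV over ~250 gold pairs, ~450 edges); a complete acceptance
run takes a couple of seconds and the full test suite a few seconds. These
sizes were chosen so that AUC/F estimates are stable to within a few
percent across seeds while the whole protocol — including per-fold
relationship recomputation, which dominates the cost on large networks —
remains interactive.

## Known limitations

- Only direct-interactor evidence: genes whose true associations are two
  hops away score 0 by construction.
- Genes with no annotated neighbors produce no candidates; the method
  cannot propose diseases absent from the neighborhood union.
- Identifier mapping (e.g. STRING protein IDs to gene symbols) is the
  caller's responsibility beyond an optional two-column alias file; symbols
  are opaque, case-sensitive strings.
- The reported "true negatives" are scored-but-not-curated pairs; some are
  genuinely associated pairs missing from the gold standard, so precision
  estimates are conservative.
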