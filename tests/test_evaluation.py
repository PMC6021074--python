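import itertools
import math

import numpy as np
import pytest

from dganet.evaluation import (
    bootstrap_balanced,
    crossvalidate,
    evaluate_scores,
    f_measure,
    k_sweep,
    make_folds,
    recovery_report,
    roc_auc,
    threshold_sweep,
)
from dganet.indices import compute_relationships
from dganet.network_io import AnnotationMap
from dganet.scoring import ScoreTable, score_all


def brute_force_auc(records):
    """Enumerate all positive-negative pairs; ties count one half."""
    pos = [s for s, y in records if y == 1]
    neg = [s for s, y in records if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_f_measure_fixed_point_and_cases(self):
        assert f_measure(0.78, 0.78) == pytest.approx(0.78)
        assert f_measure(0.5, 1.0) == pytest.approx(2 / 3)
        assert f_measure(0.0, 0.0) == 0.0
        assert f_measure(0.0, 1.0) == 0.0

    def test_auc_perfect_separation(self):
        assert roc_auc([(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]) == 1.0

    def test_auc_enumerated_example(self):
        records = [(0.9, 1), (0.8, 0), (0.7, 1), (0.1, 0)]
        assert roc_auc(records) == pytest.approx(0.75)
        assert brute_force_auc(records) == pytest.approx(0.75)

    def test_auc_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        records = [
            (float(rng.integers(0, 5)), int(rng.integers(0, 2))) for _ in range(60)
        ]
        if not {y for _, y in records} == {0, 1}:
            records += [(1.0, 0), (1.0, 1)]
        assert roc_auc(records) == pytest.approx(brute_force_auc(records), abs=1e-12)

    def test_auc_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        records = [(float(rng.random()), int(rng.random() < 0.5)) for _ in range(4000)]
        assert roc_auc(records) == pytest.approx(0.5, abs=0.05)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc([(0.5, 1), (0.4, 1)])


class TestMakeFolds:
    def test_sizes_and_partition(self):
        ann = AnnotationMap([(f"g{i}", f"d{i % 7}") for i in range(103)])
        plan = make_folds(ann, seed=3)
        sizes = sorted(len(f) for f in plan.folds)
        assert sum(sizes) == len(ann) and sizes[-1] - sizes[0] <= 1
        all_pairs = [p for f in plan.folds for p in f]
        assert len(all_pairs) == len(set(all_pairs))

    def test_deterministic_for_seed(self):
        ann = AnnotationMap([(f"g{i}", "d") for i in range(40)])
        assert make_folds(ann, 9).folds == make_folds(ann, 9).folds
        assert make_folds(ann, 9).folds != make_folds(ann, 10).folds

    def test_too_few_pairs(self):
        ann = AnnotationMap([(f"g{i}", "d") for i in range(9)])
        with pytest.raises(ValueError, match="at least 10"):
            make_folds(ann, 0)


class TestThresholdSweep:
    @pytest.fixture
    def six_records(self):
        st = ScoreTable(
            {
                ("g1", "d"): 90.0,
                ("g2", "d"): 70.0,
                ("g3", "d"): 50.0,
                ("g4", "d"): 30.0,
                ("g5", "d"): 10.0,
                ("g6", "d"): 0.0,
            }
        )
        gold = AnnotationMap([("g1", "d"), ("g2", "d"), ("g4", "d")])
        return st, gold

    def test_hand_tabulated_confusion(self, six_records):
        st, gold = six_records
        per, best = threshold_sweep(st, gold, grid=[0, 20, 40, 60, 80, 100])
        by_t = {m.threshold: m for m in per}
        # t=40: predicted {g1,g2,g3}; TP=2 FP=1 FN=1 TN=2
        assert (by_t[40].tp, by_t[40].fp, by_t[40].fn, by_t[40].tn) == (2, 1, 1, 2)
        assert by_t[40].precision == pytest.approx(2 / 3)
        assert by_t[40].recall == pytest.approx(2 / 3)
        # t=100: nothing predicted
        assert by_t[100].recall == 0.0 and by_t[100].f_measure == 0.0

    def test_perfect_split_gives_f_one(self):
        st = ScoreTable({("a", "d"): 100.0, ("b", "d"): 0.0})
        gold = AnnotationMap([("a", "d")])
        _, best = threshold_sweep(st, gold, grid=[0, 50, 100])
        assert best.f_measure == 1.0 and best.threshold == 50

    def test_f_ties_break_to_higher_threshold(self):
        st = ScoreTable({("a", "d"): 80.0, ("b", "d"): 10.0})
        gold = AnnotationMap([("a", "d")])
        _, best = threshold_sweep(st, gold, grid=[20, 40, 60])
        assert best.f_measure == 1.0 and best.threshold == 60

    def test_unscored_gold_pair_counts_as_false_negative(self):
        st = ScoreTable({("a", "d"): 80.0})
        gold = AnnotationMap([("a", "d"), ("zz", "d9")])
        per, _ = threshold_sweep(st, gold, grid=[50])
        assert per[0].fn == 1 and per[0].recall == pytest.approx(0.5)


class TestBootstrap:
    def make_imbalanced(self):
        rng = np.random.default_rng(11)
        scores = {("p", f"d{i}"): 60.0 + float(rng.random()) for i in range(10)}
        scores.update(
            {("n", f"d{i}"): 40.0 * float(rng.random()) for i in range(500)}
        )
        gold = AnnotationMap([("p", f"d{i}") for i in range(10)])
        return ScoreTable(scores), gold

    def test_each_replicate_balanced(self):
        st, gold = self.make_imbalanced()
        boot = bootstrap_balanced(st, gold, replicates=5, seed=4)
        for rep in boot.replicates:
            assert rep["tp"] + rep["fn"] == 10
            assert rep["fp"] + rep["tn"] == 10

    def test_deterministic_under_seed(self):
        st, gold = self.make_imbalanced()
        a = bootstrap_balanced(st, gold, replicates=3, seed=21)
        b = bootstrap_balanced(st, gold, replicates=3, seed=21)
        assert a.replicates == b.replicates

    def test_mean_inside_replicate_envelope(self):
        st, gold = self.make_imbalanced()
        boot = bootstrap_balanced(st, gold, replicates=5, seed=1)
        fs = [r["best_f"] for r in boot.replicates]
        assert min(fs) <= boot.mean_best_f <= max(fs)


class TestCrossValidation:
    def test_every_gold_pair_scored_once(self, small_data):
        net, ann = small_data
        st, report = crossvalidate(net, ann, "jaccard", 6, seed=2,
                                   bootstrap_replicates=0)
        assert set(ann.pairs) <= set(st.scores)
        assert report.n_pos == len(ann)

    def test_training_maps_never_contain_held_out_pairs(self, small_data):
        _, ann = small_data
        plan = make_folds(ann, seed=5)
        for fold in plan.folds:
            train = ann.without_pairs(fold)
            assert not set(fold) & set(train.pairs)
        # the union of folds is the gold standard
        assert {p for f in plan.folds for p in f} == set(ann.pairs)

    def test_degenerate_two_fold_run_matches_manual_pooling(self):
        """Pooling wiring: recompute each fold by hand with score_all."""
        conf = {("A", "B"): 950, ("B", "C"): 960, ("C", "D"): 970,
                ("D", "A"): 980, ("A", "C"): 990}
        ann = AnnotationMap(
            [("A", "d1"), ("B", "d1"), ("C", "d1"), ("D", "d2"),
             ("A", "d2"), ("B", "d3"), ("C", "d3"), ("D", "d3"),
             ("A", "d4"), ("B", "d4"), ("C", "d4"), ("D", "d4")]
        )
        from conftest import make_network

        net = make_network(conf)
        st, _ = crossvalidate(net, ann, "jaccard", 2, seed=1, n_folds=2,
                              bootstrap_replicates=0)
        plan = make_folds(ann, seed=1, n_folds=2)
        for fold in plan.folds:
            train = ann.without_pairs(fold)
            rel = compute_relationships(net, train, "jaccard")
            fold_scores = score_all(net, rel, train, 2).scores
            for pair in fold:
                assert st.scores[pair] == pytest.approx(
                    fold_scores.get(pair, 0.0), abs=1e-12
                )

    def test_signal_exceeds_chance_by_three_standard_errors(self, small_data,
                                                            small_bundle):
        net, ann = small_data
        st, _ = crossvalidate(net, ann, "jaccard", 10, seed=1,
                              bootstrap_replicates=0)
        rec = recovery_report(st, ann, set(small_bundle.hidden_pairs))
        se = math.sqrt((rec.n_pos + rec.n_neg + 1) / (12 * rec.n_pos * rec.n_neg))
        assert rec.auc > 0.5 + 3 * se

    def test_k_sweep_reproducible_and_pointwise_independent(self, small_data):
        net, ann = small_data
        per_a, _ = k_sweep(net, ann, "jaccard", [1], seed=3)
        per_b, best_k = k_sweep(net, ann, "jaccard", [1, 2], seed=3)
        assert per_a[1] == per_b[1]
        assert best_k in per_b
        per_c, _ = k_sweep(net, ann, "jaccard", [1, 2], seed=3)
        assert per_b == per_c


class TestEvaluateScores:
    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            evaluate_scores({("a", "d"): 1.0}, {("a", "d")})

    def test_report_roundtrip_fields(self):
        scores = {("a", "d"): 90.0, ("b", "d"): 10.0, ("c", "d"): 5.0}
        rep = evaluate_scores(scores, {("a", "d")}, grid=[0, 50],
                              bootstrap_replicates=2, seed=0)
        d = rep.to_dict()
        assert d["auc"] == rep.auc == 1.0
        assert d["best_f"] == 1.0
        assert len(d["per_threshold"]) == 2
        assert len(d["bootstrap"]["replicates"]) == 2
        assert "AUC" in rep.summary()
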