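import logging

import numpy as np
import pytest

from ddifuse.data import DDITable, DrugCatalog
from ddifuse.evaluation import (chance_macro_f1, compute_metrics, run_cv,
                                split_cv)

from ._oracles import (average_precision_oracle, macro_metrics_oracle,
                       roc_auc_oracle)


def _held_drugs(plan, fold):
    return set(plan.drug_partition[fold])


class TestSplits:
    def test_s1_partitions_all_pairs(self, bench_dataset):
        ds = bench_dataset
        plan = split_cv(ds.ddis, ds.catalog, "S1", 5, seed=0)
        seen = [i for _, test in plan.folds for i in test]
        assert sorted(seen) == list(range(len(ds.ddis.pairs)))
        for train, test in plan.folds:
            assert not set(train) & set(test)
            assert len(train) + len(test) == len(ds.ddis.pairs)

    def test_s1_stratifies_types(self, bench_dataset):
        ds = bench_dataset
        plan = split_cv(ds.ddis, ds.catalog, "S1", 5, seed=0)
        labels = np.array([t for _, _, t in ds.ddis.pairs])
        for _, test in plan.folds:
            counts = np.bincount(labels[test], minlength=ds.ddis.n_types)
            overall = np.bincount(labels, minlength=ds.ddis.n_types) / 5
            assert np.abs(counts - overall).max() <= 1.0

    def test_tiny_type_warned_and_unstratified(self, caplog):
        catalog = DrugCatalog(tuple(f"d{i}" for i in range(8)))
        pairs = [("d0", "d1", 0), ("d2", "d3", 0), ("d4", "d5", 0),
                 ("d6", "d7", 1)]
        ddis = DDITable(pairs, ("a", "b"))
        with caplog.at_level(logging.WARNING, logger="ddifuse"):
            split_cv(ddis, catalog, "S1", 3, seed=0)
        assert "unstratified" in caplog.text

    def test_s2_test_pairs_touch_exactly_one_held_drug(self, bench_dataset):
        ds = bench_dataset
        plan = split_cv(ds.ddis, ds.catalog, "S2", 5, seed=0)
        for k, (train, test) in enumerate(plan.folds):
            held = _held_drugs(plan, k)
            for i in test:
                a, b, _ = ds.ddis.pairs[i]
                assert (a in held) + (b in held) == 1
            for i in train:
                a, b, _ = ds.ddis.pairs[i]
                assert a not in held and b not in held

    def test_s3_test_pairs_fully_held_out(self, bench_dataset):
        ds = bench_dataset
        plan = split_cv(ds.ddis, ds.catalog, "S3", 5, seed=0)
        for k, (train, test) in enumerate(plan.folds):
            held = _held_drugs(plan, k)
            for i in test:
                a, b, _ = ds.ddis.pairs[i]
                assert a in held and b in held
            for i in train:
                a, b, _ = ds.ddis.pairs[i]
                assert a not in held and b not in held

    def test_no_test_label_reachable_from_training(self, bench_dataset):
        # structural leakage check: a pair index never sits in both slices
        ds = bench_dataset
        for scene in ("S1", "S2", "S3"):
            plan = split_cv(ds.ddis, ds.catalog, scene, 5, seed=3)
            for train, test in plan.folds:
                assert not set(train) & set(test)

    def test_deterministic_given_seed(self, bench_dataset):
        ds = bench_dataset
        p1 = split_cv(ds.ddis, ds.catalog, "S2", 5, seed=4)
        p2 = split_cv(ds.ddis, ds.catalog, "S2", 5, seed=4)
        assert p1.folds == p2.folds and p1.drug_partition == p2.drug_partition

    def test_unknown_scene_rejected(self, bench_dataset):
        with pytest.raises(ValueError, match="scene"):
            split_cv(bench_dataset.ddis, bench_dataset.catalog, "S9", 5, 0)


def _proba_for(y_pred, l, strength=0.9):
    p = np.full((len(y_pred), l), (1 - strength) / (l - 1))
    p[np.arange(len(y_pred)), y_pred] = strength
    return p


class TestMetrics:
    def test_hand_worked_four_sample_example(self):
        y_true = np.array([0, 0, 1, 1])
        proba = _proba_for(np.array([0, 1, 1, 1]), 2)
        r = compute_metrics(y_true, proba, 2)
        assert r.acc == pytest.approx(0.75)
        assert r.precision_macro == pytest.approx(5 / 6)
        assert r.recall_macro == pytest.approx(0.75)
        assert r.f1_macro == pytest.approx(0.78947, abs=1e-5)

    def test_perfect_prediction_maximal_everywhere(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        r = compute_metrics(y, _proba_for(y, 3, strength=0.99), 3)
        for key in ("acc", "f1_macro", "aupr_micro", "auc_micro",
                    "precision_macro", "recall_macro", "plain_accuracy"):
            assert getattr(r, key) == pytest.approx(1.0)

    def test_uniform_scorer_has_half_auc(self):
        y = np.array([0, 1] * 20)
        proba = np.full((40, 2), 0.5)
        assert compute_metrics(y, proba, 2).auc_micro == pytest.approx(0.5)

    def test_rows_not_summing_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_metrics(np.array([0, 1]), np.array([[0.7, 0.7], [0.5, 0.5]]), 2)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            n, l = 300, 6
            y = rng.integers(0, l, n)
            p = rng.random((n, l))
            p /= p.sum(axis=1, keepdims=True)
            r = compute_metrics(y, p, l)
            acc, mp, mr, f1 = macro_metrics_oracle(y, p.argmax(1), l)
            assert r.acc == pytest.approx(acc, abs=1e-9)
            assert r.precision_macro == pytest.approx(mp, abs=1e-9)
            assert r.recall_macro == pytest.approx(mr, abs=1e-9)
            assert r.f1_macro == pytest.approx(f1, abs=1e-9)
            y_flat = np.eye(l)[y].ravel()
            assert r.aupr_micro == pytest.approx(
                average_precision_oracle(y_flat, p.ravel()), abs=1e-9)
            assert r.auc_micro == pytest.approx(
                roc_auc_oracle(y_flat, p.ravel()), abs=1e-9)

    def test_absent_class_uses_zero_convention(self):
        y = np.array([0, 0, 1, 1])  # class 2 absent
        r = compute_metrics(y, _proba_for(np.array([0, 0, 1, 1]), 3), 3)
        assert r.recall_macro == pytest.approx(2 / 3)  # (1 + 1 + 0) / 3


class TestRunCV:
    def test_deterministic_and_above_chance(self, bench_dataset, small_config):
        r1 = run_cv(bench_dataset, small_config)
        r2 = run_cv(bench_dataset, small_config)
        assert r1.aggregate == r2.aggregate
        chance = chance_macro_f1(bench_dataset.ddis)
        assert r1.aggregate["f1_macro"] > 3 * chance

    def test_chance_level_near_uniform_for_balancedish_labels(self, bench_dataset):
        chance = chance_macro_f1(bench_dataset.ddis)
        assert 0.1 < chance < 0.3  # ~1/l for 5 roughly balanced types
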