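import numpy as np
import pytest

from ddifuse.data import DDITable, DNNConfig, DrugCatalog
from ddifuse.mda import UnifiedEmbedding
from ddifuse.predictor import (aggregate_pairs, fit_pair_classifier,
                               pair_probabilities, predict_proba,
                               rank_novel_pairs, train_dnn)

FAST = DNNConfig(hidden_dims=(32, 16), epochs=40)


@pytest.fixture(scope="module")
def toy_emb():
    catalog = DrugCatalog(("a", "b"))
    return UnifiedEmbedding(np.array([[1.0, 2.0], [3.0, 4.0]]),
                            catalog.drug_ids), catalog


class TestAggregation:
    @pytest.mark.parametrize("operator,expected", [
        ("inner", [3.0, 8.0]),
        ("sum", [4.0, 6.0]),
        ("concat", [1.0, 2.0, 3.0, 4.0]),
    ])
    def test_operator_worked_examples(self, toy_emb, operator, expected):
        emb, catalog = toy_emb
        x = aggregate_pairs(emb, [("a", "b")], operator, catalog)
        assert x.values[0].tolist() == expected
        assert x.operator_name == operator

    def test_unknown_operator_and_drug_rejected(self, toy_emb):
        emb, catalog = toy_emb
        with pytest.raises(ValueError, match="operator"):
            aggregate_pairs(emb, [("a", "b")], "hadamard", catalog)
        with pytest.raises(KeyError):
            aggregate_pairs(emb, [("a", "zz")], "sum", catalog)


def _planted_problem(rng, n=600, d=8, l=4):
    y = rng.integers(0, l, n)
    centers = rng.normal(size=(l, d)) * 2.0
    return centers[y] + rng.normal(size=(n, d)) * 0.5, y


class TestTraining:
    def test_learns_above_chance_on_planted_labels(self, rng):
        x, y = _planted_problem(rng)
        model = train_dnn(x, y, FAST, seed=0)
        acc = (predict_proba(model, x).argmax(1) == y).mean()
        assert acc > 1.0 / 4  # chance level for four balanced classes
        assert acc > 0.8

    def test_shuffled_labels_stay_at_majority_rate(self, rng):
        x, y = _planted_problem(rng)
        y_sh = rng.permutation(y)
        cut = int(0.7 * len(y))
        model = train_dnn(x[:cut], y_sh[:cut], FAST, seed=0)
        held_acc = (predict_proba(model, x[cut:]).argmax(1) == y_sh[cut:]).mean()
        n_test = len(y) - cut
        p_maj = np.bincount(y_sh[cut:]).max() / n_test
        se = np.sqrt(p_maj * (1 - p_maj) / n_test)
        assert abs(held_acc - p_maj) <= 3 * se

    def test_fixed_seed_reproduces_parameters_exactly(self, rng):
        x, y = _planted_problem(rng, n=200)
        m1 = train_dnn(x, y, FAST, seed=5)
        m2 = train_dnn(x, y, FAST, seed=5)
        for p1, p2 in zip(m1.net.state(), m2.net.state()):
            np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(50, 4))
        with pytest.raises(ValueError, match="single class"):
            train_dnn(x, np.zeros(50, dtype=int), FAST, seed=0)

    def test_training_loss_decreases_initially(self, rng):
        x, y = _planted_problem(rng)
        model = train_dnn(x, y, FAST, seed=1)
        log = [r["train_loss"] for r in model.training_log]
        assert log[min(5, len(log) - 1)] < log[0]


class TestInference:
    def test_probability_rows_sum_to_one(self, rng):
        x, y = _planted_problem(rng, n=200)
        model = train_dnn(x, y, FAST, seed=0)
        p = predict_proba(model, rng.normal(size=(37, 8)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.min() >= 0

    def test_duplicate_inputs_get_identical_outputs(self, rng):
        x, y = _planted_problem(rng, n=200)
        model = train_dnn(x, y, FAST, seed=0)
        q = rng.normal(size=(1, 8))
        p = predict_proba(model, np.vstack([q, q]))
        np.testing.assert_array_equal(p[0], p[1])

    def test_width_mismatch_rejected(self, rng):
        x, y = _planted_problem(rng, n=200)
        model = train_dnn(x, y, FAST, seed=0)
        with pytest.raises(ValueError, match="width"):
            predict_proba(model, rng.normal(size=(3, 5)))

    def test_concat_scores_invariant_to_pair_orientation(self, bench_dataset,
                                                         bench_embedding,
                                                         small_config):
        ds = bench_dataset
        model = fit_pair_classifier(
            bench_embedding, ds.ddis.pairs[:400], small_config.dnn, 0,
            "concat", ds.catalog, ds.ddis.n_types,
        )
        pairs = [(a, b) for a, b, _ in ds.ddis.pairs[400:430]]
        fwd = pair_probabilities(model, bench_embedding, pairs, "concat", ds.catalog)
        rev = pair_probabilities(model, bench_embedding,
                                 [(b, a) for a, b in pairs], "concat", ds.catalog)
        np.testing.assert_array_equal(fwd, rev)


@pytest.fixture(scope="module")
def ranking_setup(small_config):
    from ddifuse.evaluation import build_drug_representation
    from ddifuse.synth import SynthConfig, generate_dataset

    ds = generate_dataset(SynthConfig(label_noise=0.0, seed=2))
    emb = build_drug_representation(ds, small_config, "nmdadnn")
    rng = np.random.default_rng(3)
    target = 0
    t_pairs = [i for i, (_, _, t) in enumerate(ds.ddis.pairs) if t == target]
    withheld = set(rng.choice(t_pairs, 30, replace=False).tolist())
    known = DDITable(
        [p for i, p in enumerate(ds.ddis.pairs) if i not in withheld],
        ds.ddis.type_names,
    )
    model = fit_pair_classifier(emb, known.pairs, small_config.dnn, 0,
                                "concat", ds.catalog, ds.ddis.n_types)
    return ds, emb, known, model, target


class TestRanking:
    def test_known_pairs_excluded(self, ranking_setup):
        ds, emb, known, model, target = ranking_setup
        top = rank_novel_pairs(model, emb, known, target, 50, ds.catalog)
        known_keys = known.pair_keys()
        assert all(frozenset(p) not in known_keys for p, _ in top)

    def test_oversized_k_returns_all_candidates_sorted(self, ranking_setup):
        ds, emb, known, model, target = ranking_setup
        n_cand = len(ds.catalog) * (len(ds.catalog) - 1) // 2 - len(known.pairs)
        top = rank_novel_pairs(model, emb, known, target, n_cand + 999, ds.catalog)
        assert len(top) == n_cand
        scores = [s for _, s in top]
        assert scores == sorted(scores, reverse=True)

    def test_type_out_of_range_rejected(self, ranking_setup):
        ds, emb, known, model, _ = ranking_setup
        with pytest.raises(ValueError, match="type_id"):
            rank_novel_pairs(model, emb, known, 99, 5, ds.catalog)

    def test_correct_group_pairs_enriched_at_top(self, ranking_setup):
        from scipy.stats import hypergeom

        from ddifuse.synth import default_type_rule

        ds, emb, known, model, target = ranking_setup
        top = rank_novel_pairs(model, emb, known, target, 50, ds.catalog)
        rule = default_type_rule(4, 5)
        gid = {d: ds.groups[i] for i, d in enumerate(ds.catalog.drug_ids)}

        def true_type(a, b):
            g, h = sorted((gid[a], gid[b]))
            return rule[(g, h)]

        ids = ds.catalog.drug_ids
        known_keys = known.pair_keys()
        cands = [
            (ids[i], ids[j])
            for i in range(len(ids)) for j in range(i + 1, len(ids))
            if frozenset((ids[i], ids[j])) not in known_keys
        ]
        n_success = sum(true_type(a, b) == target for a, b in cands)
        hits = sum(true_type(a, b) == target for (a, b), _ in top)
        pval = hypergeom.sf(hits - 1, len(cands), n_success, len(top))
        assert pval < 1e-10
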