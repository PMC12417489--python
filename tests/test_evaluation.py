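"""Balanced accuracy, probes, splits, the fraction sampler and zero-shot logic."""

import numpy as np
import pytest

from eegtext.evaluation import (
    FEWSHOT_FRACTIONS,
    FewShotData,
    SplitPlan,
    balanced_accuracy,
    confidence_bands,
    few_shot_protocol,
    make_split_plan,
    probe,
    recording_embedding,
    stratified_fraction,
    subset_hash,
    zero_shot_classify,
)
from eegtext.models import DualEncoderModel, HashingTextEncoder

WIDTHS = (6, 6, 12, 24, 48)


@pytest.fixture(scope="module")
def model():
    return DualEncoderModel(HashingTextEncoder(dim=32), widths=WIDTHS,
                            head_hidden_dim=32, seed=0).eval()


class TestBalancedAccuracy:
    def test_perfect(self):
        labels = [True, True, False, False]
        assert balanced_accuracy(labels, labels) == 1.0

    def test_constant_predictor_is_half(self):
        labels = [True] * 6 + [False] * 4
        assert balanced_accuracy([True] * 10, labels) == 0.5

    def test_hand_computed_confusion(self):
        # TP=8 FN=2 TN=5 FP=5 -> (0.8 + 0.5) / 2
        labels = [True] * 10 + [False] * 10
        preds = [True] * 8 + [False] * 2 + [False] * 5 + [True] * 5
        assert balanced_accuracy(preds, labels) == pytest.approx(0.65)

    def test_matches_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score
        rng = np.random.default_rng(0)
        labels = rng.random(50) > 0.4
        preds = rng.random(50) > 0.5
        assert balanced_accuracy(preds, labels) == pytest.approx(
            balanced_accuracy_score(labels, preds))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_accuracy([True, False], [True, True])


class TestRecordingEmbedding:
    def test_identical_windows_match_single_window(self, model):
        w = np.random.default_rng(0).normal(size=(1, 21, 1200)).astype(np.float32)
        stacked = np.repeat(w, 4, axis=0)
        single = recording_embedding(model, w)
        mean = recording_embedding(model, stacked)
        np.testing.assert_allclose(single, mean, atol=1e-5)

    def test_mean_oracle(self, model):
        from eegtext.models import eeg_encode
        rng = np.random.default_rng(1)
        windows = rng.normal(size=(5, 21, 1200)).astype(np.float32)
        expected = eeg_encode(windows, model).mean(axis=0)
        np.testing.assert_allclose(recording_embedding(model, windows), expected,
                                   atol=1e-6)

    def test_projection_space_is_unit_norm(self, model):
        rng = np.random.default_rng(2)
        windows = rng.normal(size=(3, 21, 1200)).astype(np.float32)
        vec = recording_embedding(model, windows, space="projection")
        assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-5)

    def test_empty_rejected(self, model):
        with pytest.raises(ValueError, match="no windows"):
            recording_embedding(model, np.zeros((0, 21, 1200)))


class TestZeroShot:
    def test_untrained_model_near_chance(self, model):
        rng = np.random.default_rng(3)
        scores = []
        for seed in range(5):
            gen = np.random.default_rng(seed)
            recs = [gen.normal(size=(2, 21, 1200)).astype(np.float32)
                    for _ in range(20)]
            labels = np.arange(20) % 2 == 0
            preds, _ = zero_shot_classify(model, recs, task="pathological")
            scores.append(balanced_accuracy(preds, labels))
        assert abs(np.mean(scores) - 0.5) < 0.15

    def test_window_level_margins_returned(self, model):
        rng = np.random.default_rng(4)
        recs = [rng.normal(size=(3, 21, 1200)).astype(np.float32)
                for _ in range(4)]
        preds, _, margins = zero_shot_classify(model, recs, task="pathological",
                                               window_level=True)
        assert len(margins) == 4
        assert all(m.shape == (3,) for m in margins)
        # the recording-level call is unchanged by the flag
        preds2, _ = zero_shot_classify(model, recs, task="pathological")
        np.testing.assert_array_equal(preds, preds2)

    def test_prompt_count_validated(self, model):
        with pytest.raises(ValueError, match="two prompts"):
            zero_shot_classify(model, [], prompts={"A": "x"})

    def test_task_or_prompts_required(self, model):
        with pytest.raises(ValueError):
            zero_shot_classify(model, [])


class TestProbe:
    def test_separable_embeddings_reach_one(self):
        rng = np.random.default_rng(0)
        train = np.vstack([rng.normal(5, 1, (20, 8)), rng.normal(-5, 1, (20, 8))])
        labels = np.array([True] * 20 + [False] * 20)
        result = probe(train, labels, train, labels, head="logreg", task="t")
        assert result.balanced_accuracy == 1.0
        assert result.method == "eegclip_logreg"

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        scores = []
        for seed in range(5):
            gen = np.random.default_rng(seed)
            X = gen.normal(size=(60, 8))
            y = gen.random(60) > 0.5
            if y.all() or (~y).all():
                continue
            Xe = gen.normal(size=(40, 8))
            ye = np.arange(40) % 2 == 0
            scores.append(probe(X, y, Xe, ye).balanced_accuracy)
        assert abs(np.mean(scores) - 0.5) < 0.12

    def test_mlp_beats_logreg_on_xor(self):
        rng = np.random.default_rng(2)
        n = 200
        X = rng.normal(size=(n, 2)) + rng.choice([-3, 3], size=(n, 2))
        y = (X[:, 0] > 0) ^ (X[:, 1] > 0)
        res_lin = probe(X[:150], y[:150], X[150:], y[150:], head="logreg")
        res_mlp = probe(X[:150], y[:150], X[150:], y[150:], head="mlp", seed=0)
        assert res_mlp.balanced_accuracy >= res_lin.balanced_accuracy

    def test_unknown_head_rejected(self):
        with pytest.raises(ValueError):
            probe(np.zeros((4, 2)), [0, 1, 0, 1], np.zeros((2, 2)), [0, 1],
                  head="transformer")

    def test_result_range_validated(self):
        from eegtext.evaluation import EvalResult
        with pytest.raises(ValueError):
            EvalResult(task="t", method="m", balanced_accuracy=1.2)


class TestSplits:
    def test_60_20_20_disjoint_and_stratified(self):
        ids = [f"r{i}" for i in range(100)]
        classes = ["a"] * 50 + ["b"] * 50
        plan = make_split_plan(ids, classes, seed=0)
        assert len(plan.contrastive_train) == 60
        assert len(plan.fewshot_pool) == 20
        assert len(plan.eval) == 20
        assert not (set(plan.contrastive_train) & set(plan.fewshot_pool))
        assert not (set(plan.eval) & set(plan.fewshot_pool))
        assert not (set(plan.eval) & set(plan.contrastive_train))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(("a", "b"), ("b", "c"), ("d",))

    def test_fraction_sampler_half_of_100(self):
        ids = [f"r{i}" for i in range(100)]
        labels = {r: i % 2 == 0 for i, r in enumerate(ids)}
        chosen = stratified_fraction(ids, labels, 0.5, np.random.default_rng(0))
        assert len(chosen) == 50
        values = [labels[r] for r in chosen]
        assert sum(values) == 25

    def test_fraction_sampler_guarantees_both_classes(self):
        ids = [f"r{i}" for i in range(40)]
        labels = {r: i % 2 == 0 for i, r in enumerate(ids)}
        chosen = stratified_fraction(ids, labels, 1 / 50, np.random.default_rng(0))
        values = {labels[r] for r in chosen}
        assert values == {True, False}

    def test_fraction_sampler_single_class_pool_rejected(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError, match="both classes"):
            stratified_fraction(ids, {"a": True, "b": True}, 0.5,
                                np.random.default_rng(0))

    def test_subset_hash_order_invariant(self):
        assert subset_hash(["b", "a"]) == subset_hash(["a", "b"])
        assert subset_hash(["a"]) != subset_hash(["a", "b"])


class TestFewShotProtocol:
    @staticmethod
    def _toy_data(n=50, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"r{i}" for i in range(n)]
        labels = {r: i % 2 == 0 for i, r in enumerate(ids)}
        emb = {r: rng.normal(loc=3.0 if labels[r] else -3.0, size=8)
               for r in ids}
        return ids, labels, emb

    def test_identical_subsets_across_methods(self):
        ids, labels, emb = self._toy_data()
        plan = make_split_plan(ids, [labels[r] for r in ids], seed=0,
                               fractions=(0.5, 0.1))
        data = FewShotData(labels=labels, embeddings=emb, alt_embeddings=emb)
        df = few_shot_protocol(plan, data,
                               methods=("eegclip_logreg", "alternative_task"),
                               seeds=(0, 1), task="pathological")
        for _, group in df.groupby(["fraction", "seed"]):
            assert group["subset_hash"].nunique() == 1

    def test_separable_embeddings_score_high(self):
        ids, labels, emb = self._toy_data()
        plan = make_split_plan(ids, [labels[r] for r in ids], seed=0,
                               fractions=(0.5,))
        data = FewShotData(labels=labels, embeddings=emb)
        df = few_shot_protocol(plan, data, methods=("eegclip_logreg",),
                               seeds=(0,), task="pathological")
        assert df["balanced_accuracy"].iloc[0] == 1.0

    def test_confidence_bands_are_percentile_intervals(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        values = np.clip(0.75 + rng.normal(0, 0.05, size=40), 0, 1)
        rows = [{"task": "t", "method": "m", "fraction": 0.5, "seed": s,
                 "balanced_accuracy": float(v)} for s, v in enumerate(values)]
        bands = confidence_bands(pd.DataFrame(rows))
        row = bands.iloc[0]
        assert row.lo == pytest.approx(np.quantile(values, 0.1))
        assert row.hi == pytest.approx(np.quantile(values, 0.9))
        assert row.lo <= row["mean"] <= row.hi
        narrow = confidence_bands(pd.DataFrame(rows), level=0.5).iloc[0]
        assert (narrow.hi - narrow.lo) <= (row.hi - row.lo)

    def test_unknown_method_rejected(self):
        ids, labels, emb = self._toy_data(20)
        plan = make_split_plan(ids, [labels[r] for r in ids], seed=0,
                               fractions=(0.5,))
        data = FewShotData(labels=labels, embeddings=emb)
        with pytest.raises(ValueError, match="unknown method"):
            few_shot_protocol(plan, data, methods=("boosting",), seeds=(0,))

    def test_default_fractions(self):
        assert FEWSHOT_FRACTIONS == (1 / 2, 1 / 5, 1 / 10, 1 / 20, 1 / 50)
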