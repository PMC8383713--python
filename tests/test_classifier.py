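import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msnakit import (
    ClassifierConfig,
    LabeledWindowSet,
    build_classifier,
    load_model,
    predict_window,
    roc_auc,
    save_model,
    simulate_labeled_windows,
    split_train_test,
    train_once,
    train_repeated,
    triplicate_positives,
)
from msnakit.classifier import TrainingError


def small_dataset(n=60, input_len=64, seed=0, separation=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, input_len))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X[: n // 2, input_len // 2] += separation
    perm = rng.permutation(n)
    return LabeledWindowSet(X[perm], y[perm])


SMALL_CFG = dict(input_len=64, hidden_widths=(16, 8, 4, 4, 4), epochs=5, batch_size=8)


class TestSplit:
    def test_1100_gives_880_220(self):
        ds = small_dataset(n=1100)
        train, test = split_train_test(ds, 0.8, seed=1)
        assert len(train) == 880
        assert len(test) == 220

    def test_determinism(self):
        ds = small_dataset()
        t1 = split_train_test(ds, 0.8, seed=5)
        t2 = split_train_test(ds, 0.8, seed=5)
        np.testing.assert_array_equal(t1[0].windows, t2[0].windows)
        np.testing.assert_array_equal(t1[1].labels, t2[1].labels)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(4, 200), st.integers(0, 2**31 - 1))
    def test_partition_law(self, n, seed):
        ds = LabeledWindowSet(np.arange(n, dtype=float)[:, None], np.zeros(n, dtype=int))
        train, test = split_train_test(ds, 0.8, seed)
        combined = np.sort(np.concatenate([train.windows[:, 0], test.windows[:, 0]]))
        np.testing.assert_array_equal(combined, np.arange(n))

    def test_too_small_rejected(self):
        ds = LabeledWindowSet(np.zeros((1, 4)), np.zeros(1, dtype=int))
        with pytest.raises(ValueError):
            split_train_test(ds, 0.8, seed=0)


class TestTriplication:
    def test_880_with_306_positives_gives_1492(self):
        rng = np.random.default_rng(2)
        y = np.zeros(880, dtype=int)
        y[:306] = 1
        ds = LabeledWindowSet(rng.normal(0, 1, (880, 8)), y)
        out = triplicate_positives(ds, seed=0)
        assert len(out) == 1492
        assert out.labels.sum() == 3 * 306

    def test_no_positives_unchanged_in_size(self):
        ds = LabeledWindowSet(np.random.default_rng(0).normal(0, 1, (10, 4)), np.zeros(10, dtype=int))
        assert len(triplicate_positives(ds)) == 10

    def test_all_positive_triples(self):
        ds = LabeledWindowSet(np.random.default_rng(0).normal(0, 1, (10, 4)), np.ones(10, dtype=int))
        assert len(triplicate_positives(ds)) == 30

    def test_content_unchanged(self):
        ds = small_dataset(n=20, input_len=8)
        out = triplicate_positives(ds, seed=3)
        orig = {tuple(w) for w in ds.windows}
        assert {tuple(w) for w in out.windows} == orig


class TestBuildPredict:
    def test_preset_dimensions(self):
        m1 = build_classifier(ClassifierConfig.preset("dtct1"))
        assert m1.input_len == 4001
        assert m1.weights[-1].shape[1] == 2
        m2 = build_classifier(ClassifierConfig.preset("dtct2"))
        assert m2.input_len == 1000
        assert len(m2.weights) == 6  # five hidden + output

    def test_preset_protocols(self):
        c1 = ClassifierConfig.preset("dtct1")
        c2 = ClassifierConfig.preset("dtct2")
        c3 = ClassifierConfig.preset("dtct3")
        assert (c1.batch_size, c1.epochs) == (32, 6)
        assert (c2.batch_size, c2.epochs) == (32, 20)
        assert (c3.batch_size, c3.epochs) == (16, 35)
        assert c2.triplicate_positives and not c1.triplicate_positives

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            ClassifierConfig.preset("dtct9")

    def test_softmax_outputs_sum_to_one(self):
        model = build_classifier(ClassifierConfig(**SMALL_CFG), seed=0)
        rng = np.random.default_rng(1)
        p_neg, p_pos, label = predict_window(model, rng.normal(0, 1, 64))
        assert p_neg + p_pos == pytest.approx(1.0, abs=1e-6)
        assert label == int(p_pos >= p_neg)

    def test_length_mismatch_rejected(self):
        model = build_classifier(ClassifierConfig(**SMALL_CFG), seed=0)
        with pytest.raises(ValueError):
            predict_window(model, np.zeros(63))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ClassifierConfig(hidden_widths=())
        with pytest.raises(ValueError):
            ClassifierConfig(dropout_rate=1.0)


BUMP_CFG = dict(input_len=200, hidden_widths=(32, 16, 8, 4, 4), epochs=10, batch_size=8)


class TestTrainOnce:
    def test_separable_set_high_accuracy(self):
        ds = simulate_labeled_windows(160, input_len=200, separation=5.0, seed=0)
        res = train_once(ds, ClassifierConfig(**BUMP_CFG), seed=0)
        assert res.accuracy >= 0.9

    def test_curves_have_epoch_length(self):
        ds = small_dataset(n=80)
        cfg = ClassifierConfig(**SMALL_CFG)
        res = train_once(ds, cfg, seed=0)
        for curve in (res.train_accuracy_curve, res.test_accuracy_curve,
                      res.train_loss_curve, res.test_loss_curve):
            assert curve.size == cfg.epochs

    def test_single_class_split_errors(self):
        ds = LabeledWindowSet(np.random.default_rng(0).normal(0, 1, (40, 8)), np.zeros(40, dtype=int))
        with pytest.raises(TrainingError):
            train_once(ds, ClassifierConfig(input_len=8, hidden_widths=(4,), epochs=1), seed=0)

    def test_determinism(self):
        ds = small_dataset(n=80)
        cfg = ClassifierConfig(**SMALL_CFG)
        r1 = train_once(ds, cfg, seed=9)
        r2 = train_once(ds, cfg, seed=9)
        assert r1.accuracy == r2.accuracy
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.model.weights[0], r2.model.weights[0])

    def test_input_len_mismatch(self):
        ds = small_dataset(n=40, input_len=32)
        with pytest.raises(ValueError):
            train_once(ds, ClassifierConfig(**SMALL_CFG), seed=0)


class TestTrainRepeated:
    def test_bookkeeping(self):
        ds = small_dataset(n=80)
        cfg = ClassifierConfig(**SMALL_CFG, n_repetitions=5, seed=3)
        report, model = train_repeated(ds, cfg)
        assert len(report.per_rep_accuracy) == 5
        assert len(report.per_rep_auc) == 5
        assert report.mean_test_accuracy_curve.size == cfg.epochs
        assert model is not None

    def test_mean_accuracy_on_separable_set(self):
        ds = simulate_labeled_windows(160, input_len=200, separation=5.0, seed=0)
        cfg = ClassifierConfig(**BUMP_CFG, n_repetitions=3, seed=0)
        report, _ = train_repeated(ds, cfg)
        assert np.mean(report.per_rep_accuracy) >= 0.9


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_reversed(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_ties_averaged(self):
        assert roc_auc(np.array([0, 1]), np.array([0.5, 0.5])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4), np.linspace(0, 1, 4))


class TestPersistence:
    def test_round_trip_bit_stable(self, tmp_path):
        ds = small_dataset(n=80)
        res = train_once(ds, ClassifierConfig(**SMALL_CFG), seed=0)
        save_model(res.model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        for w1, w2 in zip(res.model.weights, back.weights):
            np.testing.assert_array_equal(w1, w2)
        x = np.random.default_rng(0).normal(0, 1, 64)
        assert predict_window(res.model, x) == predict_window(back, x)
        assert back.config == res.model.config


def test_simulated_burst_windows_separable():
    ds = simulate_labeled_windows(120, input_len=200, separation=6.0, seed=2)
    cfg = ClassifierConfig(input_len=200, hidden_widths=(32, 16, 8, 4, 4), epochs=10, batch_size=8)
    res = train_once(ds, cfg, seed=2)
    assert res.accuracy >= 0.85
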