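import numpy as np
import pandas as pd
import pytest

from steppedemo import nn
from steppedemo.cnn_abc import (
    TrainingSpec,
    abc_estimate_parameters,
    abc_select_model,
    calibrate_temperature,
    evaluate_classifier,
    free_param_names,
    predict_probabilities,
    train_classifier,
    train_regressor,
    transform_params,
)
from steppedemo.demography import ScenarioId

from conftest import make_toy_table


class _StubModel:
    """Duck-typed model emitting fixed logits (for contract tests)."""

    def __init__(self, logits, input_shape=(20, 60), n_classes=3):
        self._logits = np.asarray(logits, dtype=float)
        self.input_shape = input_shape
        self.n_classes = n_classes

    def logits(self, images):
        n = 1 if np.asarray(images).ndim == 2 else len(images)
        return np.broadcast_to(self._logits, (n, self._logits.shape[-1])).copy()


class TestTrainClassifier:
    def test_separable_toy_classes_learned(self, toy_model, toy_tables):
        ev = evaluate_classifier(toy_model, 1.0, toy_tables["test"])
        assert ev.accuracy == 1.0
        assert np.array_equal(ev.confusion, np.diag([30, 30, 30]))

    def test_permuted_labels_give_chance_accuracy(self, toy_tables):
        shuffled = make_toy_table(60, seed=21, shuffle_labels=True)
        model = train_classifier(shuffled, toy_tables["val"], TrainingSpec(epochs=8), seed=1)
        ev = evaluate_classifier(model, 1.0, toy_tables["test"])
        # chance level for 3 balanced classes, 90 test items: 3 sigma band
        assert abs(ev.accuracy - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 90)

    def test_training_is_deterministic_in_seed(self, toy_tables):
        spec = TrainingSpec(epochs=2)
        a = train_classifier(toy_tables["train"], toy_tables["val"], spec, seed=7)
        b = train_classifier(toy_tables["train"], toy_tables["val"], spec, seed=7)
        c = train_classifier(toy_tables["train"], toy_tables["val"], spec, seed=8)
        assert a.weights_hash() == b.weights_hash()
        assert a.weights_hash() != c.weights_hash()

    def test_shape_mismatch_rejected(self, toy_tables):
        other = make_toy_table(5, height=10, seed=3)
        with pytest.raises(ValueError, match="shape"):
            train_classifier(toy_tables["train"], other, TrainingSpec(epochs=1), seed=0)


class TestCalibration:
    def test_never_increases_nll_and_preserves_argmax(self, toy_model, toy_tables):
        val = toy_tables["val"]
        calib = calibrate_temperature(toy_model, val)
        assert calib.temperature > 0
        assert calib.loss_after <= calib.loss_before
        raw = toy_model.logits(val.images)
        cal = predict_probabilities(toy_model, calib.temperature, val.images)
        assert np.array_equal(raw.argmax(axis=1), cal.argmax(axis=1))

    def test_recovers_unit_temperature_for_true_log_probabilities(self):
        """Labels drawn from the very distribution the logits encode: the NLL
        optimum is T = 1."""
        rng = np.random.default_rng(0)
        n = 4000
        logits = rng.normal(size=(n, 3))
        probs = nn.softmax(logits)
        labels = np.array([rng.choice(3, p=p) for p in probs])

        class _VaryingStub(_StubModel):
            def logits(self, images):
                return logits

        table = make_toy_table(5, seed=1)
        table.images = np.zeros((n, 20, 60), dtype=np.int8)
        table.labels = labels
        calib = calibrate_temperature(_VaryingStub(np.zeros(3)), table)
        assert calib.temperature == pytest.approx(1.0, abs=0.05)

    def test_single_class_validation_rejected(self, toy_model, toy_tables):
        val = toy_tables["val"]
        single = val.subset(np.flatnonzero(val.labels == 0))
        with pytest.raises(ValueError, match="class"):
            calibrate_temperature(toy_model, single)


class TestPredictProbabilities:
    def test_zero_logits_give_uniform(self):
        stub = _StubModel(np.zeros(3))
        probs = predict_probabilities(stub, 1.0, np.zeros((4, 20, 60), dtype=np.int8))
        assert np.allclose(probs, 1 / 3)

    def test_high_temperature_limit_approaches_uniform(self):
        stub = _StubModel(np.array([5.0, -1.0, 0.5]))
        probs = predict_probabilities(stub, 1e6, np.zeros((2, 20, 60), dtype=np.int8))
        assert np.allclose(probs, 1 / 3, atol=1e-5)

    def test_rows_sum_to_one_and_order_preserved(self, toy_model, toy_tables):
        imgs = toy_tables["test"].images
        probs = predict_probabilities(toy_model, 2.0, imgs)
        assert probs.shape == (len(imgs), 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        first = predict_probabilities(toy_model, 2.0, imgs[:1])
        assert np.allclose(first[0], probs[0])


class TestEvaluate:
    def test_constant_predictor_on_balanced_test(self, toy_tables):
        stub = _StubModel(np.array([10.0, 0.0, 0.0]))
        ev = evaluate_classifier(stub, 1.0, toy_tables["test"])
        assert ev.accuracy == pytest.approx(1 / 3)
        assert ev.confusion.sum(axis=1).tolist() == [30, 30, 30]


class TestAbcSelectModel:
    def test_full_tolerance_returns_label_prior_exactly(self):
        rng = np.random.default_rng(1)
        ref = rng.dirichlet(np.ones(3), size=90)
        labels = np.repeat([0, 1, 2], 30)
        res = abc_select_model(np.array([0.5, 0.3, 0.2]), ref, labels, tolerance=1.0)
        assert np.array_equal(res.pp, [1 / 3, 1 / 3, 1 / 3])

    def test_exact_match_with_minimal_tolerance(self):
        rng = np.random.default_rng(2)
        ref = rng.dirichlet(np.ones(3), size=30)
        labels = np.repeat([0, 1, 2], 10)
        res = abc_select_model(ref[17], ref, labels, tolerance=1 / 30)
        assert res.pp[labels[17]] == 1.0

    def test_pp_always_sums_to_one(self):
        rng = np.random.default_rng(3)
        ref = rng.dirichlet(np.ones(3), size=60)
        labels = np.repeat([0, 1, 2], 20)
        for tol in (0.05, 0.33, 0.9):
            res = abc_select_model(rng.dirichlet(np.ones(3)), ref, labels, tolerance=tol)
            assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(res.retained) == round(tol * 60)

    def test_unbalanced_reference_warns(self):
        ref = np.tile([[0.4, 0.3, 0.3]], (5, 1))
        with pytest.warns(UserWarning, match="balanced"):
            abc_select_model(np.array([1.0, 0.0, 0.0]), ref, np.array([0, 0, 0, 1, 2]), 1.0)


def regression_table(n=480, seed=4, shuffle_targets=False):
    """Images whose +1 fraction encodes log10(t_split): R^2 -> 1 is achievable.

    With ``shuffle_targets`` the stored t_split values are permuted AFTER the
    images are drawn, severing the image-target link."""
    table = make_toy_table(n // 3, seed=seed)
    rng = np.random.default_rng(seed + 1)
    scen = int(ScenarioId.PARALLEL_EXPANSION)
    table = table.subset(np.flatnonzero(table.labels == scen))
    t_split = table.params["t_split_years"].to_numpy()
    lo, hi = np.log10(3e5), np.log10(1.6e6)
    frac = 0.1 + 0.8 * (np.log10(t_split) - lo) / (hi - lo)
    images = np.stack(
        [
            np.where(rng.random((20, 60)) < f, 1, -1).astype(np.int8)
            for f in frac
        ]
    )
    table.images = images
    if shuffle_targets:
        table.params["t_split_years"] = rng.permutation(t_split)
    return table


class TestTrainRegressor:
    SMALL_SPEC = TrainingSpec(epochs=60, conv_channels=(8, 8), kernels=(2, 5),
                              learning_rate=3e-3)

    def test_learns_constructed_signal(self):
        table = regression_table()
        reg = train_regressor(table, self.SMALL_SPEC, seed=0)
        held = regression_table(seed=40)
        pred = reg.predict(held.images)
        j = reg.param_names.index("t_split_years")
        truth = transform_params(held.params, ["t_split_years"])[:, 0]
        resid = truth - pred[:, j]
        r2 = 1 - resid.var() / truth.var()
        assert r2 > 0.85

    def test_shuffled_targets_learn_nothing(self):
        table = regression_table(shuffle_targets=True)
        reg = train_regressor(table, self.SMALL_SPEC, seed=0)
        held = regression_table(seed=41, shuffle_targets=True)
        pred = reg.predict(held.images)
        j = reg.param_names.index("t_split_years")
        truth = transform_params(held.params, ["t_split_years"])[:, 0]
        resid = truth - pred[:, j]
        r2 = 1 - resid.var() / truth.var()
        assert r2 < 0.2

    def test_deterministic_and_single_scenario_required(self, toy_tables):
        table = regression_table(n=90)
        a = train_regressor(table, TrainingSpec(epochs=2), seed=5)
        b = train_regressor(table, TrainingSpec(epochs=2), seed=5)
        assert np.allclose(a.predict(table.images[:3]), b.predict(table.images[:3]))
        with pytest.raises(ValueError, match="single scenario"):
            train_regressor(toy_tables["train"], TrainingSpec(epochs=1), seed=0)


class TestAbcEstimateParameters:
    def _ref(self, n=60, seed=6):
        rng = np.random.default_rng(seed)
        names = free_param_names(int(ScenarioId.PARALLEL_EXPANSION))
        table = make_toy_table(n // 3 + 1, seed=seed)
        table = table.subset(np.flatnonzero(table.labels == 0)).subset(np.arange(n // 3))
        params = table.params
        preds = transform_params(params, names) + rng.normal(scale=0.05, size=(len(params), len(names)))
        return preds, params, names

    def test_full_tolerance_reproduces_reference_medians(self):
        preds, params, names = self._ref()
        post = abc_estimate_parameters(preds[0], preds, params, 1.0, param_names=names)
        for name in names:
            assert post.summary.loc[name, "median"] == np.median(params[name])

    def test_tiny_tolerance_concentrates_on_matching_record(self):
        preds, params, names = self._ref()
        post = abc_estimate_parameters(preds[7], preds, params, 1.0 / len(params), param_names=names)
        assert len(post.samples) == 1
        assert post.samples.iloc[0]["t_split_years"] == params.iloc[7]["t_split_years"]

    def test_zero_variance_dimension_dropped_with_warning(self):
        preds, params, names = self._ref()
        preds = preds.copy()
        preds[:, 2] = 1.234
        obs = preds[0]
        with pytest.warns(UserWarning, match="zero-variance"):
            post = abc_estimate_parameters(obs, preds, params, 0.5, param_names=names)
        assert (post.summary["hpd_low"] <= post.summary["median"]).all()
        assert (post.summary["median"] <= post.summary["hpd_high"]).all()


def test_transform_params_scales():
    df = pd.DataFrame(
        {"t_split_years": [1e6], "n_anc": [1e4], "m_ez_to_z_pre": [1e-3]}
    )
    out = transform_params(df, ["t_split_years", "n_anc", "m_ez_to_z_pre"])
    assert out[0, 0] == pytest.approx(6.0)
    assert out[0, 1] == pytest.approx(4.0)
    assert out[0, 2] == pytest.approx(np.log(1e-3 / (1 - 1e-3)))
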