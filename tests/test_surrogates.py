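"""Surrogate training, prediction and uncertainty estimation."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import poolbo as pb
from poolbo.surrogates import (
    NeuralNetSurrogate,
    RandomForestSurrogate,
    SurrogateError,
    SurrogateSpec,
    TrainingSet,
    create_surrogate,
    load_checkpoint,
    mve_loss,
    save_checkpoint,
    train,
)


def _toy_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = (rng.random((n, 2048)) < 0.05).astype(np.uint8)
    w = rng.normal(size=2048)
    return TrainingSet(x, x @ w)


class TestSpecValidation:
    def test_unknown_architecture_rejected(self):
        with pytest.raises(SurrogateError):
            SurrogateSpec(architecture="gp")

    def test_incompatible_uncertainty_rejected(self):
        with pytest.raises(SurrogateError):
            SurrogateSpec(architecture="rf", uncertainty_method="mc-dropout")

    def test_architecture_defaults(self):
        assert SurrogateSpec(architecture="rf").resolved_uncertainty == "ensemble-variance"
        assert SurrogateSpec(architecture="nn").resolved_uncertainty == "mc-dropout"

    def test_mpn_not_available(self):
        with pytest.raises(NotImplementedError):
            create_surrogate(SurrogateSpec(architecture="mpn"))


class TestRandomForest:
    def test_constant_targets_predict_constant(self):
        data = _toy_data()
        const = TrainingSet(data.inputs, np.full(len(data), 3.25))
        model = RandomForestSurrogate(SurrogateSpec(), seed=0).fit(const)
        pred = model.predict(data.inputs)
        assert np.allclose(pred.mean, 3.25)

    def test_single_tree_forest_has_zero_variance(self):
        data = _toy_data()
        model = RandomForestSurrogate(
            SurrogateSpec(rf_trees=1), seed=0
        ).fit(data)
        pred = model.predict(data.inputs)
        assert np.all(pred.variance == 0.0)

    def test_variance_is_across_tree_variance(self):
        data = _toy_data()
        model = RandomForestSurrogate(SurrogateSpec(), seed=0).fit(data)
        pred = model.predict(data.inputs[:5])
        per_tree = np.stack(
            [t.predict(data.inputs[:5].astype(float)) for t in model._forest.estimators_]
        )
        assert np.allclose(pred.mean, per_tree.mean(axis=0))
        assert np.allclose(pred.variance, per_tree.var(axis=0))


class TestNeuralNet:
    def test_inference_without_dropout_is_deterministic(self):
        data = _toy_data()
        model = NeuralNetSurrogate(
            SurrogateSpec(architecture="nn", uncertainty_method="none"), seed=1
        ).fit(data)
        a = model.predict(data.inputs)
        b = model.predict(data.inputs)
        assert np.array_equal(a.mean, b.mean)

    def test_mc_dropout_with_p_zero_has_exactly_zero_variance(self):
        data = _toy_data()
        model = NeuralNetSurrogate(
            SurrogateSpec(architecture="nn", nn_dropout=0.0), seed=1
        ).fit(data)
        pred = model.predict(data.inputs)
        assert np.all(pred.variance == 0.0)

    def test_mc_dropout_matches_large_sample_estimate(self):
        """The 10-pass MC-dropout mean/variance should agree with a
        10,000-pass estimate within Monte-Carlo error on a fixed net."""
        data = _toy_data(n=30, seed=3)
        model = NeuralNetSurrogate(SurrogateSpec(architecture="nn"), seed=2).fit(data)
        x = data.inputs[:8]
        few = model.predict(x, mc_seed=11)
        big_spec = SurrogateSpec(architecture="nn", nn_mc_passes=10_000)
        model.spec = big_spec  # same weights, more passes
        many = model.predict(x, mc_seed=12)
        # SE of a 10-pass mean is sqrt(var/10); allow 4 Ssuch errors
        se_mean = np.sqrt(many.variance / 10)
        assert np.all(np.abs(few.mean - many.mean) <= 4 * se_mean + 1e-9)
        # variances agree within the (wide) sampling error of a 10-pass
        # variance estimate: sd(s^2) ~ var * sqrt(2/(n-1))
        se_var = many.variance * math.sqrt(2.0 / 9.0)
        assert np.all(np.abs(few.variance - many.variance) <= 4 * se_var + 1e-9)

    def test_fewer_than_two_distinct_targets_warns_and_fits(self):
        data = _toy_data()
        const = TrainingSet(data.inputs, np.zeros(len(data)))
        model = NeuralNetSurrogate(
            SurrogateSpec(architecture="nn", uncertainty_method="none"), seed=0
        )
        with pytest.warns(UserWarning, match="distinct targets"):
            model.fit(const)
        pred = model.predict(data.inputs)
        assert np.all(np.isfinite(pred.mean))

    def test_mve_head_variance_positive(self):
        data = _toy_data(n=60, seed=4)
        model = NeuralNetSurrogate(
            SurrogateSpec(architecture="nn", uncertainty_method="mve"), seed=0
        ).fit(data)
        pred = model.predict(data.inputs)
        assert np.all(pred.variance > 0)
        assert np.all(np.isfinite(pred.mean))


class TestMveLoss:
    def test_zero_residual_unit_variance(self):
        assert mve_loss(1.0, 1.0, 1.0) == pytest.approx(0.5 * math.log(2 * math.pi))

    def test_direct_evaluation(self):
        assert mve_loss(0.0, 2.0, 1.0) == pytest.approx(
            0.5 * math.log(4 * math.pi) + 0.25
        )

    def test_minimized_over_variance_at_squared_residual(self):
        mean, target = 0.3, 1.7
        opt = (target - mean) ** 2
        grid = np.linspace(0.1 * opt, 10 * opt, 2001)
        losses = [mve_loss(mean, v, target) for v in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(opt, rel=5e-3)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(SurrogateError):
            mve_loss(0.0, 0.0, 1.0)

    def test_batch_loss_is_mean_over_examples(self):
        means, variances, targets = np.array([0.0, 1.0]), np.array([1.0, 2.0]), np.array([1.0, 0.0])
        per = [mve_loss(m, v, t) for m, v, t in zip(means, variances, targets)]
        assert mve_loss(means, variances, targets) == pytest.approx(np.mean(per))


class TestRecovery:
    """On a noiseless linear landscape, a surrogate trained on 10% of the
    pool should rank the held-out 90% well."""

    def test_rf_recovery(self, recovery_fixture):
        fx = recovery_fixture
        rng = np.random.default_rng(5)
        idx = rng.permutation(fx.pool.size)
        n_tr = fx.pool.size // 10
        tr, te = idx[:n_tr], idx[n_tr:]
        model = RandomForestSurrogate(SurrogateSpec(), seed=0).fit(
            TrainingSet(fx.pool.fingerprints[tr], fx.true_objective[tr])
        )
        rho = spearmanr(
            model.predict(fx.pool.fingerprints[te]).mean, fx.true_objective[te]
        ).statistic
        assert rho > 0.7

    def test_nn_recovery(self, trained_nn, recovery_fixture):
        model, _tr, te = trained_nn
        fx = recovery_fixture
        rho = spearmanr(
            model.predict(fx.pool.fingerprints[te]).mean, fx.true_objective[te]
        ).statistic
        assert rho > 0.7

    def test_predictions_finite_and_variance_nonnegative(self, trained_nn, recovery_fixture):
        model, _, _ = trained_nn
        pred = model.predict(recovery_fixture.pool.fingerprints)
        assert np.all(np.isfinite(pred.mean))
        assert np.all(pred.variance >= 0)


class TestTrainEntryPoint:
    def test_full_mode_reinitializes(self):
        data = _toy_data()
        spec = SurrogateSpec(architecture="rf")
        m1 = train(spec, data, seed=9)
        m2 = train(spec, data, seed=9)
        assert np.allclose(
            m1.predict(data.inputs).mean, m2.predict(data.inputs).mean
        )

    def test_online_mode_continues_previous_nn(self):
        data = _toy_data(n=60)
        spec = SurrogateSpec(architecture="nn", retrain_mode="online",
                             uncertainty_method="none")
        first = train(spec, data, seed=0)
        before = first.predict(data.inputs).mean.copy()
        more = TrainingSet(data.inputs[:20], data.targets[:20])
        second = train(spec, more, seed=0, previous=first)
        assert second is first  # fine-tuned in place, not reinitialized
        after = second.predict(data.inputs).mean
        assert after.shape == before.shape

    def test_training_set_rejects_nonfinite_targets(self):
        data = _toy_data()
        y = data.targets.copy()
        y[0] = np.nan
        with pytest.raises(SurrogateError):
            TrainingSet(data.inputs, y)


def test_checkpoint_round_trip(tmp_path):
    data = _toy_data()
    model = RandomForestSurrogate(SurrogateSpec(), seed=0).fit(data)
    path = tmp_path / "model.joblib"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert np.array_equal(
        model.predict(data.inputs).mean, loaded.predict(data.inputs).mean
    )
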