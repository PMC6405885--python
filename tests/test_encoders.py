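import warnings

import numpy as np
import pytest

from cnnrf import build_cnn, crossval_similarity, fit_baseline, nonlinearity_index, safe_pearson, train
from cnnrf.encoders import CNNConfig, BaselineEncoder, make_baseline
from cnnrf._nn import ConvNet, sgd_momentum_step


class TestArchitecture:
    def test_feature_map_arithmetic(self):
        # 10 -> 8 -> 6 -> 4 -> 2 after four valid 3x3 convolutions, then 1x1x32
        net = ConvNet(input_size=10)
        assert net._conv_out == 2 and net._pooled == 1 and net._flat == 32

    def test_too_small_input_rejected_with_trace(self):
        with pytest.raises(ValueError, match="spatial size"):
            ConvNet(input_size=8)

    def test_untrained_output_in_unit_interval(self):
        m = build_cnn()
        m.net.init_params(0)
        x = np.random.default_rng(1).standard_normal((7, 10, 10))
        y = m.predict(x)
        assert ((y > 0) & (y < 1)).all()

    def test_prediction_deterministic_without_dropout(self):
        m = build_cnn()
        m.net.init_params(0)
        x = np.random.default_rng(2).standard_normal((10, 10))
        np.testing.assert_array_equal(m.predict(x), m.predict(x))


class TestSGD:
    def test_momentum_step_scalar_oracle(self):
        # v <- 0.9 v + eps g ; w <- w - v
        w = np.array([1.0])
        v = np.array([0.5])
        sgd_momentum_step(w, v, np.array([2.0]), lr=0.1, momentum=0.9)
        assert v[0] == pytest.approx(0.9 * 0.5 + 0.1 * 2.0)
        assert w[0] == pytest.approx(1.0 - (0.9 * 0.5 + 0.1 * 2.0))

    def test_lr_decay_schedule(self):
        # eps_t = eps0 / (1 + decay t): after many updates the rate shrinks
        cfg = CNNConfig()
        assert cfg.lr_decay == 5e-5
        eps_0 = cfg.learning_rate / (1 + cfg.lr_decay * 0)
        eps_1000 = cfg.learning_rate / (1 + cfg.lr_decay * 1000)
        assert eps_0 == 0.1 and eps_1000 == pytest.approx(0.1 / 1.05)

    def test_batch_size_rule(self):
        assert CNNConfig().resolve_batch_size(300) == 5
        assert CNNConfig().resolve_batch_size(2000) == 30
        assert CNNConfig(batch_size=16).resolve_batch_size(2000) == 16


class TestTraining:
    def test_overfits_noiseless_linear_cell(self):
        # memorisation-capacity check: 20 samples, patience disabled
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 10, 10))
        w = rng.standard_normal((10, 10))
        z = x.reshape(20, -1) @ w.ravel()
        y = (z - z.min()) / (z.max() - z.min())
        cfg = CNNConfig(max_epochs=250, patience=0, val_fraction=0.0, dropout_rate=0.0)
        m = build_cnn(cfg)
        res = train(m, x, y, cfg, seed=1)
        losses = [l for _, l, _ in res.loss_history]
        assert losses[-1] < 1e-3
        # loss decreases overall and does not climb back up
        assert losses[-1] < 0.01 * losses[0]
        running_min = np.minimum.accumulate(losses)
        assert np.all(np.asarray(losses) <= running_min + 0.05 * losses[0])

    def test_training_seed_determinism(self, small_stimuli, simple_cell_noiseless):
        _, resp = simple_cell_noiseless
        cfg = CNNConfig(max_epochs=2, patience=0)
        m1 = build_cnn(cfg)
        m2 = build_cnn(cfg)
        train(m1, small_stimuli, resp.averaged[:200], cfg, seed=5)
        train(m2, small_stimuli, resp.averaged[:200], cfg, seed=5)
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])


class TestCrossval:
    def test_perfect_and_negated_predictions(self, medium_stimuli):
        responses = np.random.default_rng(3).random(500)

        class Echo:
            def __init__(self, sign):
                self.sign = sign

            def predict(self, images):
                idx = [hash(bytes(np.asarray(im, dtype=np.float64).round(6))) for im in images]
                return self.sign * np.array([lookup[i] for i in idx])

        lookup = {hash(bytes(np.asarray(im).round(6))): r for im, r in zip(medium_stimuli.images, responses)}
        pos = crossval_similarity(lambda x, y, s: Echo(1), medium_stimuli, responses, k=5, seed=0)
        neg = crossval_similarity(lambda x, y, s: Echo(-1), medium_stimuli, responses, k=5, seed=0)
        assert pos.prediction_similarity == pytest.approx(1.0)
        assert neg.prediction_similarity == pytest.approx(-1.0)

    def test_fold_assignment_reproducible(self, medium_stimuli):
        seen = []

        def factory(x, y, s):
            seen.append(x.sum())

            class Zero:
                def predict(self, images):
                    return np.zeros(len(images))

            return Zero()

        y = np.random.default_rng(1).random(500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            crossval_similarity(factory, medium_stimuli, y, k=5, seed=9)
            first = list(seen)
            seen.clear()
            crossval_similarity(factory, medium_stimuli, y, k=5, seed=9)
        assert seen == first

    def test_too_few_stimuli_rejected(self, small_stimuli):
        with pytest.raises(ValueError, match="folds|k"):
            crossval_similarity(lambda x, y, s: None, small_stimuli.images[:3], np.ones(3), k=5)


class TestBaselines:
    def test_hyperparameters_fixed(self):
        assert make_baseline("lasso").estimator.alpha == 0.01
        assert make_baseline("ridge").estimator.alpha == 1e4
        svr = make_baseline("svr").estimator
        assert svr.gamma == 0.01 and svr.C == 0.01

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            make_baseline("forest")

    def test_ridge_recovers_noiseless_linear_cell(self, simple_cell_noiseless):
        # heavy shrinkage preserves the prediction direction, but finite
        # sampling tilts S^T y away from the filter by ~sqrt(p/n), so
        # held-out r > 0.99 needs n >> 100 pixels
        from cnnrf import make_white_noise_stimuli

        spec, _ = simple_cell_noiseless
        stim = make_white_noise_stimuli(8000, size=10, seed=55)
        y = stim.flat @ spec.filters[0].ravel()
        res = fit_baseline("ridge", stim, y, k=5, seed=0)
        assert res.prediction_similarity > 0.99

    def test_full_shrinkage_reports_zero_with_warning(self, medium_stimuli):
        from sklearn.linear_model import Lasso

        def factory(x, y, s):
            est = Lasso(alpha=1e9)
            est.fit(x.reshape(len(x), -1), y)
            return BaselineEncoder(est)

        y = np.random.default_rng(2).random(500)
        with pytest.warns(UserWarning, match="constant"):
            res = crossval_similarity(factory, medium_stimuli, y, k=5, seed=0)
        assert res.prediction_similarity == 0.0


class TestNonlinearityIndex:
    @pytest.mark.parametrize(
        "r_lasso, r_cnn, expected",
        [(0.4, 0.4, 0.0), (0.0, 0.5, 1.0), (0.2, 0.4, 0.5)],
    )
    def test_arithmetic(self, r_lasso, r_cnn, expected):
        assert nonlinearity_index(r_lasso, r_cnn) == pytest.approx(expected)

    def test_nonpositive_cnn_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(nonlinearity_index(0.2, 0.0))


class TestModelOrderingProperties:
    def test_lasso_cnn_parity_on_noiseless_simple_cells(self):
        """Rectified-linear cells are nearly linear: Lasso and CNN held-out
        similarities are both high and statistically indistinguishable."""
        from scipy.stats import wilcoxon

        from cnnrf import make_white_noise_stimuli, sample_cell, simulate_responses

        stim = make_white_noise_stimuli(300, size=10, seed=77)
        cfg = CNNConfig(max_epochs=20, patience=0)
        diffs = []
        for i in range(10):
            spec = sample_cell("simple", seed=1000 + i)
            spec.noise_sd = 0.0
            resp = simulate_responses(spec, stim, seed=i)

            def factory(x, y, s):
                m = build_cnn(cfg)
                train(m, x, y, cfg, seed=s)
                return m

            r_cnn = crossval_similarity(factory, stim, resp.averaged, k=2, seed=i).prediction_similarity
            r_lasso = fit_baseline("lasso", stim, resp.averaged, k=2, seed=i).prediction_similarity
            diffs.append(r_cnn - r_lasso)
            assert r_lasso > 0.6  # a rectified-linear cell is largely linear
        assert wilcoxon(diffs).pvalue > 0.01 or abs(np.mean(diffs)) < 0.05
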