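"""Forward/reverse diffusion operators, losses and the sampling loop."""

import numpy as np
import pytest

from spinediff.diffusion import (ensemble_average, loss_bce, loss_simple,
                                 loss_total, posterior_mean, q_sample,
                                 reverse_step, sample, train_step)
from spinediff.networks import build_model
from spinediff.nn import Adam
from spinediff.schedule import make_schedule, schedule_from_betas
from spinediff.synthetic import SynthConfig, generate_pair


def one(v):
    return np.array([[v]], dtype=np.float64)


class TestQSample:
    def test_scalar_oracle(self):
        # abar = 0.64: x_t = 0.8 * 1 + 0.6 * 0.5 + 0.6 * 0.5 = 1.4
        s = schedule_from_betas([0.36])
        xt = q_sample(one(1.0), one(0.5), s, 1, one(0.5))
        assert xt[0, 0] == pytest.approx(1.4, abs=1e-12)

    def test_pure_prior_limit(self):
        # abar -> 0 (beta close to 1): x_t -> f(b) when eps = 0
        s = schedule_from_betas([1.0 - 1e-12])
        xt = q_sample(one(1.0), one(0.3), s, 1, one(0.0))
        assert xt[0, 0] == pytest.approx(0.3, abs=1e-5)

    def test_identity_limit(self):
        # abar -> 1: x_t -> x0
        s = schedule_from_betas([1e-12])
        xt = q_sample(one(0.8), one(0.1), s, 1, one(0.0))
        assert xt[0, 0] == pytest.approx(0.8, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        s = make_schedule(10)
        with pytest.raises(ValueError):
            q_sample(np.zeros((2, 2)), np.zeros((3, 3)), s, 1, np.zeros((2, 2)))

    def test_marginal_moments(self):
        """Empirical mean/variance of x_t match the closed-form marginal."""
        s = make_schedule(100)
        rng = np.random.default_rng(0)
        x0, fb, t = 1.0, 0.4, 60
        ab = s.alpha_bar_t(t)
        draws = q_sample(np.full(10000, x0), np.full(10000, fb), s, t,
                         rng.standard_normal(10000))
        exp_mean = np.sqrt(ab) * x0 + np.sqrt(1 - ab) * fb
        exp_var = 1 - ab
        se_mean = np.sqrt(exp_var / 10000)
        assert abs(draws.mean() - exp_mean) < 4 * se_mean
        se_var = exp_var * np.sqrt(2.0 / 9999)
        assert abs(draws.var(ddof=1) - exp_var) < 4 * se_var


class TestPosteriorMean:
    def test_scalar_oracle(self):
        s = schedule_from_betas([0.1, 0.1])  # alpha=0.9, abar2=0.81
        mu = posterior_mean(one(1.0), one(1.0), one(0.0), s, 2)
        expected = np.sqrt(0.9) * 0.1 / 0.19 + np.sqrt(0.9) * 0.1 / 0.19
        assert mu[0, 0] == pytest.approx(expected, abs=1e-12)
        assert mu[0, 0] == pytest.approx(0.99861, abs=1e-5)

    def test_zero_inputs(self):
        s = make_schedule(10)
        mu = posterior_mean(one(0.0), one(0.0), one(0.0), s, 5)
        assert mu[0, 0] == 0.0

    def test_first_step_collapses_to_x0(self):
        # t=1: abar_0 = 1 kills the x_t coefficient and mu = x0
        s = make_schedule(10)
        mu = posterior_mean(one(0.7), one(-3.0), one(0.0), s, 1)
        assert mu[0, 0] == pytest.approx(0.7, abs=1e-12)


class TestReverseStep:
    def test_scalar_oracle(self):
        # alpha_2 = 0.99, abar_2 = 0.5
        s = schedule_from_betas([1.0 - 0.5 / 0.99, 0.01])
        assert s.alpha_bar_t(2) == pytest.approx(0.5, abs=1e-12)
        x = reverse_step(one(1.0), one(0.5), s, 2, one(0.0))
        expected = (1.0 - (0.01 / np.sqrt(0.5)) * 0.5) / np.sqrt(0.99)
        assert x[0, 0] == pytest.approx(expected, abs=1e-12)
        assert x[0, 0] == pytest.approx(0.997932, abs=1e-6)

    def test_zero_prediction(self):
        s = make_schedule(10)
        x = reverse_step(one(1.0), one(0.0), s, 5, one(0.0))
        assert x[0, 0] == pytest.approx(1.0 / np.sqrt(s.alpha_t(5)), abs=1e-12)

    def test_last_step_rejects_noise(self):
        s = make_schedule(10)
        with pytest.raises(ValueError):
            reverse_step(one(1.0), one(0.0), s, 1, one(0.5))
        # and accepts the zero grid
        reverse_step(one(1.0), one(0.0), s, 1, one(0.0))


class TestLosses:
    def test_simple_examples(self):
        assert loss_simple(one(1.0), one(1.0)) == 0.0
        assert loss_simple(one(1.0), one(0.0)) == 1.0
        assert loss_simple(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_bce_examples(self):
        assert loss_bce(one(1.0), one(0.5)) == pytest.approx(np.log(2), abs=1e-9)
        assert loss_bce(one(0.0), one(0.5)) == pytest.approx(np.log(2), abs=1e-9)
        assert loss_bce(one(1.0), one(1.0)) == pytest.approx(0.0, abs=1e-5)

    def test_total_is_sum(self):
        eps, eps_hat = one(1.0), one(0.0)
        tgt, pred = one(1.0), one(0.5)
        total = loss_total(eps, eps_hat, tgt, pred)
        assert total == pytest.approx(1.0 + np.log(2), abs=1e-9)
        assert total >= max(loss_simple(eps, eps_hat), loss_bce(tgt, pred))


class TestEnsembleAverage:
    def test_identity_midpoint_mean(self):
        m = np.random.default_rng(0).random((4, 4))
        np.testing.assert_array_equal(ensemble_average([m]), m)
        np.testing.assert_allclose(
            ensemble_average([np.zeros((2, 2)), np.ones((2, 2))]), 0.5)
        assert ensemble_average([one(0.2), one(0.4), one(0.9)])[0, 0] == \
            pytest.approx(0.5, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])


class _ZeroDenoiser:
    """Dummy model predicting eps_hat = 0, for the loop-unrolled oracle."""

    def eval(self):
        return self

    def train(self, mode=True):
        return self

    def condition(self, image):
        from spinediff.nn import Tensor
        z = Tensor(np.zeros((1, 1) + image.shape[-2:], dtype=np.float32))
        return z, z

    def denoise(self, xt, t, cond, prior):
        from spinediff.nn import Tensor
        arr = xt.data if hasattr(xt, "data") else np.asarray(xt)
        return Tensor(np.zeros_like(arr, dtype=np.float32))


class _SeedNoiseRng:
    """Yields a fixed x_T on the first draw, then zeros (z pinned to 0)."""

    def __init__(self, xT):
        self.xT = xT
        self.first = True

    def standard_normal(self, shape):
        if self.first:
            self.first = False
            return np.full(shape, self.xT, dtype=np.float64)
        return np.zeros(shape)


class TestSampleLoop:
    def test_matches_unrolled_scalar_oracle(self):
        """With eps_hat = 0 and z = 0 the chain is a closed-form recursion."""
        s = make_schedule(5, 0.05, 0.3)
        xT = 0.37
        x = xT
        for t in range(5, 0, -1):
            x = x / np.sqrt(s.alpha_t(t))
        expected = np.clip(x, 0.0, 1.0)
        out = sample(np.zeros((1, 1)), _ZeroDenoiser(), s, _SeedNoiseRng(xT))
        assert out[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_output_in_unit_interval_and_deterministic(self):
        s = make_schedule(8)
        img, _ = generate_pair(SynthConfig(height=16, width=16, n_vertebrae=2))
        model = build_model(0)
        a = sample(img, model, s, np.random.default_rng(5))
        b = sample(img, model, s, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0


class TestSampleEnsemble:
    def test_batch_of_one_matches_single_chain(self):
        from spinediff.diffusion import sample_ensemble
        s = make_schedule(10)
        img, _ = generate_pair(SynthConfig(height=24, width=16, n_vertebrae=2))
        model = build_model(2)
        a = sample(img, model, s, np.random.default_rng(8))
        b = sample_ensemble(img, model, s, np.random.default_rng(8), 1)[0]
        np.testing.assert_array_equal(a, b)

    def test_chains_differ_and_stay_bounded(self):
        from spinediff.diffusion import sample_ensemble
        s = make_schedule(10)
        img, _ = generate_pair(SynthConfig(height=24, width=16, n_vertebrae=2))
        model = build_model(2)
        chains = sample_ensemble(img, model, s, np.random.default_rng(8), 3)
        assert len(chains) == 3
        assert not np.array_equal(chains[0], chains[1])
        for c in chains:
            assert c.min() >= 0.0 and c.max() <= 1.0


class TestTrainStep:
    def test_deterministic_and_finite(self):
        cfg = SynthConfig(height=32, width=16, n_vertebrae=2)
        img, msk = generate_pair(cfg)
        s = make_schedule(20)
        losses = []
        for _ in range(2):
            model = build_model(7)
            opt = Adam(model.parameters(), lr=1e-3)
            rng = np.random.default_rng(42)
            trace = [train_step(img, msk.astype(np.float32), model, s, opt,
                                rng)["loss"] for _ in range(3)]
            losses.append(trace)
        assert losses[0] == losses[1]
        assert all(np.isfinite(v) and v >= 0 for v in losses[0])

    def test_loss_trend_decreases(self):
        """Short training run lowers the moving-average hybrid loss."""
        cfg = SynthConfig(height=48, width=32, n_vertebrae=3)
        img, msk = generate_pair(cfg)
        s = make_schedule(50)
        model = build_model(1)
        opt = Adam(model.parameters(), lr=1e-3)
        rng = np.random.default_rng(3)
        trace = [train_step(img, msk.astype(np.float32), model, s, opt,
                            rng)["loss"] for _ in range(150)]
        assert np.mean(trace[-30:]) < np.mean(trace[:30])
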