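"""ELBO assembly, Gaussian KL closed forms, contrastive loss, the
training loop's contracts, and the overfitting detector."""

import numpy as np
import pytest

import gyrosde as g
from gyrosde.autodiff import Tensor
from gyrosde.exceptions import InvalidArgumentError
from gyrosde.generative import GenerativeConfig, GenerativeModel, PCAPrior
from gyrosde.inference import GPT2Posterior, TransformerConfig
from gyrosde.model import MotionSDE
from gyrosde.training import (ContrastNet, contrast_loss, detect_overfitting,
                              elbo_objective, gaussian_kl)


class TestGaussianKL:
    def test_identical_distributions(self):
        assert gaussian_kl([0.3, 0.4], 1.2, [0.3, 0.4], 1.2) == 0.0

    def test_unit_gaussians_shifted_mean(self):
        assert gaussian_kl([0.0], 1.0, [1.0], 1.0) == pytest.approx(0.5)

    def test_k2_scale_mismatch(self):
        expected = 2 * np.log(2.0) + 2.0 / 8.0 - 1.0  # ~ 0.63629
        assert gaussian_kl([0.0, 0.0], 1.0, [0.0, 0.0], 2.0) \
            == pytest.approx(expected, abs=1e-5)

    def test_nonnegative_over_random_parameters(self, rng):
        for _ in range(200):
            mu_q, mu_p = rng.standard_normal((2, 3))
            sd_q, sd_p = np.exp(rng.standard_normal(2))
            assert gaussian_kl(mu_q, sd_q, mu_p, sd_p) >= 0.0

    def test_bad_sd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gaussian_kl([0.0], 0.0, [0.0], 1.0)


def _toy_models(L=3):
    """Hand-set tiny networks: zero drift, zero decoder output, unit
    observation sd, unit posterior sd, zero posterior means, mu0 = 0."""
    rng = np.random.default_rng(0)
    gen = GenerativeModel(GenerativeConfig(drift_hidden=(4,),
                                           decoder_hidden=(4,)), rng)
    gen.decoder_net.layers[-1].w.data[:] = 0.0
    gen.decoder_net.layers[-1].b.data[:] = 0.0
    gen.obs_log_sd.data = np.asarray(0.0)
    post = GPT2Posterior(TransformerConfig(n_layers=0, embed_dim=4,
                                           max_len=L), rng)
    post.head.w.data[:] = 0.0
    post.head.b.data[:] = 0.0
    post.q_log_sd.data = np.asarray(0.0)
    prior = PCAPrior(sigma0=0.2)
    prior.components_ = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
    prior.mean_ = np.zeros(4)
    return gen, post, prior


class TestElbo:
    def test_hand_assembled_toy(self):
        """Window of 3 zero frames: two reconstruction terms at the
        4-D standard-normal mode, one initial KL against the tight
        sigma_0 = 0.2 prior, one transition KL against the SDE noise."""
        gen, post, prior = _toy_models(L=3)
        windows = np.zeros((1, 3, 4))
        loss, bd, _ = elbo_objective(windows, gen, post, prior, seed=0,
                                     sample_noise=False)
        expected_recon = 2 * (-4 * 0.5 * np.log(2 * np.pi))
        expected_kl0 = gaussian_kl([0.0, 0.0], 1.0, [0.0, 0.0], 0.2)
        expected_kltr = gaussian_kl([0.0, 0.0], 1.0, [0.0, 0.0],
                                    gen.sigma_theta)
        assert bd.recon == pytest.approx(expected_recon, abs=1e-9)
        assert bd.kl_initial == pytest.approx(expected_kl0, abs=1e-9)
        assert bd.kl_transitions == pytest.approx(expected_kltr, abs=1e-9)
        assert float(loss.data) == pytest.approx(-bd.elbo, abs=1e-9)

    def test_matched_initial_distribution_zeroes_kl(self):
        gen, post, prior = _toy_models(L=2)
        post.q_log_sd.data = np.asarray(np.log(0.2))  # q(z0|x0) = p(z0)
        _, bd, _ = elbo_objective(np.zeros((1, 2, 4)), gen, post, prior,
                                  seed=0, sample_noise=False)
        assert bd.kl_initial == pytest.approx(0.0, abs=1e-12)
        assert bd.kl_transitions == 0.0  # no transitions in a 2-frame window

    def test_batch_order_invariance(self, rng):
        gen, post, prior = _toy_models(L=4)
        windows = rng.standard_normal((6, 4, 4))
        loss_a, _, _ = elbo_objective(windows, gen, post, prior, seed=0,
                                      sample_noise=False)
        loss_b, _, _ = elbo_objective(windows[::-1].copy(), gen, post, prior,
                                      seed=0, sample_noise=False)
        assert float(loss_a.data) == pytest.approx(float(loss_b.data),
                                                   abs=1e-10)

    def test_kl_terms_nonnegative_under_random_models(self, rng):
        cfg = TransformerConfig(n_layers=1, embed_dim=8, max_len=6)
        for seed in range(5):
            r = np.random.default_rng(seed)
            gen = GenerativeModel(GenerativeConfig((8,), (8,)), r)
            post = GPT2Posterior(cfg, r)
            prior = PCAPrior()
            prior.fit(r.standard_normal((50, 4)))
            _, bd, _ = elbo_objective(r.standard_normal((2, 6, 4)), gen,
                                      post, prior, seed=seed)
            assert bd.kl_initial >= 0.0
            assert bd.kl_transitions >= -1e-12

    def test_mc_averaging_reduces_estimator_variance(self, rng):
        gen, post, prior = _toy_models(L=4)
        # non-degenerate decoder so the sampled z matters
        gen.decoder_net.layers[-1].w.data[:] = \
            rng.standard_normal((4, 4)) * 0.5
        window = rng.standard_normal((1, 4, 4))

        def estimates(mc, n=60):
            return [float(elbo_objective(window, gen, post, prior,
                                         seed=1000 + i,
                                         mc_samples=mc)[0].data)
                    for i in range(n)]

        v1 = np.var(estimates(1))
        v4 = np.var(estimates(4))
        assert np.isfinite(v1) and v1 > 0
        assert v4 < v1  # ~ 1/mc shrinkage


class TestContrastLoss:
    def _zero_net(self):
        net = ContrastNet(np.random.default_rng(0), hidden=(8,))
        net.net.layers[-1].w.data[:] = 0.0
        net.net.layers[-1].b.data[:] = 0.0
        return net

    def test_zero_scorer_gives_2_log2(self, rng):
        net = self._zero_net()
        xs = [rng.standard_normal((7, 4)) for _ in range(2)]
        zs = [rng.standard_normal((7, 2)) for _ in range(2)]
        loss = contrast_loss(xs, zs, net)
        assert float(loss.data) == pytest.approx(2 * np.log(2.0), abs=1e-12)

    def test_perfect_discriminator_limit(self):
        # user 0 lives at x0 = +1, z0 = +1; user 1 at x0 = -1, z0 = -1.
        # an oracle scorer agreeing on matched signs saturates the loss to 0
        xs = [np.ones((5, 4)), -np.ones((5, 4))]
        zs = [np.ones((5, 2)), -np.ones((5, 2))]

        class Ideal:
            def logits(self, x, z):
                xd = x.data if isinstance(x, Tensor) else np.asarray(x)
                zd = z.data if isinstance(z, Tensor) else np.asarray(z)
                match = np.sign(xd[..., 0]) == np.sign(zd[..., 0])
                return Tensor(np.where(match, 60.0, -60.0))

        loss = contrast_loss(xs, zs, Ideal())
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_relabeling(self, rng):
        net = ContrastNet(rng, hidden=(8,))
        xs = [rng.standard_normal((6, 4)) for _ in range(3)]
        zs = [rng.standard_normal((6, 2)) for _ in range(3)]
        a = float(contrast_loss(xs, zs, net).data)
        order = [2, 0, 1]
        b = float(contrast_loss([xs[i] for i in order],
                                [zs[i] for i in order], net).data)
        assert a == pytest.approx(b, abs=1e-10)

    def test_single_user_rejected(self, rng):
        net = ContrastNet(rng)
        with pytest.raises(InvalidArgumentError):
            contrast_loss([rng.standard_normal((5, 4))],
                          [rng.standard_normal((5, 2))], net)

    def test_literal_form_differs(self, rng):
        net = ContrastNet(rng, hidden=(8,))
        xs = [rng.standard_normal((5, 4)) for _ in range(2)]
        zs = [rng.standard_normal((5, 2)) for _ in range(2)]
        a = float(contrast_loss(xs, zs, net, literal_form=False).data)
        b = float(contrast_loss(xs, zs, net, literal_form=True).data)
        assert a != pytest.approx(b)


class TestTrainLoop:
    @pytest.fixture()
    def smoke_model(self, tiny_model_config, walking_recording):
        return MotionSDE.from_recordings([walking_recording], T=30,
                                         config=tiny_model_config)

    def test_loss_decreases_and_validation_recorded(self, smoke_model):
        res = smoke_model.fit(g.TrainConfig(n_epochs=50, seed=0))
        assert res.history.train_loss[-1] < res.history.train_loss[0]
        assert len(res.history.val_loss) == 50

    def test_seed_reproducibility(self, smoke_model):
        h1 = smoke_model.fit(g.TrainConfig(n_epochs=5, seed=0)).history
        h2 = smoke_model.fit(g.TrainConfig(n_epochs=5, seed=0)).history
        h3 = smoke_model.fit(g.TrainConfig(n_epochs=5, seed=1)).history
        assert h1.train_loss == h2.train_loss
        assert h1.train_loss != h3.train_loss

    def test_disabled_contrast_leaves_omega_untouched(
            self, tiny_model_config, two_subject_recordings):
        model = MotionSDE.from_recordings(two_subject_recordings, T=30,
                                          config=tiny_model_config)
        res = model.fit(g.TrainConfig(n_epochs=3, seed=0,
                                      contrast_weight=0.0))
        # replay the construction seed stream => identical init; training
        # must not have changed the contrast weights
        rng = np.random.default_rng(0)
        from gyrosde.generative import GenerativeModel
        from gyrosde.inference import GPT2Posterior
        GenerativeModel(tiny_model_config.generative, rng)
        GPT2Posterior(tiny_model_config.transformer, rng)
        ref = ContrastNet(rng, hidden=tiny_model_config.contrast_hidden)
        for got, want in zip(res.contrast.state_arrays(),
                             ref.state_arrays()):
            np.testing.assert_array_equal(got, want)

    def test_contrast_training_moves_omega(self, tiny_model_config,
                                           two_subject_recordings):
        model = MotionSDE.from_recordings(two_subject_recordings, T=30,
                                          config=tiny_model_config)
        res = model.fit(g.TrainConfig(n_epochs=3, seed=0,
                                      contrast_weight=10.0))
        rng = np.random.default_rng(0)
        from gyrosde.generative import GenerativeModel
        from gyrosde.inference import GPT2Posterior
        GenerativeModel(tiny_model_config.generative, rng)
        GPT2Posterior(tiny_model_config.transformer, rng)
        ref = ContrastNet(rng, hidden=tiny_model_config.contrast_hidden)
        moved = any(not np.array_equal(a, b)
                    for a, b in zip(res.contrast.state_arrays(),
                                    ref.state_arrays()))
        assert moved


class TestOverfittingDetector:
    def test_fires_on_u_shaped_trace(self):
        trace = list(np.linspace(5.0, 1.0, 30)) + \
            list(np.linspace(1.05, 2.5, 15))
        fired, best = detect_overfitting(trace, patience=10)
        assert fired and best == 29

    def test_silent_on_monotone_decrease(self):
        fired, _ = detect_overfitting(np.linspace(5.0, 1.0, 50), patience=10)
        assert not fired

    def test_silent_on_short_plateau(self):
        trace = list(np.linspace(5.0, 1.0, 30)) + [1.01] * 3
        fired, _ = detect_overfitting(trace, patience=10)
        assert not fired

    def test_bad_patience_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_overfitting([1.0], patience=0)
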