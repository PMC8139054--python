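"""WGAN-GP losses, InfoGAN MI bound, projection discriminator, training."""

import numpy as np
import pytest

from michigan import _autodiff as ad
from michigan._autodiff import Tensor, grad
from michigan._nn import Dense
from michigan.gan import (GANConfig, InfoWGANGP, PCWGANGP, WGANGP,
                          info_mi_lower_bound, projection_disc_score,
                          wgan_gp_disc_loss, wgan_gp_gen_loss)

_LOG2PI = np.log(2.0 * np.pi)


@pytest.fixture()
def f64():
    with ad.use_dtype(np.float64):
        yield


class TestGradientPenalty:
    def test_unit_norm_linear_critic_has_zero_penalty(self, rng, f64):
        w = rng.normal(size=(6, 1))
        w /= np.linalg.norm(w)
        critic = lambda x: x @ Tensor(w)
        real = rng.normal(size=(8, 6))
        fake = rng.normal(size=(8, 6))
        _, penalty = wgan_gp_disc_loss(real, fake, critic, 10.0,
                                       np.random.default_rng(0))
        assert penalty.item() == pytest.approx(0.0, abs=1e-10)

    def test_double_norm_linear_critic_penalty_is_one(self, rng, f64):
        w = rng.normal(size=(6, 1))
        w /= np.linalg.norm(w)
        critic = lambda x: x @ Tensor(2.0 * w)   # gradient norm 2 everywhere
        real = rng.normal(size=(8, 6))
        fake = rng.normal(size=(8, 6))
        loss, penalty = wgan_gp_disc_loss(real, fake, critic, 10.0,
                                          np.random.default_rng(0))
        assert penalty.item() == pytest.approx(1.0, abs=1e-10)  # (2-1)^2
        # loss includes lambda * penalty
        wasser = (critic(Tensor(fake)).mean()
                  - critic(Tensor(real)).mean()).item()
        assert loss.item() == pytest.approx(wasser + 10.0, abs=1e-8)

    def test_penalty_matches_finite_difference_gradient_norm(self, f64):
        """Penalty value equals the finite-difference computation of the
        critic's input-gradient norm within 1e-4 relative error."""
        rng = np.random.default_rng(8)
        net_rng = np.random.default_rng(9)
        layers = [Dense(5, 8, net_rng), Dense(8, 1, net_rng)]

        def critic(x):
            return layers[1](layers[0](x).tanh())

        real = rng.normal(size=(6, 5))
        fake = rng.normal(size=(6, 5))
        mix_rng = np.random.default_rng(3)
        eps = mix_rng.random((6, 1))
        _, penalty = wgan_gp_disc_loss(real, fake, critic, 10.0,
                                       np.random.default_rng(3))
        interp = eps * real + (1 - eps) * fake
        h = 1e-6
        norms = []
        for i in range(6):
            g = np.zeros(5)
            for j in range(5):
                xp, xm = interp[i].copy(), interp[i].copy()
                xp[j] += h
                xm[j] -= h
                with ad.no_grad():
                    fp = critic(Tensor(xp[None])).item()
                    fm = critic(Tensor(xm[None])).item()
                g[j] = (fp - fm) / (2 * h)
            norms.append(np.linalg.norm(g))
        expected = np.mean((np.array(norms) - 1.0) ** 2)
        assert penalty.item() == pytest.approx(expected, rel=1e-4)


class TestGeneratorLoss:
    def test_equal_scores_give_minus_c(self):
        scores = Tensor(np.full((7, 1), 2.5))
        assert wgan_gp_gen_loss(scores).item() == pytest.approx(-2.5)

    def test_constant_critic_gives_zero_gradient(self, rng, f64):
        fake = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
        critic = lambda x: x @ Tensor(np.zeros((4, 1))) + 3.0
        loss = wgan_gp_gen_loss(critic(fake))
        g, = grad(loss, [fake])
        assert np.allclose(g.data, 0.0)

    def test_one_step_raises_scores_under_frozen_linear_critic(self, rng,
                                                               f64):
        w = rng.normal(size=(4, 1))
        critic = lambda x: x @ Tensor(w)
        fake = Tensor(rng.normal(size=(16, 4)), requires_grad=True)
        before = critic(fake).mean().item()
        g, = grad(wgan_gp_gen_loss(critic(fake)), [fake])
        stepped = Tensor(fake.data - 0.1 * g.data)
        assert critic(stepped).mean().item() > before


class TestInfoMIBound:
    def test_maximized_at_correct_mean(self, rng, f64):
        codes = rng.normal(size=(64, 3))
        best = info_mi_lower_bound(Tensor(codes), Tensor(codes)).item()
        for delta in (0.3, 1.0):
            worse = info_mi_lower_bound(
                Tensor(codes), Tensor(codes + delta)).item()
            assert worse < best
            # quadratic form: shifting all means by delta costs d
            # delta^2 / 2
            assert best - worse == pytest.approx(3 * delta**2 / 2, rel=1e-6)

    def test_uninformative_q_gives_zero_bound(self, f64):
        rng = np.random.default_rng(0)
        n = 100_000
        codes = rng.standard_normal((n, 2))
        q_mean = np.zeros((n, 2))  # Q ignores X
        val = info_mi_lower_bound(Tensor(codes), Tensor(q_mean)).item()
        # E[log Q] = -d/2 (log 2pi + 1) cancels H(C) exactly in expectation
        assert val == pytest.approx(0.0, abs=0.02)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            info_mi_lower_bound(Tensor(rng.normal(size=(4, 2))),
                                Tensor(rng.normal(size=(4, 3))))


class TestProjectionScore:
    def test_zero_projection_reduces_to_unconditional(self, rng, f64):
        net_rng = np.random.default_rng(1)
        psi = Dense(4, 1, net_rng)
        V = Dense(4, 3, net_rng)
        V.W.data[:] = 0.0
        V.b.data[:] = 0.0
        f = Tensor(rng.normal(size=(6, 4)))
        code = Tensor(rng.normal(size=(6, 3)))
        s = projection_disc_score(f, code, psi, V)
        assert np.allclose(s.data, psi(f).data)

    def test_zero_code_is_independent_of_projection(self, rng, f64):
        net_rng = np.random.default_rng(2)
        psi = Dense(4, 1, net_rng)
        f = Tensor(rng.normal(size=(6, 4)))
        code = Tensor(np.zeros((6, 3)))
        s1 = projection_disc_score(f, code, psi, Dense(4, 3, net_rng))
        s2 = projection_disc_score(f, code, psi, Dense(4, 3, net_rng))
        assert np.allclose(s1.data, s2.data)


class TestTraining:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GANConfig(gp_lambda=0.0)
        with pytest.raises(ValueError):
            GANConfig(disc_steps_per_gen=0)
        with pytest.raises(ValueError):
            WGANGP(np.zeros((10, 4)), GANConfig(noise_dim=2, code_dim=3))
        with pytest.raises(ValueError):
            PCWGANGP(np.zeros((10, 4)), codes=None)

    def test_seeded_first_steps_replicate(self, small_linear_dataset):
        cfg = GANConfig(noise_dim=4, code_dim=0, epochs=2, batch_size=64,
                        seed=5, gen_hidden=[16, 32, 32],
                        disc_hidden=[32, 16, 8])
        a = WGANGP(small_linear_dataset, cfg).fit()
        b = WGANGP(small_linear_dataset, cfg).fit()
        assert a.disc_loss_history == b.disc_loss_history
        assert a.gen_loss_history == b.gen_loss_history

    def test_generation_is_deterministic_given_seed(self,
                                                    small_linear_dataset):
        cfg = GANConfig(noise_dim=4, code_dim=0, epochs=1, batch_size=64,
                        seed=5, gen_hidden=[16, 32, 32],
                        disc_hidden=[32, 16, 8])
        res = WGANGP(small_linear_dataset, cfg).fit()
        x1, z1 = res.generate(n=20, seed=3)
        x2, z2 = res.generate(n=20, seed=3)
        assert np.array_equal(x1, x2)
        assert np.array_equal(z1, z2)

    def test_infowgan_trains_with_q_head(self, small_linear_dataset):
        cfg = GANConfig(noise_dim=3, code_dim=3, epochs=1, batch_size=64,
                        seed=1, gen_hidden=[16, 32, 32],
                        disc_hidden=[32, 16, 8])
        res = InfoWGANGP(small_linear_dataset, cfg).fit()
        assert res.critic.q is not None
        x, c = res.generate(n=10, seed=0)
        assert x.shape == (10, small_linear_dataset.n_genes)
        assert c.shape == (10, 3)

    def test_conditional_fidelity_on_visible_coordinate(self):
        """After conditional training on toy data whose first coordinate
        equals the 1-D code, regressing that coordinate of generated
        samples on the code gives slope in [0.8, 1.2]."""
        rng = np.random.default_rng(0)
        n = 512
        code = rng.standard_normal((n, 1))
        X = np.concatenate([code, 0.3 * rng.standard_normal((n, 3))],
                           axis=1)
        cfg = GANConfig(noise_dim=4, epochs=120, batch_size=128, seed=0,
                        lr=5e-4, gen_hidden=[32, 64, 64],
                        disc_hidden=[64, 32, 8], dropout=0.0)
        res = PCWGANGP(X, code, cfg).fit()
        grid = np.linspace(-2, 2, 200)[:, None]
        gen = res.generate(codes=grid, seed=1)
        slope = np.polyfit(grid[:, 0], gen[:, 0], 1)[0]
        assert 0.8 <= slope <= 1.2
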