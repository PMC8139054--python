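"""Wasserstein GAN engines with gradient penalty.

Four modes share one training loop:

* ``wgan_gp`` -- unconditional WGAN-GP.
* ``infowgan_gp`` -- adds an auxiliary head Q predicting the latent code
  from generated data and maximizes the variational mutual-information
  lower bound L_MI(G, Q) = E[log Q(C|X)] + H(C) (Q factorized normal with
  unit variance, which stabilizes training).
* ``ss_infowgan_gp`` -- InfoWGAN-GP plus a supervised term tying Q's
  prediction on *real* cells to their known codes.
* ``pcwgan_gp`` -- conditional WGAN-GP with a projection discriminator:
  the critic score is psi(phi(x)) + c^T V phi(x), the inner-product
  conditioning suited to unimodal continuous codes such as VAE posteriors.

Sign conventions (minimization objectives):
    critic loss     E[D(fake)] - E[D(real)] + lambda E[(||grad D||_2 - 1)^2]
    generator loss  -E[D(fake)]

The gradient penalty is evaluated at per-sample random interpolates
X~ = eps X + (1 - eps) G(Z); in conditional mode the real sample's code is
reused for its interpolate (the penalty acts on the data argument only).
The critic is a plain MLP -- no batch normalization, which would couple
samples and invalidate the per-sample penalty; the generator uses batch
normalization and dropout as usual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, grad, no_grad
from ._nn import Adam, Dense, LeakyReLU, Sequential, mlp
from .data import ExpressionDataset

__all__ = [
    "GANConfig",
    "WGANGP",
    "InfoWGANGP",
    "PCWGANGP",
    "GANResults",
    "wgan_gp_disc_loss",
    "wgan_gp_gen_loss",
    "info_mi_lower_bound",
    "projection_disc_score",
    "train_gan",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GANConfig:
    """Hyperparameters of the GAN family.

    ``noise_dim`` defaults to 118 when conditioning on 10-dimensional codes
    (codes + noise = 128 generator inputs); unconditional models typically
    use 10 or 128.
    """

    noise_dim: int = 118
    code_dim: int = 0
    gen_hidden: list = field(default_factory=lambda: [256, 512, 1024])
    disc_hidden: list = field(default_factory=lambda: [1024, 512, 10])
    gp_lambda: float = 10.0
    disc_steps_per_gen: int = 5
    epochs: int = 200
    batch_size: int = 128
    lr: float = 1e-4
    adam_betas: tuple = (0.5, 0.9)
    dropout: float = 0.2
    mi_lambda: float = 1.0
    sup_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gp_lambda <= 0:
            raise ValueError("gp_lambda must be > 0")
        if self.disc_steps_per_gen < 1:
            raise ValueError("disc_steps_per_gen must be >= 1")
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")


# ---------------------------------------------------------------------------
# loss pieces
# ---------------------------------------------------------------------------

def _grad_norm(critic_fn, x: Tensor) -> Tensor:
    """Per-sample L2 norm of d critic / d x, kept differentiable."""
    score = critic_fn(x).sum()
    gx, = grad(score, [x], create_graph=True)
    return ((gx * gx).sum(axis=1) + 1e-12) ** 0.5


def wgan_gp_disc_loss(real, fake, critic_fn, gp_lambda: float,
                      mix_rng: np.random.Generator):
    """WGAN-GP critic objective (to be minimized).

    ``critic_fn`` maps a Tensor batch to per-sample scores; ``fake`` is
    treated as constant (already detached). Returns (loss, penalty).
    """
    real_t = real if isinstance(real, Tensor) else Tensor(real)
    fake_t = Tensor(fake.data if isinstance(fake, Tensor) else fake)
    eps = mix_rng.random((real_t.shape[0], 1))
    interp = Tensor(eps * real_t.data + (1.0 - eps) * fake_t.data,
                    requires_grad=True)
    gnorm = _grad_norm(critic_fn, interp)
    penalty = ((gnorm - 1.0) ** 2.0).mean()
    loss = (critic_fn(fake_t).mean() - critic_fn(real_t).mean()
            + gp_lambda * penalty)
    return loss, penalty


def wgan_gp_gen_loss(fake_scores: Tensor) -> Tensor:
    """Generator objective: minimizing it raises critic scores of fakes
    (loss = -mean score; all-equal scores c give loss -c)."""
    return -fake_scores.mean()


def info_mi_lower_bound(codes: Tensor, q_mean: Tensor,
                        code_entropy: float | None = None) -> Tensor:
    """Variational lower bound on I(C; X): E[log Q(C|X)] + H(C).

    Q is factorized normal with unit variance, so
    log Q(c|x) = -1/2 ||c - q_mean||^2 - d/2 log(2 pi).  For the standard
    normal code prior H(C) = d/2 log(2 pi e).
    """
    codes_t = codes if isinstance(codes, Tensor) else Tensor(codes)
    if codes_t.shape != q_mean.shape:
        raise ValueError("code and prediction dimensions differ")
    d = codes_t.shape[1]
    if code_entropy is None:
        code_entropy = 0.5 * d * (_LOG2PI + 1.0)  # H of N(0, I_d)
    logq = (-0.5 * ((codes_t - q_mean) ** 2.0).sum(axis=1)
            - 0.5 * d * _LOG2PI).mean()
    return logq + code_entropy


def projection_disc_score(features: Tensor, code: Tensor, psi: Dense,
                          V: Dense) -> Tensor:
    """Projection-discriminator score psi(phi(x)) + c^T V phi(x)."""
    base = psi(features)
    proj = (code * V(features)).sum(axis=1, keepdims=True)
    return base + proj


# ---------------------------------------------------------------------------
# critics / generators
# ---------------------------------------------------------------------------

class _Critic:
    """MLP trunk -> feature; scalar head; optional Q / projection heads."""

    def __init__(self, n_genes, cfg: GANConfig, rng, q_head=False,
                 projection=False):
        hidden = list(cfg.disc_hidden)
        feat = hidden[-1]
        layers = []
        prev = n_genes
        for h in hidden:
            layers += [Dense(prev, h, rng), LeakyReLU(0.2)]
            prev = h
        self.trunk = Sequential(*layers)
        self.psi = Dense(feat, 1, rng)
        self.q = Dense(feat, cfg.code_dim, rng) if q_head else None
        self.V = Dense(feat, cfg.code_dim, rng) if projection else None
        if self.V is not None:
            self.V.b.requires_grad = False  # pure linear projection

    def features(self, x: Tensor) -> Tensor:
        return self.trunk(x)

    def score(self, x: Tensor, code: Tensor | None = None) -> Tensor:
        f = self.features(x)
        if self.V is not None and code is not None:
            return projection_disc_score(f, code, self.psi, self.V)
        return self.psi(f)

    def q_mean(self, x: Tensor) -> Tensor:
        return self.q(self.features(x))

    def parameters(self):
        ps = self.trunk.parameters() + self.psi.parameters()
        if self.q is not None:
            ps += self.q.parameters()
        if self.V is not None:
            ps += [self.V.W]
        return ps

    def state_arrays(self):
        out = self.trunk.state_arrays() + self.psi.state_arrays()
        if self.q is not None:
            out += self.q.state_arrays()
        if self.V is not None:
            out += [self.V.W.data]
        return out

    def load_state_arrays(self, arrays):
        pos = len(self.trunk.state_arrays())
        self.trunk.load_state_arrays(arrays[:pos])
        self.psi.load_state_arrays(arrays[pos:pos + 2])
        pos += 2
        if self.q is not None:
            self.q.load_state_arrays(arrays[pos:pos + 2])
            pos += 2
        if self.V is not None:
            self.V.W.data = np.asarray(arrays[pos],
                                       dtype=self.V.W.data.dtype)


class _Generator:
    def __init__(self, n_in, n_genes, cfg: GANConfig, rng):
        self.net = mlp(n_in, list(cfg.gen_hidden), n_genes, rng,
                       batchnorm=True, dropout=cfg.dropout)

    def __call__(self, z: Tensor, rng=None) -> Tensor:
        return self.net(z, rng)

    def train(self, mode=True):
        self.net.train(mode)
        return self

    def parameters(self):
        return self.net.parameters()

    def state_arrays(self):
        return self.net.state_arrays()

    def load_state_arrays(self, arrays):
        self.net.load_state_arrays(arrays)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _GANBase:
    mode = "wgan_gp"

    def __init__(self, data, config: GANConfig | None = None,
                 codes: np.ndarray | None = None,
                 labels: np.ndarray | None = None):
        self.X = data.X if isinstance(data, ExpressionDataset) else \
            np.asarray(data, dtype=np.float64)
        self.config = config or GANConfig()
        self.codes = None if codes is None else np.asarray(codes, float)
        self.labels = labels
        if self.mode == "pcwgan_gp":
            if self.codes is None:
                raise ValueError("pcwgan_gp requires per-cell codes")
            if self.codes.shape[0] != self.X.shape[0]:
                raise ValueError("codes and data row counts differ")
            if self.config.code_dim == 0:
                self.config.code_dim = self.codes.shape[1]
            elif self.config.code_dim != self.codes.shape[1]:
                raise ValueError("code_dim does not match codes")

    def _make_nets(self, rng):
        cfg = self.config
        q_head = self.mode in ("infowgan_gp", "ss_infowgan_gp")
        projection = self.mode == "pcwgan_gp"
        gen_in = cfg.noise_dim + cfg.code_dim
        self.generator = _Generator(gen_in, self.X.shape[1], cfg, rng)
        self.critic = _Critic(self.X.shape[1], cfg, rng, q_head=q_head,
                              projection=projection)

    def _sample_gen_input(self, n, rng, codes=None):
        cfg = self.config
        noise = rng.standard_normal((n, cfg.noise_dim))
        if cfg.code_dim == 0:
            return noise, None
        if codes is None:
            codes = rng.standard_normal((n, cfg.code_dim))
        return np.concatenate([codes, noise], axis=1), codes

    def fit(self, verbose: bool = False) -> "GANResults":
        cfg = self.config
        X = self.X
        n = X.shape[0]
        init_rng = np.random.default_rng(np.random.SeedSequence(
            [int(cfg.seed), 10]))
        run_rng = np.random.default_rng(np.random.SeedSequence(
            [int(cfg.seed), 11]))
        self._make_nets(init_rng)
        gen, critic = self.generator, self.critic

        opt_d = Adam(critic.parameters(), lr=cfg.lr, betas=cfg.adam_betas)
        opt_g = Adam(gen.parameters() + self._q_params(), lr=cfg.lr,
                     betas=cfg.adam_betas)
        batch = min(cfg.batch_size, n)
        iters_per_epoch = max(n // batch, 1)
        d_losses, g_losses = [], []
        conditional = self.mode == "pcwgan_gp"

        for epoch in range(cfg.epochs):
            d_epoch = g_epoch = 0.0
            for _ in range(iters_per_epoch):
                # critic updates
                for _ in range(cfg.disc_steps_per_gen):
                    idx = run_rng.integers(n, size=batch)
                    real = X[idx]
                    real_codes = self.codes[idx] if conditional else None
                    gin, gcodes = self._sample_gen_input(
                        batch, run_rng, codes=real_codes)
                    with no_grad():
                        fake = gen(Tensor(gin), run_rng).data
                    if conditional:
                        code_t = Tensor(real_codes)
                        critic_fn = lambda x: critic.score(x, code_t)
                    else:
                        critic_fn = critic.score
                    d_loss, _ = wgan_gp_disc_loss(
                        real, fake, critic_fn, cfg.gp_lambda, run_rng)
                    gs = grad(d_loss, critic.parameters())
                    opt_d.step(gs)
                    d_epoch += d_loss.item()
                # generator update
                idx = run_rng.integers(n, size=batch)
                real_codes = self.codes[idx] if conditional else None
                gin, gcodes = self._sample_gen_input(batch, run_rng,
                                                     codes=real_codes)
                fake = gen(Tensor(gin), run_rng)
                if conditional:
                    scores = critic.score(fake, Tensor(real_codes))
                else:
                    scores = critic.score(fake)
                g_loss = wgan_gp_gen_loss(scores)
                g_loss = self._augment_gen_loss(g_loss, fake, gcodes,
                                                X, run_rng)
                gs = grad(g_loss, opt_g.params)
                opt_g.step(gs)
                g_epoch += g_loss.item()
            d_losses.append(d_epoch / (iters_per_epoch *
                                       cfg.disc_steps_per_gen))
            g_losses.append(g_epoch / iters_per_epoch)
            if not np.isfinite(d_losses[-1]) or abs(d_losses[-1]) > 1e6:
                warnings.warn(f"critic loss diverged at epoch {epoch}; "
                              "halting with current parameters")
                break
            if verbose and epoch % 20 == 0:
                print(f"epoch {epoch:4d}  D {d_losses[-1]:+.3f}  "
                      f"G {g_losses[-1]:+.3f}")
        gen.train(False)
        return GANResults(self.mode, gen, critic, self.config,
                          d_losses, g_losses, codes=self.codes)

    # Q-head plumbing (InfoGAN variants share the generator optimizer)
    def _q_params(self):
        return []

    def _augment_gen_loss(self, g_loss, fake, gcodes, X, rng):
        return g_loss


class WGANGP(_GANBase):
    """Unconditional Wasserstein GAN with gradient penalty."""

    mode = "wgan_gp"

    def __init__(self, data, config: GANConfig | None = None):
        config = config or GANConfig(noise_dim=10, code_dim=0)
        if config.code_dim != 0:
            raise ValueError("unconditional WGAN-GP takes code_dim=0")
        super().__init__(data, config)


class InfoWGANGP(_GANBase):
    """InfoWGAN-GP; set ``semi_supervised=True`` (with per-cell labels/codes)
    for the ssInfoGAN variant."""

    mode = "infowgan_gp"

    def __init__(self, data, config: GANConfig | None = None,
                 labels: np.ndarray | None = None,
                 semi_supervised: bool = False):
        config = config or GANConfig(noise_dim=10, code_dim=10)
        if config.code_dim < 1:
            raise ValueError("InfoWGAN-GP needs code_dim >= 1")
        if semi_supervised:
            if labels is None:
                raise ValueError("semi-supervised variant needs labels")
            self.mode = "ss_infowgan_gp"
        super().__init__(data, config, labels=labels)
        self._sup = semi_supervised
        if labels is not None:
            self._label_arr = np.asarray(labels, dtype=float)
            if self._label_arr.ndim == 1:
                self._label_arr = self._label_arr[:, None]

    def _q_params(self):
        return self.critic.q.parameters()

    def _augment_gen_loss(self, g_loss, fake, gcodes, X, rng):
        cfg = self.config
        q_pred = self.critic.q_mean(fake)
        mi = info_mi_lower_bound(Tensor(gcodes), q_pred)
        g_loss = g_loss - cfg.mi_lambda * mi
        if self._sup:
            idx = rng.integers(X.shape[0], size=fake.shape[0])
            q_real = self.critic.q_mean(Tensor(X[idx]))
            k = min(q_real.shape[1], self._label_arr.shape[1])
            sup = ((Tensor(self._label_arr[idx][:, :k])
                    - q_real[:, :k]) ** 2.0).sum(axis=1).mean()
            g_loss = g_loss + cfg.sup_lambda * sup
        return g_loss


class PCWGANGP(_GANBase):
    """Conditional WGAN-GP with projection discriminator (PCWGAN-GP)."""

    mode = "pcwgan_gp"

    def __init__(self, data, codes, config: GANConfig | None = None):
        config = config or GANConfig(noise_dim=118)
        super().__init__(data, config, codes=codes)


def train_gan(data, config: GANConfig, mode: str = "wgan_gp",
              codes=None, labels=None, verbose: bool = False) -> "GANResults":
    """Functional entry point over the model classes."""
    if mode == "wgan_gp":
        model = WGANGP(data, config)
    elif mode == "infowgan_gp":
        model = InfoWGANGP(data, config, labels=labels)
    elif mode == "ss_infowgan_gp":
        model = InfoWGANGP(data, config, labels=labels, semi_supervised=True)
    elif mode == "pcwgan_gp":
        model = PCWGANGP(data, codes, config)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return model.fit(verbose=verbose)


class GANResults:
    """Trained generator (+critic) with seeded sampling."""

    def __init__(self, mode, generator, critic, config, d_losses, g_losses,
                 codes=None):
        self.mode = mode
        self.generator = generator
        self.critic = critic
        self.config = config
        self.disc_loss_history = d_losses
        self.gen_loss_history = g_losses
        self.training_codes = codes

    def generate(self, n: int | None = None, seed: int = 0,
                 codes: np.ndarray | None = None, batch: int = 4096):
        """Generate expression profiles.

        Unconditional: returns (X_gen, noise) for ``n`` cells.
        Conditional: pass ``codes`` (n x code_dim); returns X_gen.
        Deterministic given (codes, seed).
        """
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
        conditional = self.mode == "pcwgan_gp"
        if conditional:
            if codes is None:
                raise ValueError("conditional generator needs codes")
            codes = np.asarray(codes, float)
            if codes.shape[1] != cfg.code_dim:
                raise ValueError("code dimension mismatch")
            n = codes.shape[0]
            noise = rng.standard_normal((n, cfg.noise_dim))
            gin = np.concatenate([codes, noise], axis=1)
        else:
            if n is None:
                raise ValueError("pass n for unconditional generation")
            noise = rng.standard_normal((n, cfg.noise_dim))
            gin = noise
            if cfg.code_dim:  # InfoGAN: prepend code draws
                codes = rng.standard_normal((n, cfg.code_dim))
                gin = np.concatenate([codes, noise], axis=1)
        out = []
        with no_grad():
            for start in range(0, gin.shape[0], batch):
                out.append(self.generator(
                    Tensor(gin[start:start + batch])).data.astype(float))
        X = np.concatenate(out)
        if conditional:
            return X
        return X, (codes if cfg.code_dim else noise)

    def summary(self) -> str:
        cfg = self.config
        lines = [f"{self.mode} (noise_dim={cfg.noise_dim}, "
                 f"code_dim={cfg.code_dim}, gp_lambda={cfg.gp_lambda})",
                 f"  epochs trained : {len(self.disc_loss_history)}",
                 f"  final critic loss    : {self.disc_loss_history[-1]:+.4f}",
                 f"  final generator loss : {self.gen_loss_history[-1]:+.4f}"]
        return "\n".join(lines)
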