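"""Variational autoencoders: VAE, beta-VAE and beta-TCVAE.

The encoder is a diagonal-Gaussian amortized posterior q_phi(Z|X); the
decoder a factorized Gaussian with unit variance on the processed expression
values, so the reconstruction term of the (negative) ELBO is a squared
error.  Disentanglement pressure is added either on the whole KL term
(``penalty_mode="kl_total"``, the beta-VAE) or on the total correlation of
the aggregate posterior (``penalty_mode="total_correlation"``, the
beta-TCVAE), the latter estimated per minibatch by stratified importance
sampling since the aggregate posterior q_phi(Z) = E_X[q_phi(Z|X)] has no
closed form.

With ``beta = 0`` both modes reduce term-by-term to the plain VAE objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, grad, no_grad
from ._nn import Adam, Dense, mlp
from .data import ExpressionDataset, GaussianPosterior

__all__ = [
    "VAEConfig",
    "VAE",
    "VAEResults",
    "elbo_loss",
    "gaussian_kl",
    "tc_penalty_minibatch",
]

KL_TOTAL = "kl_total"
TOTAL_CORRELATION = "total_correlation"

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VAEConfig:
    """Hyperparameters of the VAE family.

    Two hidden layers per network (deeper encoders destabilize training on
    expression data); batch normalization, leaky-ReLU and dropout 0.2 on
    every hidden layer.
    """

    latent_dim: int = 10
    beta: float = 0.0
    penalty_mode: str = TOTAL_CORRELATION
    hidden_sizes_enc: list = field(default_factory=lambda: [512, 256])
    hidden_sizes_dec: list = field(default_factory=lambda: [256, 512])
    dropout: float = 0.2
    epochs: int = 1000
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.penalty_mode not in (KL_TOTAL, TOTAL_CORRELATION):
            raise ValueError(f"unknown penalty_mode {self.penalty_mode!r}")
        if len(self.hidden_sizes_enc) != 2 or len(self.hidden_sizes_dec) != 2:
            raise ValueError("exactly two hidden layers per network")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs, batch_size must be >= 1")


# ---------------------------------------------------------------------------
# loss pieces (exposed for testing and reuse)
# ---------------------------------------------------------------------------

def gaussian_kl(mean: Tensor, logvar: Tensor) -> Tensor:
    """Mean over the batch of KL{ N(mean, exp(logvar)) || N(0, I) }.

    Closed form per cell: 1/2 sum_j (mu_j^2 + sigma_j^2 - log sigma_j^2 - 1).
    """
    kl = 0.5 * (mean * mean + logvar.exp() - logvar - 1.0).sum(axis=1)
    return kl.mean()


def elbo_loss(x: Tensor, recon_mean: Tensor, post_mean: Tensor,
              post_logvar: Tensor) -> Tensor:
    """Negative ELBO (per-cell average) for a unit-variance Gaussian decoder.

    reconstruction NLL  = 1/2 ||x - recon||^2   (additive constant dropped)
    + KL{ q_phi(Z|X) || N(0, I) }.
    """
    nll = (0.5 * (x - recon_mean) ** 2.0).sum(axis=1).mean()
    return nll + gaussian_kl(post_mean, post_logvar)


def _logsumexp(t: Tensor, axis: int) -> Tensor:
    m = Tensor(np.max(t.data, axis=axis, keepdims=True))
    out = (t - m).exp().sum(axis=axis).log()
    return out + Tensor(np.squeeze(m.data, axis=axis))


def tc_penalty_minibatch(post_mean: Tensor, post_logvar: Tensor,
                         z: Tensor, dataset_size: int) -> Tensor:
    """Minibatch stratified-sampling estimate of the total correlation
    KL[ q_phi(Z) || prod_j q_phi(Z_j) ].

    Each z_i is a sample from q(z|x_i); the aggregate density
    q(z_i) = (1/N) sum_k q(z_i|x_k) is estimated from the minibatch with
    stratified importance weights -- the own component gets weight 1/N, the
    other M-1 batch components stand in for the remaining N-1 cells with
    weight (N-1)/(N (M-1)) each -- applied jointly and per dimension before
    the log-sum-exp (N = dataset size, M = batch size).
    """
    M, d = z.shape
    if dataset_size < M:
        raise ValueError("dataset_size must be >= batch size")
    N = float(dataset_size)
    # mat[i, k, j] = log q(z_i^(j) | x_k)
    zi = z.reshape(M, 1, d)
    mu = post_mean.reshape(1, M, d)
    lv = post_logvar.reshape(1, M, d)
    prec = -0.5 * (-lv).exp()          # small (1, M, d) factors
    offs = -0.5 * (lv + _LOG2PI)
    mat = ((zi - mu) ** 2.0) * prec + offs
    if M == 1:
        logw = np.array([[-np.log(N)]])
    else:
        logw = np.full((M, M), np.log((N - 1.0) / (N * (M - 1.0))))
        np.fill_diagonal(logw, -np.log(N))
    logw_t = Tensor(logw)
    log_qz = _logsumexp(mat.sum(axis=2) + logw_t, axis=1)
    log_qz_marg = _logsumexp(mat + logw_t.reshape(M, M, 1), axis=1
                             ).sum(axis=1)
    return (log_qz - log_qz_marg).mean()


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class _Encoder:
    def __init__(self, n_genes, cfg: VAEConfig, rng):
        self.trunk = mlp(n_genes, list(cfg.hidden_sizes_enc),
                         cfg.hidden_sizes_enc[-1], rng,
                         batchnorm=True, dropout=cfg.dropout)
        # trunk's final Dense acts as a linear bridge; separate heads for
        # posterior mean and log-variance
        h = cfg.hidden_sizes_enc[-1]
        self.mean_head = Dense(h, cfg.latent_dim, rng)
        self.logvar_head = Dense(h, cfg.latent_dim, rng)

    def __call__(self, x: Tensor, rng=None):
        h = self.trunk(x, rng).leaky_relu(0.2)
        mean = self.mean_head(h)
        logvar = self.logvar_head(h).clip(-8.0, 8.0)
        return mean, logvar

    def train(self, mode=True):
        self.trunk.train(mode)
        return self

    def parameters(self):
        return (self.trunk.parameters() + self.mean_head.parameters()
                + self.logvar_head.parameters())

    def state_arrays(self):
        return (self.trunk.state_arrays() + self.mean_head.state_arrays()
                + self.logvar_head.state_arrays())

    def load_state_arrays(self, arrays):
        n1 = len(self.trunk.state_arrays())
        n2 = len(self.mean_head.state_arrays())
        self.trunk.load_state_arrays(arrays[:n1])
        self.mean_head.load_state_arrays(arrays[n1:n1 + n2])
        self.logvar_head.load_state_arrays(arrays[n1 + n2:])


class VAE:
    """VAE-family model bound to a dataset (fit() returns a VAEResults)."""

    def __init__(self, data, config: VAEConfig | None = None):
        self.X = data.X if isinstance(data, ExpressionDataset) else \
            np.asarray(data, dtype=np.float64)
        self.config = config or VAEConfig()

    def fit(self, verbose: bool = False) -> "VAEResults":
        cfg = self.config
        X = self.X
        n, g = X.shape
        init_rng = np.random.default_rng(np.random.SeedSequence(
            [int(cfg.seed), 0]))
        run_rng = np.random.default_rng(np.random.SeedSequence(
            [int(cfg.seed), 1]))

        encoder = _Encoder(g, cfg, init_rng)
        decoder = mlp(cfg.latent_dim, list(cfg.hidden_sizes_dec), g,
                      init_rng, batchnorm=True, dropout=cfg.dropout)
        params = encoder.parameters() + decoder.parameters()
        opt = Adam(params, lr=cfg.learning_rate)

        losses = []
        checkpoint = [p.data.copy() for p in params]
        batch = min(cfg.batch_size, n)
        for epoch in range(cfg.epochs):
            order = run_rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for start in range(0, n - batch + 1, batch):
                idx = order[start:start + batch]
                x = Tensor(X[idx])
                mean, logvar = encoder(x, run_rng)
                eps = Tensor(run_rng.standard_normal(mean.shape))
                z = mean + (0.5 * logvar).exp() * eps
                recon = decoder(z, run_rng)
                loss = elbo_loss(x, recon, mean, logvar)
                if cfg.beta > 0:
                    if cfg.penalty_mode == TOTAL_CORRELATION:
                        penalty = tc_penalty_minibatch(mean, logvar, z, n)
                    else:
                        penalty = gaussian_kl(mean, logvar)
                    loss = loss + cfg.beta * penalty
                if not np.isfinite(loss.data):
                    warnings.warn(
                        f"non-finite loss at epoch {epoch}; reverting to "
                        "last-good checkpoint and halting")
                    for p, c in zip(params, checkpoint):
                        p.data = c
                    return self._results(encoder, decoder, losses)
                gs = grad(loss, params)
                opt.step(gs)
                epoch_loss += loss.item()
                nb += 1
            losses.append(epoch_loss / max(nb, 1))
            checkpoint = [p.data.copy() for p in params]
            if verbose and (epoch % 50 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:4d}  loss {losses[-1]:.3f}")
            if (len(losses) > 50 and
                    losses[-1] > losses[-51] and epoch == cfg.epochs - 1):
                warnings.warn("training loss increased over the last 50 "
                              "epochs; model may not have converged")
        return self._results(encoder, decoder, losses)

    def _results(self, encoder, decoder, losses):
        encoder.train(False)
        decoder.train(False)
        return VAEResults(encoder, decoder, self.X, self.config,
                          list(losses))


class VAEResults:
    """Fitted VAE: frozen networks, per-cell posterior, loss history."""

    def __init__(self, encoder, decoder, X, config: VAEConfig, losses):
        self._encoder = encoder
        self._decoder = decoder
        self.config = config
        self.loss_history = losses
        self.posterior = self.encode(X)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def encode(self, X, batch: int = 4096) -> GaussianPosterior:
        X = X.X if isinstance(X, ExpressionDataset) else np.asarray(X)
        means, lvs = [], []
        with no_grad():
            for start in range(0, X.shape[0], batch):
                m, lv = self._encoder(Tensor(X[start:start + batch]))
                means.append(m.data)
                lvs.append(lv.data)
        mean = np.concatenate(means)
        var = np.exp(np.concatenate(lvs))
        return GaussianPosterior(mean, var)

    @property
    def codes(self) -> np.ndarray:
        """Posterior-mean codes of the training cells."""
        return self.posterior.mean

    def sample_codes(self, rng: np.random.Generator) -> np.ndarray:
        """Posterior samples z ~ q(z|x) for the training cells."""
        return self.posterior.sample(rng)

    def decode(self, Z, batch: int = 4096) -> np.ndarray:
        Z = np.asarray(Z, dtype=np.float64)
        out = []
        with no_grad():
            for start in range(0, Z.shape[0], batch):
                out.append(self._decoder(Tensor(Z[start:start + batch])).data)
        return np.concatenate(out)

    def generate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Decode draws from the aggregate posterior of the training cells."""
        idx = rng.integers(self.posterior.mean.shape[0], size=n)
        z = self.posterior.subset(idx).sample(rng)
        return self.decode(z)

    def log_density(self, z: np.ndarray, subset_idx=None) -> np.ndarray:
        """log of the aggregate-posterior mixture density at each row of z."""
        post = self.posterior if subset_idx is None else \
            self.posterior.subset(subset_idx)
        return _mixture_logpdf(z, post.mean, post.var)

    def summary(self) -> str:
        cfg = self.config
        name = {(KL_TOTAL): "beta-VAE", (TOTAL_CORRELATION): "beta-TCVAE"}[
            cfg.penalty_mode] if cfg.beta > 0 else "VAE"
        lines = [f"{name} (latent_dim={cfg.latent_dim}, beta={cfg.beta})",
                 f"  epochs trained : {len(self.loss_history)}",
                 f"  final -ELBO    : {self.loss_history[-1]:.4f}"
                 if self.loss_history else "  (no training run)"]
        return "\n".join(lines)


def _mixture_logpdf(z, means, varis):
    """log (1/n) sum_i N(z; mean_i, var_i) row-wise, log-sum-exp stabilized."""
    z = np.atleast_2d(z)
    out = np.empty(z.shape[0])
    n = means.shape[0]
    logdet = np.log(varis).sum(axis=1)
    for start in range(0, z.shape[0], 512):
        zz = z[start:start + 512]
        # (m, n) matrix of log component densities
        quad = (((zz[:, None, :] - means[None, :, :]) ** 2)
                / varis[None, :, :]).sum(axis=2)
        lp = -0.5 * (quad + logdet[None, :] + z.shape[1] * _LOG2PI)
        mx = lp.max(axis=1, keepdims=True)
        out[start:start + 512] = (
            np.log(np.exp(lp - mx).sum(axis=1)) + mx[:, 0] - np.log(n))
    return out
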