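"""Two-stage sampling from disentangled representations.

Stage 1 fits a disentangling representation (beta-TCVAE or probabilistic
PCA) and is then frozen.  Stage 2 trains a conditional Wasserstein GAN with
projection discriminator on (code, cell) pairs, where the codes are the
stage-1 posterior means or posterior samples.  After training, the GAN
generator acts as a high-quality decoder of the disentangled latent space:
generation, latent traversals and latent-arithmetic predictions all draw
codes from stage 1 and data from stage 2.
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionDataset
from .gan import GANConfig, PCWGANGP
from .ppca import PPCAResults, ProbabilisticPCA
from .vae import VAE, VAEConfig, VAEResults

__all__ = ["MichiGAN", "MichiGANResults"]

POSTERIOR_MEAN = "posterior_mean"
POSTERIOR_SAMPLE = "posterior_sample"


class MichiGAN:
    """Two-stage model: disentangling representation + conditional GAN.

    Parameters
    ----------
    data
        Processed :class:`ExpressionDataset` (or matrix).
    representation
        Either a configuration (:class:`VAEConfig` for the VAE family,
        ``"ppca"`` for probabilistic PCA) or an already fitted stage-1
        results object (:class:`VAEResults` / :class:`PPCAResults`), which
        is then reused as-is (stage 2 never updates stage-1 parameters).
    gan_config
        Stage-2 :class:`GANConfig`; ``code_dim`` is inferred from stage 1.
    code_mode
        ``"posterior_mean"`` or ``"posterior_sample"`` -- which codes
        condition the GAN. Sampled codes are the default for arithmetic
        workloads; means give slightly cleaner traversals.
    latent_dim
        Latent dimensionality when ``representation="ppca"``.
    """

    def __init__(self, data, representation="ppca",
                 gan_config: GANConfig | None = None,
                 code_mode: str = POSTERIOR_SAMPLE, latent_dim: int = 10,
                 seed: int = 0):
        if code_mode not in (POSTERIOR_MEAN, POSTERIOR_SAMPLE):
            raise ValueError(f"unknown code_mode {code_mode!r}")
        self.data = data
        self.representation = representation
        self.gan_config = gan_config
        self.code_mode = code_mode
        self.latent_dim = latent_dim
        self.seed = seed

    def fit(self, verbose: bool = False) -> "MichiGANResults":
        rep = self.representation
        if isinstance(rep, (VAEResults, PPCAResults)):
            stage1 = rep
        elif isinstance(rep, VAEConfig):
            stage1 = VAE(self.data, rep).fit(verbose=verbose)
        elif rep == "ppca":
            stage1 = ProbabilisticPCA(self.data, self.latent_dim).fit()
        elif rep in ("btcvae", "vae"):
            cfg = VAEConfig(latent_dim=self.latent_dim,
                            beta=10.0 if rep == "btcvae" else 0.0,
                            seed=self.seed)
            stage1 = VAE(self.data, cfg).fit(verbose=verbose)
        else:
            raise ValueError(f"unknown representation {rep!r}")

        d = stage1.latent_dim
        if self.code_mode == POSTERIOR_SAMPLE:
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(self.seed), 31]))
            codes = stage1.sample_codes(rng)
        else:
            codes = stage1.codes
        gcfg = self.gan_config or GANConfig(noise_dim=118, seed=self.seed)
        if gcfg.code_dim not in (0, d):
            raise ValueError(
                f"generator code_dim {gcfg.code_dim} != latent_dim {d}")
        gan = PCWGANGP(self.data, codes, gcfg).fit(verbose=verbose)
        return MichiGANResults(stage1, gan, codes, self.code_mode)


class MichiGANResults:
    """Fitted two-stage bundle."""

    def __init__(self, stage1, gan, codes, code_mode):
        self.stage1 = stage1
        self.gan = gan
        self.codes = np.asarray(codes)
        self.code_mode = code_mode

    @property
    def latent_dim(self) -> int:
        return self.codes.shape[1]

    def encode(self, X):
        """Stage-1 posterior-mean codes for new data."""
        if isinstance(self.stage1, PPCAResults):
            return self.stage1.transform(X)
        return self.stage1.encode(X).mean

    def generate(self, codes: np.ndarray | None = None,
                 seed: int = 0) -> np.ndarray:
        """Generate cells from latent codes (training codes by default)."""
        codes = self.codes if codes is None else np.asarray(codes, float)
        if codes.size and codes.shape[1] != self.latent_dim:
            raise ValueError("code dimension mismatch")
        if codes.shape[0] == 0:
            return np.empty((0, self.gan.generator.net
                             ._children[-1].W.shape[1]))
        return self.gan.generate(codes=codes, seed=seed)

    def latent_traversal(self, anchor: np.ndarray, dim: int,
                         grid: np.ndarray | None = None, n_points: int = 7,
                         seed: int = 0):
        """Vary one latent dimension of an anchor code over a grid.

        The default grid is ``n_points`` evenly spaced values between the
        1st and 99th percentile of that dimension over the training codes.
        Returns (grid, generated matrix with one row per grid value).
        """
        anchor = np.asarray(anchor, float).ravel()
        if not 0 <= dim < self.latent_dim:
            raise ValueError("dim out of range")
        if grid is None:
            lo, hi = np.percentile(self.codes[:, dim], [1, 99])
            grid = np.linspace(lo, hi, n_points)
        grid = np.asarray(grid, float)
        if grid.size == 0:
            raise ValueError("empty traversal grid")
        codes = np.tile(anchor, (grid.size, 1))
        codes[:, dim] = grid
        return grid, self.generate(codes, seed=seed)

    def summary(self) -> str:
        rep = ("probabilistic PCA" if isinstance(self.stage1, PPCAResults)
               else self.stage1.summary().splitlines()[0])
        return "\n".join([
            "MichiGAN two-stage model",
            f"  stage 1 : {rep}",
            f"  stage 2 : {self.gan.summary().splitlines()[0]}",
            f"  codes   : {self.code_mode} "
            f"({self.codes.shape[0]} x {self.codes.shape[1]})",
        ])
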