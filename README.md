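# michigan

Disentangled representation learning and high-fidelity conditional
generation for single-cell gene expression data.

## The problem

Deep generative models of scRNA-seq face a trade-off. Variational
autoencoders — especially variants that penalize statistical dependence
between latent dimensions — learn *disentangled* representations in which
individual dimensions track interpretable factors of cellular identity
(batch, differentiation stage, library size, treatment), but their
factorized Gaussian decoders generate blurry, unimodal expression
profiles. Wasserstein GANs generate profiles that classifiers struggle to
tell from real cells, but their latent space is entangled and
uninterpretable.

This package implements a two-stage composition that keeps both
properties:

1. **Stage 1 — disentangle.** Fit a beta-TCVAE (a VAE whose loss adds
   `beta * KL[q(Z) || prod_j q(Z_j)]`, the *total correlation* of the
   aggregate posterior, estimated per minibatch by stratified importance
   sampling) or closed-form probabilistic PCA.
2. **Stage 2 — generate.** Freeze stage 1 and train a conditional
   Wasserstein GAN with gradient penalty and a *projection discriminator*
   (critic score `psi(phi(x)) + c^T V phi(x)`) on (latent code, cell)
   pairs. The generator becomes a sharp decoder of the disentangled
   space: traversing one latent dimension changes one semantic attribute
   of the generated cells, and unseen (cell type, treatment) combinations
   can be predicted by latent vector arithmetic,
   `Zhat(C', D') = Z(C_k, D') + mean_s[Z(C', D_s) - Z(C_k, D_s)]`.

Alongside the models, the package ships the full evaluation suite
(normalized mutual information, MIG, the FactorVAE metric, Spearman
correlation gaps, random-forest real-vs-fake error, inception score), the
latent-entropy diagnostic `delta_H` that ranks combination predictions by
reliability, and a seeded simulator of factor-annotated scRNA-seq counts
(batch / path / step / library size, linear or non-linear differentiation;
branching trajectories) so every experiment is reproducible without
downloads. It is aimed at computational biologists studying perturbation
response and at methods researchers who need disentanglement baselines on
expression data.

The neural models run on a small bundled reverse-mode autodiff engine over
numpy — no GPU framework required (and none used); see
[docs/methods.md](docs/methods.md) for the models, estimators and
numerical choices.

## Worked example

```python
import numpy as np
from michigan import (SimConfig, SplatterSimulator, log1p_counts,
                      VAE, VAEConfig, GANConfig, MichiGAN,
                      ProbabilisticPCA, mig, spearman_gap,
                      knn_infer_factors)

# simulate 1,000 cells x 200 genes with four ground-truth factors
cfg = SimConfig(n_cells=1000, n_genes=200, step_mode="linear", seed=0)
data = log1p_counts(SplatterSimulator(cfg).sample(cfg.n_cells))

# linear baseline and a beta-TCVAE (beta = 10, 10 latent dimensions)
ppca = ProbabilisticPCA(data, 10).fit()
btcvae = VAE(data, VAEConfig(latent_dim=10, beta=10.0, epochs=200,
                             batch_size=256, learning_rate=2e-3,
                             seed=0)).fit()

rng = np.random.default_rng(0)
print("PPCA   Spearman gap:", round(spearman_gap(ppca.codes,
                                                 data.factors), 3))
print("bTCVAE Spearman gap:", round(spearman_gap(btcvae.codes,
                                                 data.factors), 3))
print("bTCVAE MIG         :", round(mig(btcvae.posterior, data.factors,
                                        rng, n_samples=2000), 3))

# stage 2: conditional WGAN-GP on the frozen beta-TCVAE codes
bundle = MichiGAN(data, representation=btcvae,
                  gan_config=GANConfig(noise_dim=118, epochs=180,
                                       batch_size=128, lr=4e-4,
                                       gen_hidden=[128, 256, 512],
                                       disc_hidden=[256, 128, 10],
                                       seed=0),
                  code_mode="posterior_mean").fit()
generated = bundle.generate(seed=1)          # one cell per training code
inferred = knn_infer_factors(data, generated, k=3)
print("MichiGAN gap       :", round(spearman_gap(bundle.codes,
                                                 inferred), 3))
```

Output:

```
PPCA   Spearman gap: 0.661
bTCVAE Spearman gap: 0.319
bTCVAE MIG         : 0.292
MichiGAN gap       : 0.144
```

Reading the numbers: the probabilistic-PCA gap of 0.661 means that for a
typical ground-truth variable one latent dimension out-correlates the
runner-up by ~0.66 absolute Spearman correlation — each factor is captured
by essentially one dimension. The beta-TCVAE's MIG of 0.29 (against 0.02
for a plain VAE at this scale) quantifies the same one-factor-one-dimension
structure through mutual information. The MichiGAN gap of 0.14 is computed
on *generated* cells, whose factors are inferred by a k-nearest-neighbour
(k=3) regressor trained on the real cells: the conditional generator
retains a large share of the code-data association, where an unconditional
WGAN-GP's noise dimensions give a gap near 0.05 (entangled). At this desk
scale (200 genes, a few hundred epochs) all scores sit below their
full-scale counterparts; the orderings, not the absolute values, are the
point of the example.

A command-line interface mirrors the library
(`michigan simulate | train | generate | traverse | evaluate | predict |
rank-deltah | run-experiment`); every run directory is written with a
config snapshot and version stamp.

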