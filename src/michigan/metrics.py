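"""Disentanglement and generation-quality metrics.

Disentanglement: normalized mutual information between each latent dimension
and each ground-truth variable (estimated by stratified Monte-Carlo over the
per-cell Gaussian posteriors), the mutual information gap (MIG), the
FactorVAE fixed-factor classification metric, and a Spearman-correlation
analogue of MIG usable without a posterior (e.g. for GAN noise spaces, via
k-NN-inferred factors of generated cells).

Generation quality: random-forest real-vs-fake error on 50 principal
components (0.5 = indistinguishable) and a classifier-based inception score.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

from .data import CONTINUOUS, ExpressionDataset, FactorTable, GaussianPosterior

__all__ = [
    "MetricReport",
    "normalized_mi",
    "mig",
    "factorvae_metric",
    "spearman_gap",
    "knn_infer_factors",
    "random_forest_error",
    "inception_score",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MetricReport:
    """Named metric with replicate mean/sd and provenance hash."""

    name: str
    values: list = field(default_factory=list)
    per_factor: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 \
            else 0.0

    @property
    def n_runs(self) -> int:
        return len(self.values)

    @property
    def config_hash(self) -> str:
        blob = repr(sorted(self.config.items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def __str__(self):
        return (f"{self.name}: {self.mean:.3f} +- {self.sd:.3f} "
                f"(n={self.n_runs})")


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mixture_logpdf_1d(z, means, varis):
    """log (1/n) sum_i N(z; means_i, varis_i) for scalar components."""
    lp = (-0.5 * ((z[:, None] - means[None, :]) ** 2 / varis[None, :]
                  + np.log(varis)[None, :] + _LOG2PI))
    mx = lp.max(axis=1, keepdims=True)
    return np.log(np.exp(lp - mx).sum(axis=1)) + mx[:, 0] - np.log(len(means))


def normalized_mi(posterior: GaussianPosterior, factor: np.ndarray,
                  rng: np.random.Generator, n_samples: int = 10_000,
                  max_components: int = 2000) -> np.ndarray:
    """I(Z_j, V) / H(V) for every latent dimension j.

    V must be a categorical (or quartile-binned) factor.  The aggregate
    posterior of each dimension, overall and within each factor level, is a
    Gaussian mixture over cells; the MI is the difference of cross-entropies
    estimated by Monte-Carlo draws stratified by factor level:

        I(Z_j, V) = E_{v} E_{z ~ q(Z_j | v)} [ log q(z | v) - log q(z) ].

    ``n_samples`` is the per-dimension draw budget; mixtures are capped at
    ``max_components`` randomly chosen cells to bound cost.
    """
    factor = np.asarray(factor)
    levels, level_idx = np.unique(factor, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("factor has a single level; H(V) = 0 and the "
                         "normalized MI is undefined")
    h_v = _entropy(factor)
    n, d = posterior.mean.shape

    sub = np.arange(n)
    if n > max_components:
        sub = rng.choice(n, size=max_components, replace=False)
    mean_s, var_s, lev_s = (posterior.mean[sub], posterior.var[sub],
                            level_idx[sub])

    weights = np.bincount(level_idx, minlength=len(levels)) / n
    mi = np.zeros(d)
    for j in range(d):
        mu_j, var_j = mean_s[:, j], var_s[:, j]
        total = 0.0
        for li, w in enumerate(weights):
            members = np.flatnonzero(lev_s == li)
            if members.size == 0:
                continue
            m = max(int(round(n_samples * w)), 10)
            pick = members[rng.integers(members.size, size=m)]
            z = mu_j[pick] + np.sqrt(var_j[pick]) * rng.standard_normal(m)
            log_cond = _mixture_logpdf_1d(z, mu_j[members], var_j[members])
            log_marg = _mixture_logpdf_1d(z, mu_j, var_j)
            total += w * (log_cond - log_marg).mean()
        mi[j] = max(total, 0.0)
    return mi / h_v


def mig(posterior: GaussianPosterior, factors: FactorTable,
        rng: np.random.Generator, n_samples: int = 10_000) -> float:
    """Mutual information gap: mean over factors of the top-two gap of
    normalized mutual information across latent dimensions."""
    gaps = []
    for name in factors.names:
        nmi = normalized_mi(posterior, factors.binned(name), rng,
                            n_samples=n_samples)
        order = np.sort(nmi)[::-1]
        gaps.append(order[0] - order[1])
    return float(np.clip(np.mean(gaps), 0.0, 1.0))


# ---------------------------------------------------------------------------
# FactorVAE metric
# ---------------------------------------------------------------------------

def factorvae_metric(sampler, encode, factor_names, rng: np.random.Generator,
                     n_votes: int = 800, batch_size: int = 64,
                     n_norm: int = 2000) -> float:
    """Fixed-factor majority-vote disentanglement metric.

    Parameters
    ----------
    sampler
        ``sampler(n, rng, fixed={name: value})`` returning an
        :class:`ExpressionDataset`; ``sampler.factor_values(name, rng)``
        returning a random admissible value for a factor.
    encode
        Maps an :class:`ExpressionDataset` (or matrix) to latent codes.
    factor_names
        Ground-truth variables to vote over.

    In each vote one randomly chosen factor is clamped, a batch is
    simulated, each latent dimension is divided by its whole-data empirical
    standard deviation, and the dimension of lowest variance casts a vote
    for the clamped factor.  The metric is the accuracy of the majority-vote
    classifier mapping dimension -> factor.
    """
    if n_votes < len(factor_names):
        raise ValueError("need at least one vote per factor")
    ref = sampler(n_norm, rng)
    sd = encode(ref).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    d = sd.size

    votes = np.zeros((d, len(factor_names)), dtype=int)
    records = []
    for _ in range(n_votes):
        k = int(rng.integers(len(factor_names)))
        value = sampler.factor_values(factor_names[k], rng)
        batch = sampler(batch_size, rng, fixed={factor_names[k]: value})
        z = encode(batch) / sd
        jstar = int(np.argmin(z.var(axis=0)))
        votes[jstar, k] += 1
        records.append((jstar, k))
    classifier = votes.argmax(axis=1)
    correct = sum(classifier[j] == k for j, k in records)
    return correct / n_votes


# ---------------------------------------------------------------------------
# Spearman correlation gap
# ---------------------------------------------------------------------------

def spearman_gap(latents: np.ndarray, factors: FactorTable,
                 names=None) -> float:
    """Mean over factors of (largest - second largest) absolute Spearman
    correlation between latent dimensions and the raw factor values.

    Usable for any latent matrix (no posterior needed); constant latent
    dimensions count as correlation 0.
    """
    latents = np.asarray(latents)
    if latents.shape[1] < 2:
        raise ValueError("need at least two latent dimensions")
    names = factors.names if names is None else list(names)
    gaps = []
    for name in names:
        v = factors.raw(name)
        cors = []
        for j in range(latents.shape[1]):
            zj = latents[:, j]
            if np.std(zj) == 0 or np.std(v.astype(float)) == 0:
                cors.append(0.0)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(zj, v).statistic
            cors.append(0.0 if np.isnan(rho) else abs(float(rho)))
        order = np.sort(cors)[::-1]
        gaps.append(order[0] - order[1])
    return float(np.mean(gaps))


# ---------------------------------------------------------------------------
# k-NN ground-truth inference for generated cells
# ---------------------------------------------------------------------------

def knn_infer_factors(real: ExpressionDataset, generated: np.ndarray,
                      k: int = 3) -> FactorTable:
    """Infer ground-truth variables for generated cells from their k nearest
    real neighbours (k-NN regression for continuous factors, plurality vote
    for categorical ones)."""
    generated = np.asarray(generated)
    if generated.shape[1] != real.n_genes:
        raise ValueError("real and generated gene spaces differ")
    if k > real.n_cells:
        raise ValueError("k exceeds the number of real cells")
    cols, kinds = {}, {}
    for name in real.factors.names:
        v = real.factors.raw(name)
        kinds[name] = real.factors.kinds[name]
        if kinds[name] == CONTINUOUS:
            est = KNeighborsRegressor(n_neighbors=k)
            est.fit(real.X, v.astype(float))
            cols[name] = est.predict(generated)
        else:
            est = KNeighborsClassifier(n_neighbors=k)
            est.fit(real.X, v)
            cols[name] = est.predict(generated)
    return FactorTable(pd.DataFrame(cols), kinds)


# ---------------------------------------------------------------------------
# generation quality
# ---------------------------------------------------------------------------

def random_forest_error(real: np.ndarray, generated: np.ndarray,
                        seed: int = 0, n_cells: int = 3000,
                        n_components: int = 50, n_trees: int = 100) -> float:
    """Real-vs-generated random-forest misclassification error.

    Equal numbers of real and generated cells are projected onto the top
    principal components of the pooled matrix and a random forest is scored
    by stratified 5-fold cross-validation; 0.5 means indistinguishable.
    ``n_cells`` caps the per-side sample (smaller inputs are used whole).
    """
    real = np.asarray(real)
    generated = np.asarray(generated)
    rng = np.random.default_rng(seed)
    m = min(n_cells, real.shape[0], generated.shape[0])
    if m < 10:
        raise ValueError("too few cells for a cross-validated error")
    r = real[rng.choice(real.shape[0], size=m, replace=False)]
    g = generated[rng.choice(generated.shape[0], size=m, replace=False)]
    pooled = np.vstack([r, g])
    y = np.repeat([0, 1], m)
    k = min(n_components, pooled.shape[1], pooled.shape[0] - 1)
    pcs = PCA(n_components=k, random_state=seed).fit_transform(pooled)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    acc = cross_val_score(clf, pcs, y, cv=cv, scoring="accuracy")
    return float(1.0 - acc.mean())


def inception_score(real: ExpressionDataset, labels: np.ndarray,
                    generated: np.ndarray, seed: int = 0,
                    n_train: int = 3000, n_trees: int = 100) -> float:
    """Classifier-based inception score of generated cells.

    A random forest is trained on real cells to predict their class labels;
    IS = exp( E_x KL[ p(y|x) || p(y) ] ) over generated cells, where p(y) is
    the marginal of the predicted class probabilities.  Bounded by
    [1, n_classes]; 1 means class-uninformative generation.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        warnings.warn("single-class data: inception score is exactly 1")
        return 1.0
    rng = np.random.default_rng(seed)
    m = min(n_train, real.n_cells)
    idx = rng.choice(real.n_cells, size=m, replace=False)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 n_jobs=1)
    clf.fit(real.X[idx], labels[idx])
    p = np.clip(clf.predict_proba(np.asarray(generated)), 1e-12, 1.0)
    p = p / p.sum(axis=1, keepdims=True)
    marginal = p.mean(axis=0)
    kl = (p * (np.log(p) - np.log(marginal)[None, :])).sum(axis=1)
    return float(np.exp(kl.mean()))
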