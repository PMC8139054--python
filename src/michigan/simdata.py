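"""Seeded simulators for factor-annotated single-cell count data.

Two generators are provided:

* :func:`simulate_splatter_like` -- a gamma-Poisson hierarchy in the style of
  the Splatter simulator, with four ground-truth variables per cell: *batch*,
  *path*, *step* (progression along a differentiation path, entering linearly
  or through a smooth per-gene non-linear warp) and *library size*.
* :func:`simulate_trajectories` -- branching differentiation trajectories in
  the style of PROSSTT, with *branch*, *time* and *library size* factors.

The generative model: gene base means are gamma distributed; batch and path
act as multiplicative log-normal differential-expression factors on a random
subset of genes; cell-level expected counts are scaled to a log-normal
library size; biological noise is a gamma multiplicative layer (common
coefficient of variation ``bcv_common``) followed by Poisson sampling.

Gene-level parameters are drawn once per :class:`SplatterSimulator` instance,
so repeated sampling (e.g. with one factor clamped, as in the FactorVAE
metric protocol) stays within a single simulated "universe".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CONTINUOUS, ExpressionDataset, FactorTable

__all__ = [
    "SimConfig",
    "TrajectoryConfig",
    "SplatterSimulator",
    "simulate_splatter_like",
    "simulate_trajectories",
    "normalize_log1p",
    "log1p_counts",
]

logger = logging.getLogger(__name__)

LINEAR = "linear"
NONLINEAR = "nonlinear"


@dataclass
class SimConfig:
    """Configuration of the splatter-style simulator.

    The differential-expression parameters default to the quadruple
    (de_prob, factor_loc, factor_scale, bcv_common) = (0.5, 0.01, 0.5, 0.1);
    library-size and gene-mean hyperparameters default to the Splatter
    defaults (log-normal library with location 11 and scale 0.2; gamma gene
    means with shape 0.6 and rate 0.3).
    """

    n_cells: int = 10_000
    n_genes: int = 2000
    n_batches: int = 2
    n_paths: int = 2
    n_steps: int = 20
    de_prob: float = 0.5
    factor_loc: float = 0.01
    factor_scale: float = 0.5
    bcv_common: float = 0.1
    step_mode: str = LINEAR
    batch_loc: float = 0.1
    batch_scale: float = 0.1
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    seed: int = 0
    # optional hook: supply empirical gene means / per-gene BCV instead of
    # drawing them from the gamma prior
    gene_means: np.ndarray | None = field(default=None, repr=False)
    gene_bcv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        for name in ("n_cells", "n_genes", "n_batches", "n_paths"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_genes < 10:
            raise ValueError("n_genes < 10 gives degenerate DE sampling")
        if self.step_mode not in (LINEAR, NONLINEAR):
            raise ValueError(f"unknown step_mode {self.step_mode!r}")


@dataclass
class TrajectoryConfig:
    """Configuration of the branching-trajectory simulator."""

    n_branches: int = 3
    n_cells: int | None = None  # default depends on n_branches
    n_genes: int = 2000
    time_range: tuple = (0.0, 1.0)
    de_prob: float = 0.5
    factor_scale: float = 0.5
    bcv_common: float = 0.1
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    seed: int = 0

    _DEFAULT_CELLS = {3: 10_500, 4: 10_800, 5: 11_000}

    def __post_init__(self):
        if self.n_branches not in (3, 4, 5):
            raise ValueError("n_branches must be one of {3, 4, 5}")
        if self.n_cells is None:
            self.n_cells = self._DEFAULT_CELLS[self.n_branches]
        if self.n_cells < 1 or self.n_genes < 10:
            raise ValueError("need n_cells >= 1 and n_genes >= 10")


def _de_log_factors(rng, n_groups, n_genes, de_prob, loc, scale):
    """Log-scale multiplicative DE factors, zero for non-DE genes.

    Each gene is differentially expressed in each group with probability
    ``de_prob``; DE factors are log-normal(loc, scale) with a random half
    inverted (down-regulation), i.e. log-factors are +-|N(loc, scale)|-like
    with a random sign applied to the whole draw.
    """
    de = rng.random((n_groups, n_genes)) < de_prob
    raw = rng.normal(loc, scale, size=(n_groups, n_genes))
    sign = np.where(rng.random((n_groups, n_genes)) < 0.5, 1.0, -1.0)
    return np.where(de, sign * raw, 0.0)


class SplatterSimulator:
    """Splatter-style simulator with frozen gene-level parameters.

    Instantiating draws the gene universe (base means, batch and path DE
    factors, non-linear warp shapes) from ``cfg.seed``; :meth:`sample` then
    generates cells, optionally clamping individual factors.
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        G = cfg.n_genes
        if cfg.gene_means is not None:
            self.base_mean = np.asarray(cfg.gene_means, dtype=float)
            if self.base_mean.shape != (G,):
                raise ValueError("gene_means must have length n_genes")
        else:
            self.base_mean = rng.gamma(cfg.mean_shape,
                                       1.0 / cfg.mean_rate, size=G)
        self.base_mean = np.maximum(self.base_mean, 1e-10)
        if cfg.gene_bcv is not None:
            self.bcv = np.asarray(cfg.gene_bcv, dtype=float)
            if self.bcv.shape != (G,):
                raise ValueError("gene_bcv must have length n_genes")
        else:
            self.bcv = np.full(G, cfg.bcv_common)
        # batch effects touch every gene (replicate-to-replicate shifts),
        # with their own, weaker location/scale
        self.log_batch = _de_log_factors(
            rng, cfg.n_batches, G, 1.0, cfg.batch_loc, cfg.batch_scale)
        self.log_path = _de_log_factors(
            rng, cfg.n_paths, G, cfg.de_prob, cfg.factor_loc,
            cfg.factor_scale)
        # per-gene logistic warp for the non-linear step mode
        self.warp_mid = rng.uniform(0.25, 0.75, size=G)
        self.warp_rate = 8.0
        self._sample_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1]))

    # -- step -> path-program weight ---------------------------------------
    def step_weight(self, u: np.ndarray) -> np.ndarray:
        """Weight of the path program at progression u in [0, 1].

        Linear mode returns u itself (broadcast per gene); non-linear mode
        applies a saturating logistic ramp with gene-specific midpoints,
        normalized so every gene's weight runs from 0 at u=0 to 1 at u=1.
        """
        u = np.asarray(u, dtype=float)[:, None]
        if self.cfg.step_mode == LINEAR:
            return np.broadcast_to(u, (u.shape[0], self.cfg.n_genes))
        k, m = self.warp_rate, self.warp_mid[None, :]
        lo = _sigmoid(-k * m)
        hi = _sigmoid(k * (1.0 - m))
        return (_sigmoid(k * (u - m)) - lo) / (hi - lo)

    def mean_expression(self, batch, path, step) -> np.ndarray:
        """Noise-free relative expression programs (before library scaling)."""
        cfg = self.cfg
        u = (np.asarray(step, dtype=float) - 1.0) / (cfg.n_steps - 1.0)
        w = self.step_weight(u)
        log_mu = (np.log(self.base_mean)[None, :]
                  + self.log_batch[np.asarray(batch)]
                  + w * self.log_path[np.asarray(path)])
        return np.exp(log_mu)

    def sample(self, n_cells: int, rng: np.random.Generator | None = None,
               fixed: dict | None = None) -> ExpressionDataset:
        cfg = self.cfg
        rng = self._sample_rng if rng is None else rng
        fixed = fixed or {}

        batch = np.full(n_cells, int(fixed["batch"]), dtype=int) \
            if "batch" in fixed else rng.integers(cfg.n_batches, size=n_cells)
        path = np.full(n_cells, int(fixed["path"]), dtype=int) \
            if "path" in fixed else rng.integers(cfg.n_paths, size=n_cells)
        if "step" in fixed:
            step = np.full(n_cells, int(fixed["step"]), dtype=int)
        elif "step_quartile" in fixed:
            # clamp to one quartile band of the step range
            q = int(fixed["step_quartile"])
            edges = np.linspace(1, cfg.n_steps + 1, 5)
            step = rng.integers(int(np.ceil(edges[q])),
                                int(np.ceil(edges[q + 1])), size=n_cells)
        else:
            step = rng.integers(1, cfg.n_steps + 1, size=n_cells)

        mu0 = self.mean_expression(batch, path, step)
        if "library_size" in fixed:
            lib = np.full(n_cells, float(fixed["library_size"]))
        elif "library_size_quartile" in fixed:
            from scipy.special import ndtri

            q = int(fixed["library_size_quartile"])
            u = rng.uniform(q / 4.0, (q + 1) / 4.0, size=n_cells)
            lib = np.exp(cfg.lib_loc + cfg.lib_scale * ndtri(u))
        else:
            lib = rng.lognormal(cfg.lib_loc, cfg.lib_scale, size=n_cells)
        mu = mu0 * (lib / mu0.sum(axis=1))[:, None]

        # biological noise: gamma multiplicative layer whose CV follows the
        # Splatter-style mean trend bcv(mu) = bcv_common + 1/sqrt(mu)
        if np.all(self.bcv <= 0):
            lam = mu
        else:
            bcv = self.bcv[None, :] + 1.0 / np.sqrt(np.maximum(mu, 1e-10))
            shape = 1.0 / bcv**2
            lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)

        table = pd.DataFrame({
            "batch": batch,
            "path": path,
            "step": step.astype(float),
            "library_size": counts.sum(axis=1).astype(float),
        })
        kinds = {"batch": CATEGORICAL, "path": CATEGORICAL,
                 "step": CONTINUOUS, "library_size": CONTINUOUS}
        return ExpressionDataset(counts.astype(np.float64),
                                 FactorTable(table, kinds), counts=counts)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class MetricSampler:
    """Simulator adapter for the fixed-factor (FactorVAE-style) protocol.

    Continuous ground-truth variables are defined at quartile resolution
    (step quartile, library-size quartile), so "fixing" one clamps the
    whole quartile band rather than an exact value; categorical factors
    are clamped to one level.  ``transform`` maps raw counts to the
    model-facing values (log1p by default).
    """

    FACTORS = ("batch", "path", "step", "library_size")

    def __init__(self, sim: "SplatterSimulator", transform=None):
        self.sim = sim
        self.transform = log1p_counts if transform is None else transform

    def __call__(self, n, rng, fixed=None):
        fixed = dict(fixed or {})
        if "step" in fixed:
            fixed["step_quartile"] = fixed.pop("step")
        if "library_size" in fixed:
            fixed["library_size_quartile"] = fixed.pop("library_size")
        return self.transform(self.sim.sample(n, rng, fixed=fixed))

    def factor_values(self, name, rng):
        cfg = self.sim.cfg
        if name == "batch":
            return int(rng.integers(cfg.n_batches))
        if name == "path":
            return int(rng.integers(cfg.n_paths))
        if name in ("step", "library_size"):
            return int(rng.integers(4))  # quartile index
        raise KeyError(name)


def simulate_splatter_like(cfg: SimConfig) -> ExpressionDataset:
    """Simulate a splatter-style dataset (batch/path/step/library size)."""
    return SplatterSimulator(cfg).sample(cfg.n_cells)


def simulate_trajectories(cfg: TrajectoryConfig) -> ExpressionDataset:
    """Simulate a branching differentiation trajectory.

    All branches share the root expression program at time 0 and diverge
    smoothly (log-linearly in time) toward branch-specific programs at
    time 1, with library-size scaling and gamma-Poisson noise as in the
    splatter-style simulator.
    """
    rng = np.random.default_rng(cfg.seed)
    G, n = cfg.n_genes, cfg.n_cells
    base = np.maximum(rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=G),
                      1e-10)
    log_branch = _de_log_factors(rng, cfg.n_branches, G, cfg.de_prob, 0.0,
                                 cfg.factor_scale)
    branch = rng.integers(cfg.n_branches, size=n)
    lo, hi = cfg.time_range
    time = rng.uniform(lo, hi, size=n)

    log_mu = np.log(base)[None, :] + time[:, None] * log_branch[branch]
    mu0 = np.exp(log_mu)
    lib = rng.lognormal(cfg.lib_loc, cfg.lib_scale, size=n)
    mu = mu0 * (lib / mu0.sum(axis=1))[:, None]
    if cfg.bcv_common > 0:
        bcv = cfg.bcv_common + 1.0 / np.sqrt(np.maximum(mu, 1e-10))
        shape = 1.0 / bcv**2
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)

    table = pd.DataFrame({
        "branch": branch,
        "time": time,
        "library_size": counts.sum(axis=1).astype(float),
    })
    kinds = {"branch": CATEGORICAL, "time": CONTINUOUS,
             "library_size": CONTINUOUS}
    return ExpressionDataset(counts.astype(np.float64),
                             FactorTable(table, kinds), counts=counts)


def normalize_log1p(data: ExpressionDataset) -> ExpressionDataset:
    """Library-size normalization followed by log(1 + x).

    Cells are scaled to the median library size; all-zero cells are dropped
    (logged). Raw counts are retained alongside the normalized values.
    """
    counts = data.counts if data.counts is not None else data.X
    if np.any(counts < 0):
        raise ValueError("normalize_log1p expects nonnegative counts")
    totals = counts.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d all-zero cell(s)", n_dropped)
        data = data.subset(keep)
        counts = data.counts if data.counts is not None else data.X
        totals = counts.sum(axis=1)
    target = np.median(totals)
    X = np.log1p(counts * (target / totals)[:, None])
    return ExpressionDataset(X, data.factors.copy(), counts=data.counts,
                             gene_names=data.gene_names,
                             cell_names=data.cell_names)


def log1p_counts(data: ExpressionDataset) -> ExpressionDataset:
    """log(1 + counts) without library-size scaling.

    This is the model-facing transform used in the simulation experiments:
    it stabilizes variance while leaving library size recoverable as a
    ground-truth factor of variation.
    """
    counts = data.counts if data.counts is not None else data.X
    if np.any(counts < 0):
        raise ValueError("log1p_counts expects nonnegative counts")
    return ExpressionDataset(np.log1p(counts), data.factors.copy(),
                             counts=data.counts, gene_names=data.gene_names,
                             cell_names=data.cell_names)
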