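"""Replicated simulate -> train -> evaluate experiments.

Drives the multi-seed comparisons the package is built around: simulate a
factor-annotated dataset, fit a set of representation/generative models,
score them with disentanglement and generation metrics, and tabulate
mean +- sd per (method, metric) over seeds.  Partial failures are recorded
per seed and the affected cells marked incomplete rather than aborting the
whole run.
"""

from __future__ import annotations

import json
import platform
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import ExpressionDataset
from .gan import GANConfig, InfoWGANGP, WGANGP
from .metrics import (factorvae_metric, inception_score, knn_infer_factors,
                      mig, random_forest_error, spearman_gap)
from .pipeline import MichiGAN
from .ppca import ProbabilisticPCA
from .simdata import (SimConfig, SplatterSimulator, TrajectoryConfig,
                      log1p_counts, simulate_trajectories)
from .vae import VAE, VAEConfig

__all__ = ["run_experiment"]

VAE_METHODS = {"ppca", "vae", "betavae", "btcvae"}
GAN_METHODS = {"wgan", "infowgan", "michigan", "michigan-pca"}


def _simulate(sim_cfg: dict, seed: int):
    cfg = dict(sim_cfg)
    preset = cfg.pop("preset", "splatter")
    cfg["seed"] = seed
    if preset == "splatter":
        sim = SplatterSimulator(SimConfig(**cfg))
        data = sim.sample(sim.cfg.n_cells)
        return data, sim
    if preset == "prosstt":
        return simulate_trajectories(TrajectoryConfig(**cfg)), None
    raise ValueError(f"unknown preset {preset!r}")


def _fit_method(name: str, data, options: dict, seed: int):
    opts = dict(options)
    latent_dim = opts.pop("latent_dim", 10)
    if name == "ppca":
        return ProbabilisticPCA(data, latent_dim).fit()
    if name in ("vae", "betavae", "btcvae"):
        beta = opts.pop("beta", 0.0 if name == "vae" else 10.0)
        mode = "kl_total" if name == "betavae" else "total_correlation"
        cfg = VAEConfig(latent_dim=latent_dim, beta=beta, penalty_mode=mode,
                        seed=seed, **opts)
        return VAE(data, cfg).fit()
    if name == "wgan":
        cfg = GANConfig(noise_dim=latent_dim, code_dim=0, seed=seed, **opts)
        return WGANGP(data, cfg).fit()
    if name == "infowgan":
        cfg = GANConfig(noise_dim=latent_dim, code_dim=latent_dim,
                        seed=seed, **opts)
        return InfoWGANGP(data, cfg).fit()
    if name in ("michigan", "michigan-pca"):
        rep_opts = opts.pop("representation", {})
        if name == "michigan":
            rep = VAEConfig(latent_dim=latent_dim, beta=10.0, seed=seed,
                            **rep_opts)
        else:
            rep = "ppca"
        gcfg = GANConfig(seed=seed, **opts)
        return MichiGAN(data, representation=rep, gan_config=gcfg,
                        latent_dim=latent_dim, seed=seed).fit()
    raise ValueError(f"unknown method {name!r}")


def _latents_for_gan(result, data, seed: int):
    """(latents, generated) pair used for correlation metrics of GANs."""
    from .pipeline import MichiGANResults

    if isinstance(result, MichiGANResults):
        gen = result.generate(seed=seed)
        return result.codes, gen
    gen, latents = result.generate(n=data.n_cells, seed=seed)
    return latents, gen


def _evaluate(name, result, data, sim, metric_names, seed, rng,
              mi_samples: int):
    from .pipeline import MichiGANResults

    out = {}
    is_gan = isinstance(result, MichiGANResults) or hasattr(
        result, "disc_loss_history")
    if is_gan:
        latents, generated = _latents_for_gan(result, data, seed)
        inferred = knn_infer_factors(data, generated, k=3)
    for metric in metric_names:
        if metric == "sgap":
            out[metric] = (spearman_gap(latents, inferred) if is_gan else
                           spearman_gap(result.codes, data.factors))
        elif metric == "mig":
            if is_gan:
                continue  # no posterior for generator latents
            post = result.posterior() if callable(
                getattr(result, "posterior", None)) else result.posterior
            out[metric] = mig(post, data.factors, rng,
                              n_samples=mi_samples)
        elif metric == "factorvae":
            if is_gan or sim is None:
                continue
            from .simdata import MetricSampler

            sampler = MetricSampler(sim)
            encode = _encoder_fn(result)
            out[metric] = factorvae_metric(
                sampler, encode, list(MetricSampler.FACTORS),
                rng, n_votes=200, batch_size=64, n_norm=1000)
        elif metric == "rf":
            generated_m = generated if is_gan else result.generate(
                min(data.n_cells, 3000), rng)
            out[metric] = random_forest_error(
                data.X, generated_m, seed=seed,
                n_cells=min(data.n_cells, 3000))
        elif metric == "inception":
            labels = _composite_labels(data)
            generated_m = generated if is_gan else result.generate(
                min(data.n_cells, 3000), rng)
            out[metric] = inception_score(data, labels, generated_m,
                                          seed=seed)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def _encoder_fn(result):
    from .ppca import PPCAResults

    if isinstance(result, PPCAResults):
        return lambda d: result.transform(d)
    return lambda d: result.encode(d).mean


def _composite_labels(data: ExpressionDataset):
    """Cell-type surrogate for simulated data: batch x path composite."""
    names = data.factors.names
    cats = [n for n in names if data.factors.kinds[n] == "categorical"]
    if not cats:
        return np.zeros(data.n_cells, dtype=int)
    codes = np.zeros(data.n_cells, dtype=int)
    for n in cats:
        codes = codes * 10 + data.factors.binned(n)
    return codes


def run_experiment(config: dict | str | Path, out_dir) -> pd.DataFrame:
    """Execute a replicated experiment described by a config mapping
    (or YAML/JSON file path) and write a report directory.

    Config keys: ``seeds`` (list) or ``n_seeds``; ``simulation`` (simulator
    parameters incl. ``preset``); ``methods`` (list of names or
    {name, options} mappings); ``metrics`` (list); ``mi_samples``
    (MC budget per latent dimension); ``normalize`` ("log1p" default or
    "median_log1p").
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seeds = config.get("seeds")
    if seeds is None:
        seeds = list(range(config.get("n_seeds", 1)))
    methods = []
    for m in config.get("methods", []):
        if isinstance(m, str):
            methods.append((m, {}))
        else:
            m = dict(m)
            methods.append((m.pop("name"), m.pop("options", m)))
    metric_names = list(config.get("metrics", ["sgap"]))
    sim_cfg = dict(config.get("simulation", {}))
    normalize = config.get("normalize", "log1p")
    mi_samples = int(config.get("mi_samples", 10_000))

    rows, failures = [], []
    for seed in seeds:
        raw, sim = _simulate(sim_cfg, seed)
        if normalize == "median_log1p":
            from .simdata import normalize_log1p

            data = normalize_log1p(raw)
        else:
            data = log1p_counts(raw)
        for name, options in methods:
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(seed), 77]))
            try:
                result = _fit_method(name, data, options, seed)
                scores = _evaluate(name, result, data, sim, metric_names,
                                   seed, rng, mi_samples)
                for metric, value in scores.items():
                    rows.append({"seed": seed, "method": name,
                                 "metric": metric, "value": value})
            except Exception as exc:  # record, keep going
                failures.append({"seed": seed, "method": name,
                                 "error": repr(exc),
                                 "traceback": traceback.format_exc()})

    long = pd.DataFrame(rows)
    if len(long):
        report = (long.groupby(["method", "metric"])["value"]
                  .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1
                       else 0.0, n="count").reset_index())
    else:
        report = pd.DataFrame(columns=["method", "metric", "mean", "sd",
                                       "n"])
    report["complete"] = [m not in {f["method"] for f in failures}
                          for m in report["method"]] if len(report) else []

    long.to_csv(out_dir / "scores_long.tsv", sep="\t", index=False)
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    with open(out_dir / "config_snapshot.json", "w") as fh:
        json.dump({"config": _jsonable(config), "seeds": seeds}, fh,
                  indent=2)
    with open(out_dir / "versions.json", "w") as fh:
        json.dump({"michigan": __version__,
                   "python": platform.python_version(),
                   "numpy": np.__version__,
                   "pandas": pd.__version__}, fh, indent=2)
    if failures:
        with open(out_dir / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
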