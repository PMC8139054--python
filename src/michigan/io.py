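"""Readers and writers for the formats the toolkit touches.

Datasets travel as:

* a MatrixMarket triplet directory (``matrix.mtx`` + ``genes.tsv`` +
  ``barcodes.tsv`` + ``metadata.tsv`` with one column per factor, plus a
  small ``factor_kinds.tsv`` sidecar),
* a dense TSV (cells x genes, with a ``<stem>.metadata.tsv`` companion), or
* a single-file HDF5 bundle (``.h5ad`` via anndata; matrix in ``X``, raw
  counts in ``layers/counts``, factors in ``obs``).

Model checkpoints are single HDF5 files holding the flat parameter arrays
plus a JSON config; the architecture is rebuilt from the config and the
arrays are loaded back in order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CATEGORICAL, CONTINUOUS, ExpressionDataset, FactorTable

__all__ = ["read_expression", "write_expression", "save_model", "load_model"]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def _read_names(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None)
    return frame.iloc[:, 0].astype(str).to_numpy()


def _read_factor_table(meta_path: Path, kinds_path: Path) -> FactorTable:
    table = pd.read_csv(meta_path, sep="\t")
    kinds = {}
    if kinds_path.exists():
        kf = pd.read_csv(kinds_path, sep="\t")
        kinds = dict(zip(kf["factor"], kf["kind"]))
    else:  # fall back on dtype sniffing
        for name in table.columns:
            kinds[name] = (CONTINUOUS if np.issubdtype(
                table[name].dtype, np.floating) else CATEGORICAL)
    return FactorTable(table, kinds)


def read_expression(path) -> ExpressionDataset:
    """Load a dataset from an MTX triplet directory, dense TSV or ``.h5ad``.

    Matrix orientation is normalized to cells x genes using the name files;
    an orientation that matches neither axis raises an error naming the
    offending file.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_f, cells_f = path / "genes.tsv", path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        mat = scipy.io.mmread(mtx)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat)
                         else mat)
        genes = _read_names(genes_f)
        cells = _read_names(cells_f)
        if mat.shape == (len(cells), len(genes)):
            pass
        elif mat.shape == (len(genes), len(cells)):
            mat = mat.T
        else:
            raise ValueError(
                f"matrix.mtx shape {mat.shape} matches neither "
                f"({len(cells)} barcodes, {len(genes)} genes) orientation")
        factors = _read_factor_table(path / "metadata.tsv",
                                     path / "factor_kinds.tsv")
        counts = mat if np.allclose(mat, np.round(mat)) else None
        return ExpressionDataset(
            mat.astype(float), factors,
            counts=None if counts is None else counts.astype(np.int64),
            gene_names=genes, cell_names=cells)
    if path.suffix == ".h5ad":
        import anndata

        return ExpressionDataset.from_anndata(anndata.read_h5ad(path))
    if path.suffix in (".tsv", ".txt", ".csv"):
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        meta_path = path.with_suffix(".metadata.tsv")
        if not meta_path.exists():
            raise FileNotFoundError(
                f"dense table {path.name} needs a metadata companion "
                f"{meta_path.name}")
        factors = _read_factor_table(
            meta_path, path.with_suffix(".factor_kinds.tsv"))
        mat = frame.to_numpy(dtype=float)
        counts = mat if np.allclose(mat, np.round(mat)) else None
        return ExpressionDataset(
            mat, factors,
            counts=None if counts is None else counts.astype(np.int64),
            gene_names=frame.columns.to_numpy(),
            cell_names=frame.index.to_numpy())
    raise ValueError(f"unrecognized dataset path {path}")


def write_expression(data: ExpressionDataset, path, fmt: str | None = None
                     ) -> Path:
    """Write a dataset as an MTX triplet dir (``fmt="mtx"``), dense TSV or
    ``.h5ad`` bundle (inferred from the path when ``fmt`` is None)."""
    path = Path(path)
    if fmt is None:
        fmt = ("h5ad" if path.suffix == ".h5ad"
               else "tsv" if path.suffix in (".tsv", ".csv") else "mtx")
    if fmt == "h5ad":
        data.to_anndata().write_h5ad(path)
        return path
    mat = data.counts if data.counts is not None else data.X
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.csr_matrix(np.asarray(mat))
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        pd.Series(data.gene_names).to_csv(path / "genes.tsv", sep="\t",
                                          index=False, header=False)
        pd.Series(data.cell_names).to_csv(path / "barcodes.tsv", sep="\t",
                                          index=False, header=False)
        data.factors.table.to_csv(path / "metadata.tsv", sep="\t",
                                  index=False)
        pd.DataFrame({"factor": list(data.factors.kinds),
                      "kind": list(data.factors.kinds.values())}).to_csv(
            path / "factor_kinds.tsv", sep="\t", index=False)
        return path
    if fmt == "tsv":
        frame = pd.DataFrame(np.asarray(mat), index=data.cell_names,
                             columns=data.gene_names)
        frame.to_csv(path, sep="\t")
        data.factors.table.to_csv(path.with_suffix(".metadata.tsv"),
                                  sep="\t", index=False)
        pd.DataFrame({"factor": list(data.factors.kinds),
                      "kind": list(data.factors.kinds.values())}).to_csv(
            path.with_suffix(".factor_kinds.tsv"), sep="\t", index=False)
        return path
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def _cfg_to_json(cfg) -> str:
    d = dataclasses.asdict(cfg)
    clean = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        if isinstance(v, tuple):
            v = list(v)
        clean[k] = v
    return json.dumps(clean)


def _write_arrays(group, arrays):
    for i, a in enumerate(arrays):
        group.create_dataset(f"p{i:04d}", data=np.asarray(a))


def _read_arrays(group):
    return [np.asarray(group[k]) for k in sorted(group.keys())]


def save_model(results, path) -> Path:
    """Persist fitted results (PPCA, VAE family, GAN family, MichiGAN)."""
    import h5py

    from .gan import GANResults
    from .pipeline import MichiGANResults
    from .ppca import PPCAResults
    from .vae import VAEResults

    path = Path(path)

    def _write(h, res):
        if isinstance(res, PPCAResults):
            h.attrs["kind"] = "ppca"
            h.create_dataset("W", data=res.W)
            h.create_dataset("mean", data=res.mean)
            h.create_dataset("codes", data=res.codes)
            h.attrs["sigma2"] = res.sigma2
        elif isinstance(res, VAEResults):
            h.attrs["kind"] = "vae"
            h.attrs["config"] = _cfg_to_json(res.config)
            _write_arrays(h.create_group("encoder"),
                          res._encoder.state_arrays())
            _write_arrays(h.create_group("decoder"),
                          res._decoder.state_arrays())
            h.create_dataset("posterior_mean", data=res.posterior.mean)
            h.create_dataset("posterior_var", data=res.posterior.var)
            h.create_dataset("loss_history", data=np.asarray(
                res.loss_history))
        elif isinstance(res, GANResults):
            h.attrs["kind"] = "gan"
            h.attrs["mode"] = res.mode
            h.attrs["config"] = _cfg_to_json(res.config)
            _write_arrays(h.create_group("generator"),
                          res.generator.state_arrays())
            _write_arrays(h.create_group("critic"),
                          res.critic.state_arrays())
            if res.training_codes is not None:
                h.create_dataset("training_codes", data=res.training_codes)
            h.create_dataset("disc_loss", data=np.asarray(
                res.disc_loss_history))
            h.create_dataset("gen_loss", data=np.asarray(
                res.gen_loss_history))
        elif isinstance(res, MichiGANResults):
            h.attrs["kind"] = "michigan"
            h.attrs["code_mode"] = res.code_mode
            h.create_dataset("codes", data=res.codes)
            _write(h.create_group("stage1"), res.stage1)
            _write(h.create_group("stage2"), res.gan)
        else:
            raise TypeError(f"cannot save {type(res).__name__}")

    with h5py.File(path, "w") as h:
        _write(h, results)
    return path


def load_model(path):
    """Inverse of :func:`save_model`."""
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as h:
        return _load_group(h)


def _load_group(h):
    from .gan import GANConfig, GANResults, _Critic, _Generator
    from .pipeline import MichiGANResults
    from .ppca import PPCAResults
    from .vae import VAEConfig, VAEResults, _Encoder

    kind = h.attrs["kind"]
    if kind == "ppca":
        res = PPCAResults(W=np.asarray(h["W"]),
                          sigma2=float(h.attrs["sigma2"]),
                          mean=np.asarray(h["mean"]))
        res._codes = np.asarray(h["codes"])
        return res
    if kind == "vae":
        cfg = VAEConfig(**json.loads(h.attrs["config"]))
        enc_arrays = _read_arrays(h["encoder"])
        dec_arrays = _read_arrays(h["decoder"])
        n_genes = enc_arrays[0].shape[0]
        rng = np.random.default_rng(0)
        from ._nn import mlp

        encoder = _Encoder(n_genes, cfg, rng)
        decoder = mlp(cfg.latent_dim, list(cfg.hidden_sizes_dec), n_genes,
                      rng, batchnorm=True, dropout=cfg.dropout)
        encoder.load_state_arrays(enc_arrays)
        decoder.load_state_arrays(dec_arrays)
        encoder.train(False)
        decoder.train(False)
        res = VAEResults.__new__(VAEResults)
        res._encoder = encoder
        res._decoder = decoder
        res.config = cfg
        res.loss_history = list(np.asarray(h["loss_history"]))
        from .data import GaussianPosterior

        res.posterior = GaussianPosterior(np.asarray(h["posterior_mean"]),
                                          np.asarray(h["posterior_var"]))
        return res
    if kind == "gan":
        cfg_d = json.loads(h.attrs["config"])
        cfg_d["adam_betas"] = tuple(cfg_d.get("adam_betas", (0.5, 0.9)))
        cfg = GANConfig(**cfg_d)
        mode = h.attrs["mode"]
        gen_arrays = _read_arrays(h["generator"])
        n_genes = _read_arrays(h["critic"])[0].shape[0]
        rng = np.random.default_rng(0)
        gen = _Generator(cfg.noise_dim + cfg.code_dim, n_genes, cfg, rng)
        critic = _Critic(n_genes, cfg, rng,
                         q_head=mode in ("infowgan_gp", "ss_infowgan_gp"),
                         projection=mode == "pcwgan_gp")
        gen.load_state_arrays(gen_arrays)
        critic.load_state_arrays(_read_arrays(h["critic"]))
        gen.train(False)
        codes = np.asarray(h["training_codes"]) if "training_codes" in h \
            else None
        return GANResults(mode, gen, critic, cfg,
                          list(np.asarray(h["disc_loss"])),
                          list(np.asarray(h["gen_loss"])), codes=codes)
    if kind == "michigan":
        stage1 = _load_group(h["stage1"])
        gan = _load_group(h["stage2"])
        return MichiGANResults(stage1, gan, np.asarray(h["codes"]),
                               h.attrs["code_mode"])
    raise ValueError(f"unknown checkpoint kind {kind!r}")
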