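"""In-memory containers: expression matrices with ground-truth factor tables.

An :class:`ExpressionDataset` couples a cells x genes matrix (raw counts
and/or processed values) with a :class:`FactorTable` of per-cell variables
(batch, path, step, library size, branch, time, cell type, treatment, ...).
Continuous factors carry a quartile-binned twin used by mutual-information
based metrics; monotone-correlation metrics use the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FactorTable", "ExpressionDataset", "GaussianPosterior"]

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


@dataclass
class FactorTable:
    """Per-cell ground-truth variables with declared kinds.

    Parameters
    ----------
    table
        One row per cell, one column per factor (raw values).
    kinds
        Maps factor name to ``"categorical"`` or ``"continuous"``.
    """

    table: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in self.table.columns:
            self.kinds.setdefault(name, CATEGORICAL)

    @property
    def names(self) -> list:
        return list(self.table.columns)

    def __len__(self):
        return len(self.table)

    def _check(self, name: str) -> None:
        if name not in self.table.columns:
            raise KeyError(
                f"factor {name!r} not found; available factors: "
                f"{list(self.table.columns)}")

    def raw(self, name: str) -> np.ndarray:
        """Raw factor values (continuous factors unbinned)."""
        self._check(name)
        return self.table[name].to_numpy()

    def binned(self, name: str, n_bins: int = 4) -> np.ndarray:
        """Integer-coded version of a factor.

        Categorical factors are label-encoded; continuous factors are
        quantile-binned (quartiles by default), the discretisation used for
        mutual-information estimation.
        """
        self._check(name)
        values = self.table[name]
        if self.kinds[name] == CONTINUOUS:
            codes = pd.qcut(values.rank(method="first"), n_bins,
                            labels=False, duplicates="drop")
            return np.asarray(codes, dtype=int)
        codes, _ = pd.factorize(values, sort=True)
        return np.asarray(codes, dtype=int)

    def subset(self, idx) -> "FactorTable":
        return FactorTable(self.table.iloc[idx].reset_index(drop=True),
                           dict(self.kinds))

    def copy(self) -> "FactorTable":
        return FactorTable(self.table.copy(), dict(self.kinds))


class ExpressionDataset:
    """Cells x genes expression matrix plus a factor table.

    Attributes
    ----------
    X
        Processed (model-facing) values, cells x genes.
    counts
        Raw integer counts, same shape, or None if unavailable.
    gene_names, cell_names
        Identifier arrays.
    factors
        :class:`FactorTable` with one row per cell.
    """

    def __init__(self, X, factors: FactorTable, counts=None,
                 gene_names=None, cell_names=None):
        self.X = np.asarray(X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cells x genes)")
        self.counts = None if counts is None else np.asarray(counts)
        if self.counts is not None and self.counts.shape != self.X.shape:
            raise ValueError("counts and X shapes differ")
        n, g = self.X.shape
        if len(factors) != n:
            raise ValueError(
                f"factor table has {len(factors)} rows for {n} cells")
        self.factors = factors
        self.gene_names = (np.array([f"gene{i}" for i in range(g)])
                           if gene_names is None else np.asarray(gene_names))
        self.cell_names = (np.array([f"cell{i}" for i in range(n)])
                           if cell_names is None else np.asarray(cell_names))

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            self.X[idx],
            self.factors.subset(idx),
            counts=None if self.counts is None else self.counts[idx],
            gene_names=self.gene_names,
            cell_names=self.cell_names[idx],
        )

    def to_anndata(self):
        import anndata

        obs = self.factors.table.copy()
        obs.index = pd.Index(self.cell_names.astype(str), name="cell")
        ad = anndata.AnnData(X=self.X.copy(), obs=obs)
        ad.var_names = self.gene_names.astype(str)
        if self.counts is not None:
            ad.layers["counts"] = self.counts.copy()
        ad.uns["factor_kinds"] = dict(self.factors.kinds)
        return ad

    @classmethod
    def from_anndata(cls, ad) -> "ExpressionDataset":
        X = np.asarray(ad.X)
        kinds = dict(ad.uns.get("factor_kinds", {}))
        factors = FactorTable(ad.obs.reset_index(drop=True).copy(), kinds)
        counts = ad.layers.get("counts") if ad.layers else None
        return cls(X, factors,
                   counts=None if counts is None else np.asarray(counts),
                   gene_names=ad.var_names.to_numpy(),
                   cell_names=ad.obs_names.to_numpy())


@dataclass
class GaussianPosterior:
    """Per-cell diagonal-Gaussian latent posterior q(Z|X).

    ``mean`` and ``var`` are both cells x latent-dim arrays; PPCA posteriors
    share one covariance across cells, stored here as its diagonal repeated
    per cell.
    """

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var shapes differ")
        if not (np.all(np.isfinite(self.mean)) and np.all(self.var > 0)):
            raise ValueError("posterior must be finite with positive variance")

    @property
    def latent_dim(self) -> int:
        return self.mean.shape[1]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + np.sqrt(self.var) * rng.standard_normal(
            self.mean.shape)

    def subset(self, idx) -> "GaussianPosterior":
        return GaussianPosterior(self.mean[idx], self.var[idx])
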