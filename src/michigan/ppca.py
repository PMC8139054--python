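"""Probabilistic PCA with its exact Gaussian posterior.

Maximum-likelihood fit in closed form (Tipping & Bishop): with sample
covariance eigenpairs (lambda_i, u_i),

    sigma^2 = mean of the discarded eigenvalues,
    W = U_d (Lambda_d - sigma^2 I)^(1/2),

and the latent posterior is Gaussian,

    q(z | x) = N(M^-1 W^T (x - mu), sigma^2 M^-1),  M = W^T W + sigma^2 I.

The tractable posterior is what makes mutual-information based
disentanglement metrics computable for a linear baseline.
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionDataset, GaussianPosterior

__all__ = ["ProbabilisticPCA", "PPCAResults"]


class ProbabilisticPCA:
    """Probabilistic PCA model for a cells x genes matrix.

    Parameters
    ----------
    data
        :class:`ExpressionDataset` or plain 2-D array (cells x genes).
    n_components
        Latent dimensionality d; must satisfy d < min(n_cells, n_genes).
    """

    def __init__(self, data, n_components: int = 10):
        self.X = data.X if isinstance(data, ExpressionDataset) else \
            np.asarray(data, dtype=np.float64)
        n, g = self.X.shape
        if not 0 < n_components < min(n, g):
            raise ValueError(
                f"n_components must be in [1, {min(n, g) - 1}]")
        self.d = n_components

    def fit(self) -> "PPCAResults":
        X = self.X
        n, g = X.shape
        mu = X.mean(axis=0)
        Xc = X - mu
        # eigen-decompose through the thin SVD of the centered matrix
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        evals = s**2 / n
        d = self.d
        n_pos = int((evals > 1e-12).sum())
        if n_pos < d:
            raise ValueError(
                f"data has only {n_pos} positive eigenvalues; "
                f"the largest attainable n_components is {n_pos}")
        sigma2 = float(evals[d:].mean()) if evals.size > d else 0.0
        W = Vt[:d].T * np.sqrt(np.maximum(evals[:d] - sigma2, 0.0))
        return PPCAResults(W=W, sigma2=sigma2, mean=mu, X=X)


class PPCAResults:
    """Fitted PPCA: loadings, noise variance and the exact posterior."""

    def __init__(self, W: np.ndarray, sigma2: float, mean: np.ndarray,
                 X: np.ndarray | None = None):
        self.W = W
        self.sigma2 = sigma2
        self.mean = mean
        d = W.shape[1]
        M = W.T @ W + sigma2 * np.eye(d)
        self._Minv = np.linalg.inv(M)
        self.posterior_cov = sigma2 * self._Minv
        # guard: symmetric positive definite up to round-off (sigma2 > 0)
        self.posterior_cov = 0.5 * (self.posterior_cov +
                                    self.posterior_cov.T)
        self._codes = None if X is None else self.transform(X)

    @property
    def latent_dim(self) -> int:
        return self.W.shape[1]

    def transform(self, X) -> np.ndarray:
        """Posterior mean codes E[z | x]."""
        X = X.X if isinstance(X, ExpressionDataset) else np.asarray(X)
        return (X - self.mean) @ self.W @ self._Minv.T

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            raise ValueError("model was fitted without stored data")
        return self._codes

    def posterior(self, X=None) -> GaussianPosterior:
        """Diagonal-Gaussian view of the exact posterior (shared variances)."""
        mean = self.codes if X is None else self.transform(X)
        var_diag = np.maximum(np.diag(self.posterior_cov), 1e-12)
        return GaussianPosterior(mean, np.broadcast_to(
            var_diag, mean.shape).copy())

    def sample_codes(self, rng: np.random.Generator, X=None) -> np.ndarray:
        """Draw z ~ q(z | x) using the full posterior covariance."""
        mean = self.codes if X is None else self.transform(X)
        L = np.linalg.cholesky(self.posterior_cov + 1e-12 *
                               np.eye(self.latent_dim))
        return mean + rng.standard_normal(mean.shape) @ L.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Decode latent codes to the data space (posterior-predictive mean)."""
        return np.asarray(Z) @ self.W.T + self.mean

    def summary(self) -> str:
        lines = ["Probabilistic PCA",
                 f"  latent dimensions : {self.latent_dim}",
                 f"  genes             : {self.W.shape[0]}",
                 f"  noise variance    : {self.sigma2:.6g}"]
        share = (self.W**2).sum(axis=0)
        tot = share.sum() + self.sigma2 * self.W.shape[0]
        for j, s in enumerate(share):
            lines.append(f"  dim {j:2d} signal share: {s / tot:.3f}")
        return "\n".join(lines)
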