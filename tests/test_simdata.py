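"""Simulator contracts: determinism, factor structure, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import pearsonr, spearmanr

from michigan.data import CONTINUOUS
from michigan.ppca import ProbabilisticPCA
from michigan.simdata import (SimConfig, SplatterSimulator, TrajectoryConfig,
                              log1p_counts, normalize_log1p,
                              simulate_splatter_like, simulate_trajectories)


class TestSplatterLike:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_cells=500, n_genes=100, seed=1)
        a = simulate_splatter_like(cfg)
        b = simulate_splatter_like(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert a.factors.table.equals(b.factors.table)

    def test_counts_are_nonnegative_integers(self):
        data = simulate_splatter_like(SimConfig(n_cells=200, n_genes=50,
                                                seed=2))
        assert np.issubdtype(data.counts.dtype, np.integer)
        assert (data.counts >= 0).all()

    def test_library_size_factor_is_realized_row_sum(self):
        data = simulate_splatter_like(SimConfig(n_cells=200, n_genes=50,
                                                seed=3))
        assert np.array_equal(data.factors.raw("library_size"),
                              data.counts.sum(axis=1).astype(float))
        assert data.factors.kinds["library_size"] == CONTINUOUS
        quart = data.factors.binned("library_size")
        assert set(np.unique(quart)) == {0, 1, 2, 3}

    def test_no_de_means_no_path_signal(self):
        cfg = SimConfig(n_cells=800, n_genes=100, de_prob=0.0, seed=4)
        data = simulate_splatter_like(cfg)
        path = data.factors.raw("path")
        X = log1p_counts(data).X
        cors = [abs(spearmanr(X[:, j], path).statistic)
                for j in range(X.shape[1])]
        assert np.nanmax(cors) < 0.15

    def test_rejects_degenerate_configs(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=5)
        with pytest.raises(ValueError):
            SimConfig(de_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_steps=1)
        with pytest.raises(ValueError):
            SimConfig(step_mode="cubic")

    def test_fixed_factor_sampling(self, small_simulator, rng):
        batch = small_simulator.sample(64, rng, fixed={"path": 1, "step": 5})
        assert (batch.factors.raw("path") == 1).all()
        assert (batch.factors.raw("step") == 5.0).all()

    def test_ppca_identifies_each_factor(self):
        """Probabilistic PCA on default-structure data has at least one
        latent dimension tracking batch, path and library size."""
        cfg = SimConfig(n_cells=2000, n_genes=500, seed=0)
        data = log1p_counts(simulate_splatter_like(cfg))
        Z = ProbabilisticPCA(data, 10).fit().codes
        for name in ("batch", "path", "library_size"):
            v = data.factors.raw(name)
            best = max(abs(spearmanr(Z[:, j], v).statistic)
                       for j in range(Z.shape[1]))
            assert best > 0.5, name

    def test_nonlinear_step_reduces_linear_correlation(self):
        """The non-linear warp genuinely reduces the best linear (Pearson)
        correlation between a PCA dimension and step, on matched seeds."""
        def best_pearson(mode):
            cfg = SimConfig(n_cells=1500, n_genes=300, step_mode=mode,
                            seed=11)
            data = log1p_counts(simulate_splatter_like(cfg))
            Z = ProbabilisticPCA(data, 10).fit().codes
            step = data.factors.raw("step")
            return max(abs(pearsonr(Z[:, j], step).statistic)
                       for j in range(Z.shape[1]))

        assert best_pearson("nonlinear") < best_pearson("linear")

    def test_gene_mean_hook(self):
        means = np.linspace(0.5, 5.0, 50)
        cfg = SimConfig(n_cells=2000, n_genes=50, de_prob=0.0,
                        bcv_common=0.0, batch_scale=0.0, batch_loc=0.0,
                        seed=5, gene_means=means)
        data = simulate_splatter_like(cfg)
        profile = data.counts.mean(axis=0)
        # relative expression should follow the supplied means
        assert pearsonr(profile, means).statistic > 0.99


class TestTrajectories:
    def test_branch_count_validation(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(n_branches=2)

    def test_default_cell_counts(self):
        assert TrajectoryConfig(n_branches=3).n_cells == 10_500
        assert TrajectoryConfig(n_branches=5).n_cells == 11_000

    def test_branches_recoverable_by_nearest_centroid(self):
        cfg = TrajectoryConfig(n_branches=3, n_cells=900, n_genes=300,
                               seed=6)
        data = log1p_counts(simulate_trajectories(cfg))
        branch = data.factors.raw("branch")
        time = data.factors.raw("time")
        late = time > 0.5  # centroids from differentiated cells
        centroids = np.stack([data.X[late & (branch == b)].mean(axis=0)
                              for b in range(3)])
        test = late & (time > 0.6)
        d2 = ((data.X[test][:, None, :] - centroids[None]) ** 2).sum(axis=2)
        acc = (d2.argmin(axis=1) == branch[test]).mean()
        assert acc > 0.9

    def test_time_zero_collapses_to_root(self):
        def centroid_separation(time_range):
            cfg = TrajectoryConfig(n_branches=3, n_cells=600, n_genes=200,
                                   time_range=time_range, seed=7)
            data = log1p_counts(simulate_trajectories(cfg))
            branch = data.factors.raw("branch")
            centroids = np.stack([data.X[branch == b].mean(axis=0)
                                  for b in range(3)])
            return np.linalg.norm(centroids[0] - centroids[1])

        # at time 0 every branch expresses the root program: the residual
        # centroid separation is sampling noise, far below the separation
        # of differentiated cells
        assert centroid_separation((0.0, 0.0)) < \
            0.2 * centroid_separation((0.9, 1.0))


class TestFactorTableProperties:
    @given(values=arrays(np.float64, st.integers(8, 60),
                         elements=st.floats(-1e6, 1e6),
                         unique=True))
    @settings(max_examples=50, deadline=None)
    def test_quartile_binning_is_balanced(self, values):
        """Any continuous factor quartiles into 4 near-equal groups."""
        from michigan.data import CONTINUOUS, FactorTable

        ft = FactorTable(pd.DataFrame({"v": values}),
                         {"v": CONTINUOUS})
        binned = ft.binned("v")
        counts = np.bincount(binned, minlength=4)
        assert set(np.unique(binned)) <= {0, 1, 2, 3}
        assert counts.max() - counts.min() <= 1
        # binning respects order
        order = np.argsort(values)
        assert (np.diff(binned[order]) >= 0).all()


class TestNormalization:
    def test_all_zero_cell_dropped(self, caplog):
        X = np.array([[1, 2], [0, 0], [3, 4]])
        from michigan.data import ExpressionDataset, FactorTable
        import pandas as pd

        data = ExpressionDataset(X.astype(float), FactorTable(
            pd.DataFrame({"f": [0, 1, 0]})), counts=X)
        out = normalize_log1p(data)
        assert out.n_cells == 2

    def test_uniform_counts_give_log2(self):
        from michigan.data import ExpressionDataset, FactorTable
        import pandas as pd

        X = np.ones((4, 3))
        data = ExpressionDataset(X, FactorTable(
            pd.DataFrame({"f": [0, 1, 0, 1]})), counts=X.astype(int))
        out = normalize_log1p(data)
        assert np.allclose(out.X, np.log(2.0))

    def test_scaling_equalizes_totals(self, rng):
        from michigan.data import ExpressionDataset, FactorTable
        import pandas as pd

        counts = rng.integers(0, 20, size=(50, 20))
        counts[:, 0] += 1  # no all-zero cells
        data = ExpressionDataset(counts.astype(float), FactorTable(
            pd.DataFrame({"f": np.zeros(50)})), counts=counts)
        out = normalize_log1p(data)
        totals = (np.exp(out.X) - 1.0).sum(axis=1)
        assert np.allclose(totals, totals[0], rtol=1e-6)

    def test_log1p_keeps_library_signal(self, small_linear_dataset):
        lib = small_linear_dataset.factors.raw("library_size")
        assert abs(spearmanr(small_linear_dataset.X.sum(axis=1),
                             lib).statistic) > 0.95
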