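"""Disentanglement and generation metrics: oracles, bounds, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from michigan.data import (CATEGORICAL, CONTINUOUS, ExpressionDataset,
                           FactorTable, GaussianPosterior)
from michigan.metrics import (MetricReport, factorvae_metric,
                              inception_score, knn_infer_factors, mig,
                              normalized_mi, random_forest_error,
                              spearman_gap)

_LOG2PI = np.log(2.0 * np.pi)


def make_posterior(mean, var=None):
    mean = np.asarray(mean, float)
    if mean.ndim == 1:
        mean = mean[:, None]
    var = np.full_like(mean, 1e-4) if var is None else \
        np.broadcast_to(var, mean.shape).copy()
    return GaussianPosterior(mean, var)


class TestNormalizedMI:
    def test_independent_latent_has_zero_mi(self, rng):
        factor = np.repeat([0, 1, 2, 3], 100)
        post = make_posterior(rng.standard_normal(400), var=1.0)
        nmi = normalized_mi(post, factor, rng, n_samples=4000)
        assert nmi[0] == pytest.approx(0.0, abs=0.05)

    def test_deterministic_injective_latent_saturates(self, rng):
        factor = np.repeat([0, 1, 2, 3], 100)
        post = make_posterior(factor * 3.0, var=1e-6)
        nmi = normalized_mi(post, factor, rng, n_samples=4000)
        assert nmi[0] == pytest.approx(1.0, abs=0.02)

    def test_single_level_factor_rejected(self, rng):
        post = make_posterior(np.zeros(10))
        with pytest.raises(ValueError):
            normalized_mi(post, np.zeros(10), rng)

    def test_matches_quadrature_on_two_component_mixture(self, rng):
        """Estimator within 0.02 of numerically integrated MI for a
        balanced two-level factor with q(z|level) = N(+-1, 0.25)."""
        n = 400
        factor = np.repeat([0, 1], n // 2)
        mean = np.where(factor == 0, -1.0, 1.0)
        post = make_posterior(mean, var=0.25)

        def gauss(z, mu, var):
            return np.exp(-0.5 * (z - mu) ** 2 / var) / np.sqrt(
                2 * np.pi * var)

        def marg(z):
            return 0.5 * gauss(z, -1, 0.25) + 0.5 * gauss(z, 1, 0.25)

        # I = H(Z) - H(Z|V), computed by quadrature
        h_z = quad(lambda z: -marg(z) * np.log(marg(z)), -8, 8)[0]
        h_cond = 0.5 * np.log(2 * np.pi * np.e * 0.25)
        truth = (h_z - h_cond) / np.log(2)  # normalize by H(V) = log 2
        est = normalized_mi(post, factor, rng, n_samples=20_000)[0]
        assert est == pytest.approx(truth, abs=0.02)


class TestMIG:
    @staticmethod
    def factors_one():
        return FactorTable(pd.DataFrame(
            {"v": np.repeat([0, 1, 2, 3], 100)}), {"v": CATEGORICAL})

    def test_dedicated_latent_gives_high_mig(self, rng):
        f = self.factors_one()
        v = f.raw("v")
        mean = np.stack([v * 3.0, rng.standard_normal(400)], axis=1)
        var = np.stack([np.full(400, 1e-6), np.ones(400)], axis=1)
        post = GaussianPosterior(mean, var)
        assert mig(post, f, rng, n_samples=4000) > 0.9

    def test_duplicated_latent_contributes_zero_gap(self, rng):
        f = self.factors_one()
        v = f.raw("v").astype(float)
        mean = np.stack([v, v], axis=1)  # Z2 = Z1, tie
        post = GaussianPosterior(mean, np.full_like(mean, 1e-6))
        assert mig(post, f, rng, n_samples=4000) == pytest.approx(0.0,
                                                                  abs=0.03)

    def test_invariant_to_permutation_and_sign(self, rng):
        f = self.factors_one()
        v = f.raw("v").astype(float)
        mean = np.stack([v, rng.standard_normal(400),
                         0.3 * rng.standard_normal(400)], axis=1)
        var = np.full_like(mean, 0.01)
        base = mig(GaussianPosterior(mean, var), f,
                   np.random.default_rng(5), n_samples=4000)
        perm = mean[:, [2, 0, 1]] * np.array([1.0, -1.0, 1.0])
        flipped = mig(GaussianPosterior(perm, var[:, [2, 0, 1]]), f,
                      np.random.default_rng(5), n_samples=4000)
        assert flipped == pytest.approx(base, abs=0.03)


class TestFactorVAEMetric:
    class ToySampler:
        """Synthetic generator: K factors, each mapped to one data column
        (plus noise columns); admits factor clamping like the simulator."""

        def __init__(self, k=4, noise_cols=2, informative=True):
            self.k = k
            self.noise_cols = noise_cols
            self.informative = informative

        def __call__(self, n, rng, fixed=None):
            fixed = fixed or {}
            vals = {f"v{i}": (np.full(n, float(fixed[f"v{i}"]))
                              if f"v{i}" in fixed else
                              rng.standard_normal(n))
                    for i in range(self.k)}
            cols = [vals[f"v{i}"] for i in range(self.k)]
            cols += [rng.standard_normal(n)
                     for _ in range(self.noise_cols)]
            X = np.stack(cols, axis=1)
            table = pd.DataFrame(vals)
            kinds = {k: CONTINUOUS for k in table.columns}
            return ExpressionDataset(X, FactorTable(table, kinds))

        def factor_values(self, name, rng):
            return float(rng.standard_normal())

    def test_perfect_map_scores_near_one(self, rng):
        sampler = self.ToySampler()
        encode = lambda d: d.X[:, :4]  # identity on the informative columns
        acc = factorvae_metric(sampler, encode,
                               [f"v{i}" for i in range(4)], rng,
                               n_votes=200, batch_size=64, n_norm=500)
        assert acc > 0.95

    def test_random_latents_score_at_chance(self, rng):
        sampler = self.ToySampler()
        state = {"i": 0}

        def encode(d):
            state["i"] += 1
            return np.random.default_rng(state["i"]).standard_normal(
                (d.n_cells, 4))

        acc = factorvae_metric(sampler, encode,
                               [f"v{i}" for i in range(4)], rng,
                               n_votes=400, batch_size=64, n_norm=500)
        assert acc == pytest.approx(0.25, abs=0.12)

    def test_too_few_votes_rejected(self, rng):
        sampler = self.ToySampler(k=4)
        with pytest.raises(ValueError):
            factorvae_metric(sampler, lambda d: d.X, ["v0", "v1", "v2",
                                                      "v3"], rng, n_votes=2)


class TestSpearmanGap:
    def test_perfect_single_factor(self, rng):
        n = 500
        v = rng.standard_normal(n)
        Z = np.stack([v, rng.standard_normal(n),
                      rng.standard_normal(n)], axis=1)
        f = FactorTable(pd.DataFrame({"v": v}), {"v": CONTINUOUS})
        assert spearman_gap(Z, f) > 0.85

    def test_duplicated_dims_give_zero_gap(self, rng):
        v = rng.standard_normal(300)
        Z = np.stack([v, v], axis=1)
        f = FactorTable(pd.DataFrame({"v": v}), {"v": CONTINUOUS})
        assert spearman_gap(Z, f) == pytest.approx(0.0, abs=1e-12)

    def test_constant_dim_counts_as_zero_correlation(self, rng):
        v = rng.standard_normal(300)
        Z = np.stack([v, np.zeros(300)], axis=1)
        f = FactorTable(pd.DataFrame({"v": v}), {"v": CONTINUOUS})
        assert spearman_gap(Z, f) > 0.9

    def test_invariant_to_monotone_transform(self, rng):
        n = 400
        v = rng.standard_normal(n)
        Z = np.stack([v + 0.1 * rng.standard_normal(n),
                      rng.standard_normal(n)], axis=1)
        f = FactorTable(pd.DataFrame({"v": v}), {"v": CONTINUOUS})
        base = spearman_gap(Z, f)
        warped = np.stack([np.exp(Z[:, 0]), Z[:, 1] ** 3], axis=1)
        assert spearman_gap(warped, f) == pytest.approx(base, abs=1e-12)


class TestKNNInference:
    def test_copying_real_cells_recovers_factors(self, small_linear_dataset):
        data = small_linear_dataset
        inferred = knn_infer_factors(data, data.X[:100], k=1)
        for name in ("batch", "path"):
            assert np.array_equal(inferred.raw(name),
                                  data.factors.raw(name)[:100])

    def test_noise_input_gives_uncorrelated_factors(self,
                                                    small_linear_dataset):
        rng = np.random.default_rng(1)
        data = small_linear_dataset
        noise = rng.permuted(data.X[:200], axis=1)
        inferred = knn_infer_factors(data, noise, k=3)
        code = rng.standard_normal(200)
        from scipy.stats import spearmanr

        rho = abs(spearmanr(code, inferred.raw("step")).statistic)
        assert rho < 0.15

    def test_k_larger_than_reference_rejected(self, small_linear_dataset):
        with pytest.raises(ValueError):
            knn_infer_factors(small_linear_dataset,
                              small_linear_dataset.X[:5],
                              k=small_linear_dataset.n_cells + 1)


class TestRandomForestError:
    def test_real_vs_real_is_near_chance(self, small_linear_dataset, rng):
        X = small_linear_dataset.X
        idx = rng.permutation(X.shape[0])
        err = random_forest_error(X[idx[:300]], X[idx[300:]], seed=0,
                                  n_cells=300)
        assert 0.45 <= err <= 0.55

    def test_garbage_is_perfectly_separable(self, small_linear_dataset):
        X = small_linear_dataset.X
        err = random_forest_error(X[:300], np.zeros((300, X.shape[1])),
                                  seed=0, n_cells=300)
        assert err == pytest.approx(0.0, abs=0.02)


class TestInceptionScore:
    @staticmethod
    def toy_three_class(rng, n=600):
        labels = np.repeat([0, 1, 2], n // 3)
        centers = np.array([[0, 0], [8, 0], [0, 8]], float)
        X = centers[labels] + 0.3 * rng.standard_normal((n, 2))
        table = pd.DataFrame({"cls": labels})
        data = ExpressionDataset(X, FactorTable(table,
                                                {"cls": CATEGORICAL}))
        return data, labels

    def test_bounds_and_direct_summation(self, rng):
        data, labels = self.toy_three_class(rng)
        # confident generation covering all classes uniformly -> IS -> 3
        gen_all = data.X
        high = inception_score(data, labels, gen_all, seed=0, n_train=600)
        assert high == pytest.approx(3.0, abs=0.1)
        # mode collapse on one class -> IS -> 1 despite confident scores
        gen_one = data.X[labels == 0]
        low = inception_score(data, labels, gen_one, seed=0, n_train=600)
        assert low == pytest.approx(1.0, abs=0.1)
        # direct-summation oracle: recompute exp(mean KL to marginal)
        from sklearn.ensemble import RandomForestClassifier

        m = 600
        idx = np.random.default_rng(0).choice(600, size=m, replace=False)
        clf = RandomForestClassifier(n_estimators=100, random_state=0,
                                     n_jobs=1).fit(data.X[idx], labels[idx])
        p = np.clip(clf.predict_proba(gen_one), 1e-12, 1.0)
        p /= p.sum(axis=1, keepdims=True)
        marginal = p.mean(axis=0)
        kl = (p * (np.log(p) - np.log(marginal))).sum(axis=1).mean()
        assert low == pytest.approx(float(np.exp(kl)), rel=1e-9)

    def test_single_class_warns_and_returns_one(self, rng):
        data, labels = self.toy_three_class(rng)
        with pytest.warns(UserWarning):
            val = inception_score(data, np.zeros(600, dtype=int), data.X,
                                  seed=0)
        assert val == 1.0


class TestMetricReport:
    def test_replicate_summary(self):
        rep = MetricReport("mig", values=[0.5, 0.6, 0.7],
                           config={"d": 10})
        assert rep.mean == pytest.approx(0.6)
        assert rep.sd == pytest.approx(0.1)
        assert rep.n_runs == 3
        assert len(rep.config_hash) == 12
        assert "mig" in str(rep)
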