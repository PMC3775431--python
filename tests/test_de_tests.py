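import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln, xlogy
from scipy.stats import f as f_dist, kstest

from plasmodebench import de_tests
from plasmodebench.data_model import CountMatrix, DesignTable
from plasmodebench.de_tests import (
    ModelSpec,
    build_design_matrix,
    estimate_dispersion,
    f_statistics,
    fit_gaussian,
    fit_nb_glm,
    nb_lrt,
    permutation_pvalues,
    tabulated_pvalues,
)


def _cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"g{i+1}" for i in range(counts.shape[0])],
        [f"s{j+1}" for j in range(counts.shape[1])],
        counts,
    )


def _two_group_X(n):
    return np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])


def _nb_loglik_ref(y, mu, phi):
    """Independent NB log-likelihood used by the brute-force oracle."""
    if phi == 0:
        return float(np.sum(xlogy(y, mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + xlogy(y, phi * mu / (1 + phi * mu))
            - r * np.log1p(phi * mu)
        )
    )


class TestNBGLM:
    def test_intercept_only_saturated_at_mean(self):
        y = np.array([10, 10, 10, 10])
        fit = fit_nb_glm(y, np.ones((4, 1)), np.zeros(4), 0.0)
        np.testing.assert_allclose(fit.fitted, 10.0, rtol=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_poisson_two_group_closed_form(self, rng):
        y = rng.poisson(25, 8)
        fit = fit_nb_glm(y, _two_group_X(4), np.zeros(8), 0.0)
        np.testing.assert_allclose(fit.fitted[:4], y[:4].mean(), rtol=1e-8)
        np.testing.assert_allclose(fit.fitted[4:], y[4:].mean(), rtol=1e-8)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glm(np.array([1, 2]), np.ones((2, 1)), np.zeros(2), -0.1)

    def test_deviance_matches_brute_force_optimizer(self, rng):
        """IRLS deviance equals generic likelihood maximization on 20 random
        small instances (the optimizer is the independent oracle)."""
        X = _two_group_X(3)
        for i in range(20):
            phi = float(rng.uniform(0, 0.5))
            y = rng.poisson(rng.uniform(5, 50), 6).astype(float)
            offs = rng.normal(0, 0.1, 6)
            fit = fit_nb_glm(y, X, offs, phi)
            ll_irls = _nb_loglik_ref(y, fit.fitted, phi)

            def neg_ll(beta):
                mu = np.exp(np.clip(X @ beta + offs, -50, 50))
                return -_nb_loglik_ref(y, mu, phi)

            best = min(
                (
                    minimize(
                        neg_ll,
                        start,
                        method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                    )
                    for start in ([np.log(y.mean() + 0.5), 0.0], fit.coef)
                ),
                key=lambda r: r.fun,
            )
            # equal maximized likelihoods -> equal deviances
            assert ll_irls == pytest.approx(-best.fun, abs=1e-4)

    def test_phi_to_zero_matches_poisson_lrt(self, rng):
        y = rng.poisson(20, (15, 8))
        cm = _cm(y)
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 4 + ["b"] * 4}
            )
        )
        model = ModelSpec(("treatment",), ())
        offs = np.zeros(8)
        d0 = de_tests.DispersionEstimates(cm.gene_ids, np.zeros(15), "common")
        d_eps = de_tests.DispersionEstimates(cm.gene_ids, np.full(15, 1e-10), "common")
        s0 = nb_lrt(cm, model, design, offs, d0).statistic
        s1 = nb_lrt(cm, model, design, offs, d_eps).statistic
        np.testing.assert_allclose(s1, s0, atol=1e-6)

    def test_lrt_statistic_invariant_to_constant_offset_shift(self, rng):
        y = rng.poisson(30, (10, 6))
        cm = _cm(y)
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 3 + ["b"] * 3}
            )
        )
        model = ModelSpec(("treatment",), ())
        disp = de_tests.DispersionEstimates(cm.gene_ids, np.full(10, 0.1), "common")
        s1 = nb_lrt(cm, model, design, np.zeros(6), disp).statistic
        s2 = nb_lrt(cm, model, design, np.full(6, 2.5), disp).statistic
        np.testing.assert_allclose(s2, s1, atol=1e-7)

    def test_identical_group_means_give_null_result(self):
        cm = _cm(np.tile([[12, 12, 12, 12, 12, 12]], (3, 1)))
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 3 + ["b"] * 3}
            )
        )
        res = nb_lrt(
            cm,
            ModelSpec(("treatment",), ()),
            design,
            np.zeros(6),
            de_tests.DispersionEstimates(cm.gene_ids, np.zeros(3), "common"),
        )
        np.testing.assert_allclose(res.statistic, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.p_value, 1.0, atol=1e-8)


class TestDispersion:
    def test_common_phi_near_zero_for_poisson_data(self, rng):
        mu = rng.lognormal(3.5, 1.0, 400)
        y = rng.poisson(mu[:, None], (400, 20))
        cm = _cm(y)
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 10 + ["b"] * 10}
            )
        )
        d = estimate_dispersion(
            cm, ModelSpec(("treatment",), ()), design, np.zeros(20), "common"
        )
        assert d.phi[0] < 0.02

    def test_tagwise_recovers_shared_dispersion(self, rng):
        phi = 0.2
        mu = rng.lognormal(4, 1, 500)
        lam = rng.gamma(1 / phi, phi * mu[:, None], (500, 10))
        cm = _cm(rng.poisson(lam))
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 5 + ["b"] * 5}
            )
        )
        d = estimate_dispersion(
            cm, ModelSpec(("treatment",), ()), design, np.zeros(10), "tagwise_shrunk"
        )
        assert 0.12 < np.median(d.phi) < 0.28

    def test_trend_max_final_phi_at_least_trend(self, rng):
        mu = rng.lognormal(4, 1.5, 300)
        lam = rng.gamma(5.0, mu[:, None] / 5.0, (300, 8))
        cm = _cm(rng.poisson(lam))
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 4 + ["b"] * 4}
            )
        )
        d = estimate_dispersion(
            cm, ModelSpec(("treatment",), ()), design, np.zeros(8), "trend_max"
        )
        # recompute the moment estimates: the final value never drops below them
        q = cm.counts.astype(float)
        grp = [slice(0, 4), slice(4, 8)]
        s2 = sum(3 * q[:, g].var(axis=1, ddof=1) for g in grp) / 6
        ybar = q.mean(axis=1)
        phi_hat = np.maximum(0.0, (s2 - ybar) / ybar**2)
        assert np.all(d.phi >= phi_hat - 1e-12)

    def test_no_replication_errors(self):
        cm = _cm([[3, 4]])
        design = DesignTable(
            pd.DataFrame({"sample_id": cm.sample_ids, "treatment": ["a", "b"]})
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_dispersion(
                cm, ModelSpec(("treatment",), ()), design, np.zeros(2), "common"
            )


class TestGaussian:
    def test_hand_ols_two_groups_of_two(self):
        x = np.array([[1.0, 3.0, 2.0, 6.0]])
        Xf = _two_group_X(2)
        fit = fit_gaussian(x, Xf)
        np.testing.assert_allclose(fit.coef[0], [2.0, 2.0])  # means 2 and 4
        assert fit.rss[0] == pytest.approx(10.0)
        assert fit.df_resid == 2

    def test_f1_hand_value(self):
        # RSS_reduced = 14 about the grand mean 3, so F1 = (4/1)/(10/2) = 0.8
        x = np.array([[1.0, 3.0, 2.0, 6.0]])
        stats, df_num, df_res = f_statistics(x, _two_group_X(2), np.ones((4, 1)), "F1")
        assert (df_num, df_res) == (1, 2)
        assert stats[0] == pytest.approx(0.8)

    def test_adding_constant_changes_only_intercept(self, rng):
        x = rng.normal(size=(5, 6))
        Xf = _two_group_X(3)
        f1 = fit_gaussian(x, Xf)
        f2 = fit_gaussian(x + 7.0, Xf)
        np.testing.assert_allclose(f2.coef[:, 0], f1.coef[:, 0] + 7.0, atol=1e-10)
        np.testing.assert_allclose(f2.coef[:, 1:], f1.coef[:, 1:], atol=1e-10)
        np.testing.assert_allclose(f2.rss, f1.rss, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        x = rng.normal(size=(4, 8))
        Xf = _two_group_X(4)
        fit = fit_gaussian(x, Xf)
        resid = x - fit.coef @ Xf.T
        np.testing.assert_allclose(resid @ Xf, 0.0, atol=1e-10)

    def test_rank_deficient_design_errors(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="alias"):
            fit_gaussian(np.zeros((2, 4)), X)

    def test_fs_equals_f1_when_variances_identical(self):
        # same residual spread in every gene -> shrinkage is a no-op
        base = np.array([1.0, 3.0, 2.0, 6.0])
        x = np.vstack([base + c for c in (0.0, 5.0, -2.0, 11.0)])
        Xf, Xr = _two_group_X(2), np.ones((4, 1))
        f1, _, _ = f_statistics(x, Xf, Xr, "F1")
        fs, _, _ = f_statistics(x, Xf, Xr, "Fs")
        np.testing.assert_allclose(fs, f1, rtol=1e-12)

    def test_fs_equals_f1_at_three_genes(self, rng):
        x = rng.normal(size=(3, 6))
        Xf, Xr = _two_group_X(3), np.ones((6, 1))
        f1, _, _ = f_statistics(x, Xf, Xr, "F1")
        fs, _, _ = f_statistics(x, Xf, Xr, "Fs")
        np.testing.assert_allclose(fs, f1, rtol=1e-12)

    def test_fs_shrinks_extreme_variances_toward_center(self, rng):
        x = rng.normal(size=(100, 8))
        x[0] *= 20.0  # one very noisy gene
        Xf, Xr = _two_group_X(4), np.ones((8, 1))
        f1, _, _ = f_statistics(x, Xf, Xr, "F1")
        fs, _, _ = f_statistics(x, Xf, Xr, "Fs")
        assert not np.allclose(fs, f1)


class TestPValues:
    def test_zero_statistic_gives_p_one(self):
        rt = tabulated_pvalues(np.array([0.0]), 1, 4)
        assert rt.p_value[0] == pytest.approx(1.0)

    def test_f1_null_pvalues_uniform(self, rng):
        x = rng.normal(size=(3000, 8))
        Xf, Xr = _two_group_X(4), np.ones((8, 1))
        stats, dfn, dfd = f_statistics(x, Xf, Xr, "F1")
        p = tabulated_pvalues(stats, dfn, dfd).p_value
        assert kstest(p, "uniform").pvalue > 0.01

    def test_null_f1_median_matches_f_distribution(self, rng):
        x = rng.normal(size=(4000, 8))
        stats, dfn, dfd = f_statistics(x, _two_group_X(4), np.ones((8, 1)), "F1")
        assert np.median(stats) == pytest.approx(f_dist.median(dfn, dfd), rel=0.1)


class TestPermutation:
    @staticmethod
    def _f1_fn(data, labels):
        levels = list(dict.fromkeys(labels))
        X = np.column_stack(
            [np.ones(len(labels))]
            + [(np.asarray(labels) == l).astype(float) for l in levels[1:]]
        )
        s, _, _ = f_statistics(data, X, np.ones((len(labels), 1)), "F1")
        return s

    def test_two_vs_two_matches_exhaustive_enumeration(self):
        data = np.array([[1.0, 2.0, 10.0, 11.0]])
        labels = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="3 distinct"):
            rt = permutation_pvalues(
                self._f1_fn, data, labels, n_perm=100,
                rng=np.random.default_rng(0),
            )
        # oracle: enumerate the 3 unordered splits directly
        stats = []
        for combo in itertools.combinations(range(4), 2):
            lab = np.array(["b"] * 4, dtype=object)
            for c in combo:
                lab[c] = "a"
            stats.append(self._f1_fn(data, lab)[0])
        stats = sorted(set(np.round(stats, 12)))
        obs = self._f1_fn(data, labels)[0]
        expected = (1 + sum(s >= obs for s in stats)) / (1 + len(stats))
        assert rt.p_value[0] == pytest.approx(expected)
        assert len(stats) == 3

    def test_invariant_statistic_gives_p_one(self):
        data = np.array([[5.0, 5.0, 5.0, 5.0]])
        labels = np.array(["a", "a", "b", "b"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rt = permutation_pvalues(
                lambda d, l: np.array([1.0]), data, labels,
                rng=np.random.default_rng(0),
            )
        assert rt.p_value[0] == pytest.approx(1.0)

    def test_minimum_p_is_one_over_pool_plus_one(self, rng):
        data = rng.normal(size=(20, 6))
        data[0, 3:] += 100.0  # overwhelming effect for gene 1
        labels = np.array(["a"] * 3 + ["b"] * 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rt = permutation_pvalues(
                self._f1_fn, data, labels, n_perm=5, rng=rng
            )
        pool_size = 10 * 20  # 10 distinct splits x 20 genes
        assert rt.p_value.min() >= 1.0 / (1.0 + pool_size) - 1e-12
        assert np.all(rt.p_value > 0)

    def test_within_block_restriction_preserves_block_counts(self, rng):
        labels = np.array(["a", "a", "b", "b", "a", "b", "b", "b"])
        block = np.array(["x", "x", "x", "x", "y", "y", "y", "y"])
        seen = []

        def spy(data, lab):
            seen.append(np.array(lab))
            return np.zeros(1)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            permutation_pvalues(
                spy, np.zeros((1, 8)), labels, block=block, n_perm=50, rng=rng
            )
        for lab in seen:
            assert sorted(lab[:4]) == ["a", "a", "b", "b"]
            assert sorted(lab[4:]) == ["a", "b", "b", "b"]


class TestRunMethod:
    def test_unknown_tag_lists_valid_tags(self, small_dataset):
        cm, design = small_dataset
        with pytest.raises(ValueError, match="nb-lrt-tagwise"):
            de_tests.run_method(cm, design, "not-a-method")

    @pytest.mark.parametrize("tag", de_tests.METHOD_TAGS)
    def test_each_engine_produces_valid_results(self, tag, rng):
        mu = rng.lognormal(4, 1, 60)
        y = rng.poisson(mu[:, None], (60, 8))
        cm = _cm(y)
        design = DesignTable(
            pd.DataFrame(
                {"sample_id": cm.sample_ids, "treatment": ["a"] * 4 + ["b"] * 4}
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = de_tests.run_method(cm, design, tag, n_perm=20, rng=rng)
        assert res.method == tag
        ok = ~np.isnan(res.p_value)
        assert ok.sum() >= 55
        assert np.all((res.p_value[ok] >= 0) & (res.p_value[ok] <= 1))
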