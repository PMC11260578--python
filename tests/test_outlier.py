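import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from accessout import (
    ConfounderDesign,
    adjust_pvalues,
    build_latent,
    call_outliers,
    effect_sizes,
    fit_decoder,
    fit_dispersion,
    fit_encoder,
    init_decoder,
    nb_pvalues,
    run_epiout,
    sample_correlation,
    tune_bottleneck,
)
from accessout.metrics import auprc
from accessout.normalization import log_normalize
from accessout.outlier import (
    DISPERSION_BOUNDS,
    nb_logpmf,
    nb_loglik_per_region,
    outlier_score,
)


def nb_ll_oracle(k, mu, r):
    """Independent NB log-likelihood (direct formula, scalar loop)."""
    total = 0.0
    for ki, mi in zip(np.ravel(k), np.ravel(np.broadcast_to(mu, np.shape(k)))):
        total += (
            gammaln(ki + r) - gammaln(r) - gammaln(ki + 1)
            + r * np.log(r / (r + mi)) + ki * np.log(mi / (r + mi))
        )
    return total


class TestEncoder:
    def test_rank_one_direction(self, rng):
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 30))
        x = u @ v
        we = fit_encoder(x, 1)
        proj = (x @ we) @ we.T
        np.testing.assert_allclose(proj, x, atol=1e-10)

    def test_orthonormal_columns(self, rng):
        x = rng.normal(size=(25, 40))
        x -= x.mean(axis=0)
        we = fit_encoder(x, 6)
        np.testing.assert_allclose(we.T @ we, np.eye(6), atol=1e-10)

    def test_reconstruction_error_equals_discarded_eigenvalues(self, rng):
        x = rng.normal(size=(30, 50))
        x -= x.mean(axis=0)
        q = 4
        we = fit_encoder(x, q)
        err = np.linalg.norm(x - (x @ we) @ we.T) ** 2
        eigvals = np.sort(np.linalg.eigvalsh(x.T @ x))[::-1]
        np.testing.assert_allclose(err, eigvals[q:].sum(), rtol=1e-8)

    def test_q_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="bottleneck"):
            fit_encoder(rng.normal(size=(5, 10)), 5)


class TestLatentAndDecoderInit:
    def test_no_confounders(self, rng):
        x = rng.normal(size=(10, 20))
        we = fit_encoder(x, 3)
        np.testing.assert_array_equal(build_latent(x, we), x @ we)

    def test_constant_only_confounder(self, rng):
        x = rng.normal(size=(10, 20))
        we = fit_encoder(x, 3)
        design = ConfounderDesign.from_table(None, n_samples=10)
        h = build_latent(x, we, design)
        assert h.shape == (10, 4)
        np.testing.assert_array_equal(h[:, -1], 1.0)

    def test_shapes_with_confounders(self, rng):
        x = rng.normal(size=(12, 30))
        we = fit_encoder(x, 4)
        table = pd.DataFrame(
            {"batch": pd.Categorical(["a", "b", "c"] * 4), "age": rng.normal(size=12)}
        )
        design = ConfounderDesign.from_table(table)
        h = build_latent(x, we, design)
        # 4 latent + 2 batch dummies + 1 numeric + constant
        assert h.shape == (12, 8)

    def test_collinear_confounders_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            ConfounderDesign.from_table(table)

    def test_init_decoder_matches_closed_form(self, rng):
        h = rng.normal(size=(15, 4))
        x = rng.normal(size=(15, 1))
        w = init_decoder(h, x)
        closed = np.linalg.solve(h.T @ h, h.T @ x)
        np.testing.assert_allclose(w, closed, rtol=1e-8)

    def test_exact_linear_data_zero_residual(self, rng):
        h = rng.normal(size=(10, 3))
        w_true = rng.normal(size=(3, 7))
        x = h @ w_true
        w = init_decoder(h, x)
        np.testing.assert_allclose(h @ w, x, atol=1e-8)

    def test_extra_orthogonal_column_never_hurts(self, rng):
        h = rng.normal(size=(30, 3))
        x = rng.normal(size=(30, 5))
        rss1 = np.linalg.norm(x - h @ init_decoder(h, x)) ** 2
        extra = rng.normal(size=(30, 1))
        extra -= h @ np.linalg.lstsq(h, extra, rcond=None)[0]
        h2 = np.hstack([h, extra])
        rss2 = np.linalg.norm(x - h2 @ init_decoder(h2, x)) ** 2
        assert rss2 <= rss1 + 1e-9


class TestDispersion:
    def test_grid_oracle(self, rng):
        n, p = 40, 30
        mu = rng.uniform(20, 200, size=(1, p)) * np.ones((n, 1))
        r_true = rng.uniform(0.5, 50, size=p)
        k = rng.negative_binomial(r_true, r_true / (r_true + mu))
        fitted = fit_dispersion(k, mu)
        grid = np.exp(np.linspace(np.log(0.01), np.log(1000), 1000))
        for j in range(p):
            ll_fit = nb_logpmf(k[:, j], mu[:, j], fitted[j]).sum()
            ll_grid = max(
                nb_logpmf(k[:, j], mu[:, j], g).sum() for g in grid
            )
            assert ll_fit >= ll_grid - 1e-6

    def test_poisson_data_clamps_to_upper_bound(self, rng):
        k = rng.poisson(100, size=(200, 20))
        fitted = fit_dispersion(k, np.full_like(k, 100.0))
        assert fitted.max() <= DISPERSION_BOUNDS[1]
        assert fitted.max() == DISPERSION_BOUNDS[1]

    def test_parameter_recovery(self, rng):
        r_true = 5.0
        k = rng.negative_binomial(r_true, r_true / (r_true + 50.0), size=(500, 10))
        fitted = fit_dispersion(k, np.full_like(k, 50.0))
        assert np.all(np.abs(fitted - r_true) / r_true < 0.2)

    def test_bounds_always_respected(self, rng):
        k = rng.integers(0, 1000, size=(30, 15))
        mu = rng.uniform(1, 500, size=(30, 15))
        fitted = fit_dispersion(k, mu)
        assert np.all(fitted >= DISPERSION_BOUNDS[0])
        assert np.all(fitted <= DISPERSION_BOUNDS[1])


class TestDecoderFit:
    def _setup(self, rng, n=50, p=8, q=2):
        h = np.hstack([rng.normal(size=(n, q)), np.ones((n, 1))])
        w_true = rng.normal(scale=0.3, size=(q + 1, p))
        nbar = np.log(rng.uniform(50, 150, size=p))
        sf = rng.uniform(0.7, 1.4, size=n)
        mu = np.exp(h @ w_true + nbar) * sf[:, None]
        r = rng.uniform(5, 50, size=p)
        k = rng.negative_binomial(r, r / (r + mu))
        return h, k, r, sf, nbar, w_true

    def test_likelihood_never_decreases_per_region(self, rng):
        h, k, r, sf, nbar, _ = self._setup(rng)
        x = np.log((k + 1) / sf[:, None]) - nbar
        w0 = init_decoder(h, x)
        w1 = fit_decoder(h, k, r, sf, nbar, w_init=w0)
        from accessout.outlier import _expected_from_decoder

        ll0 = nb_loglik_per_region(k, _expected_from_decoder(h, w0, nbar, sf), r)
        ll1 = nb_loglik_per_region(k, _expected_from_decoder(h, w1, nbar, sf), r)
        assert np.all(ll1 >= ll0 - 1e-8)

    def test_noiseless_recovery(self, rng):
        h, _, r, sf, nbar, w_true = self._setup(rng)
        from accessout.outlier import _expected_from_decoder

        mu = _expected_from_decoder(h, w_true, nbar, sf)
        k = np.rint(mu)
        w0 = init_decoder(h, np.log((k + 1) / sf[:, None]) - nbar)
        w1 = fit_decoder(h, k, r, sf, nbar, w_init=w0)
        ll_true = nb_loglik_per_region(k, mu, r)
        ll_fit = nb_loglik_per_region(k, _expected_from_decoder(h, w1, nbar, sf), r)
        assert np.all(ll_fit >= ll_true - 1e-3)

    def test_two_parameter_grid_oracle(self, rng):
        # single region, single latent + intercept
        n = 60
        h = np.hstack([rng.normal(size=(n, 1)), np.ones((n, 1))])
        nbar = np.array([np.log(80.0)])
        sf = np.ones(n)
        mu = np.exp(h @ np.array([[0.4], [0.1]]) + nbar) * sf[:, None]
        r = np.array([10.0])
        k = rng.negative_binomial(r, r / (r + mu))
        w0 = init_decoder(h, np.log((k + 1)) - nbar)
        w1 = fit_decoder(h, k, r, sf, nbar, w_init=w0)
        from accessout.outlier import _expected_from_decoder

        ll_fit = nb_loglik_per_region(k, _expected_from_decoder(h, w1, nbar, sf), r)[0]
        best = -np.inf
        for a in np.linspace(-1.0, 1.5, 120):
            for b in np.linspace(-1.0, 1.0, 120):
                w = np.array([[a], [b]])
                ll = nb_loglik_per_region(
                    k, _expected_from_decoder(h, w, nbar, sf), r
                )[0]
                best = max(best, ll)
        assert ll_fit >= best - 1e-4


class TestNbPvalues:
    def test_closed_form_at_zero(self):
        # k=0, mu=100, r=1: F(0) = (1/101); doubled
        p = nb_pvalues(np.array([[0]]), np.array([[100.0]]), np.array([1.0]))
        np.testing.assert_allclose(p[0, 0], 2.0 / 101.0, rtol=1e-12)

    def test_median_capped_at_one(self):
        mu, r = 100.0, 10.0
        med = stats.nbinom.median(r, r / (r + mu))
        p = nb_pvalues(np.array([[med]]), np.array([[mu]]), np.array([r]))
        assert p[0, 0] == 1.0

    def test_literal_variant_capped_at_half(self, rng):
        k = rng.integers(0, 300, size=(5, 8))
        mu = rng.uniform(10, 200, size=(5, 8))
        r = rng.uniform(1, 100, size=8)
        p = nb_pvalues(k, mu, r, doubled=False)
        assert np.all(p <= 0.5 + 1e-12)
        np.testing.assert_allclose(
            nb_pvalues(k, mu, r), np.minimum(2 * p, 1.0), rtol=1e-12
        )

    def test_in_unit_interval(self, rng):
        k = rng.integers(0, 10_000, size=(10, 20))
        mu = rng.uniform(0.1, 500, size=(10, 20))
        r = rng.uniform(0.01, 1000, size=20)
        p = nb_pvalues(k, mu, r)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_null_calibration_small(self, rng):
        n = 20_000
        mu, r = 100.0, 10.0
        k = rng.negative_binomial(r, r / (r + mu), size=(1, n))
        p = nb_pvalues(k, np.full((1, n), mu), np.full(n, r))
        ks = stats.kstest(p.ravel(), "uniform").statistic
        assert ks < 0.07


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues(np.array([[0.037]])), [[0.037]])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_pvalues(np.ones((3, 5))), 1.0)

    def test_by_step_up_oracle(self, rng):
        p = rng.uniform(size=(1, 10))
        adj = adjust_pvalues(p)[0]
        # independent step-up enumeration
        m = 10
        cm = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p[0])
        raw = p[0][order] * m * cm / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, expected, rtol=1e-10)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=(4, 50))
        assert np.all(adjust_pvalues(p) >= p - 1e-15)

    def test_global_scope(self, rng):
        p = rng.uniform(size=(4, 50))
        adj = adjust_pvalues(p, scope="global")
        assert adj.shape == p.shape
        assert np.all(adj >= p - 1e-15)


class TestEffectSizes:
    def test_equal_counts_zero_l2fc(self):
        k = np.array([[10.0, 20.0], [30.0, 7.0]])
        l2fc, _ = effect_sizes(k, k)
        np.testing.assert_allclose(l2fc, 0.0)

    def test_direct_value(self):
        l2fc, _ = effect_sizes(np.array([[3.0], [3.0]]), np.array([[1.0], [1.0]]))
        np.testing.assert_allclose(l2fc, 1.0)

    def test_zscore_standardized(self, rng):
        k = rng.integers(0, 500, size=(30, 10))
        mu = rng.uniform(1, 300, size=(30, 10))
        _, z = effect_sizes(k, mu)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_region_zero_z_with_warning(self):
        k = np.full((5, 1), 10.0)
        with pytest.warns(UserWarning, match="zero fold-change variance"):
            _, z = effect_sizes(k, k)
        np.testing.assert_array_equal(z, 0.0)


class TestCallOutliers:
    def test_all_rules_pass(self):
        assert call_outliers(
            np.array([[0.04]]), np.array([[0.6]]), np.array([[60]]), np.array([[30.0]])
        )[0, 0]

    def test_count_rule_fails(self):
        assert not call_outliers(
            np.array([[0.04]]), np.array([[0.6]]), np.array([[10]]), np.array([[10.0]])
        )[0, 0]

    def test_alpha_boundary_strict(self):
        assert not call_outliers(
            np.array([[0.05]]), np.array([[0.6]]), np.array([[60]]), np.array([[60.0]])
        )[0, 0]

    def test_expected_count_can_satisfy_rule(self):
        assert call_outliers(
            np.array([[0.01]]), np.array([[-2.0]]), np.array([[1]]), np.array([[80.0]])
        )[0, 0]

    def test_monotone_in_alpha(self, rng):
        padj = rng.uniform(size=(6, 30))
        l2fc = rng.normal(scale=2, size=(6, 30))
        k = rng.integers(0, 200, size=(6, 30))
        mu = rng.uniform(1, 200, size=(6, 30))
        loose = call_outliers(padj, l2fc, k, mu, alpha=0.1)
        tight = call_outliers(padj, l2fc, k, mu, alpha=0.01)
        assert np.all(loose | ~tight)


class TestRunEpiout:
    def test_planted_outliers_ranked_high(self, planted_sim):
        cm, truth = planted_sim
        _, res = run_epiout(cm, q=5)
        truth_flat = (truth["mask"] != 0).ravel()
        assert truth_flat.sum() >= 20
        score = outlier_score(res.pvalue, res.zscore)
        assert auprc(truth_flat, score.ravel()) > 0.5

    def test_null_few_calls(self, small_sim):
        cm, _ = small_sim
        _, res = run_epiout(cm, q=5)
        assert res.is_outlier.mean() < 1e-3

    def test_deterministic(self, small_sim):
        cm, _ = small_sim
        _, r1 = run_epiout(cm, q=3)
        _, r2 = run_epiout(cm, q=3)
        np.testing.assert_array_equal(r1.pvalue, r2.pvalue)
        np.testing.assert_array_equal(r1.expected, r2.expected)

    def test_sample_permutation_equivariance(self, small_sim, rng):
        cm, _ = small_sim
        _, r1 = run_epiout(cm.counts, q=3)
        perm = rng.permutation(cm.counts.shape[0])
        _, r2 = run_epiout(cm.counts[perm], q=3)
        # equivariant up to floating summation-order noise amplified by the
        # iterative decoder fit
        np.testing.assert_allclose(r2.expected, r1.expected[perm], rtol=2e-2, atol=1.0)
        np.testing.assert_allclose(
            np.log(r2.pvalue), np.log(r1.pvalue[perm]), rtol=5e-2, atol=0.2
        )

    def test_result_invariants(self, small_sim):
        cm, _ = small_sim
        _, res = run_epiout(cm, q=4)
        assert np.all(res.pvalue > 0) and np.all(res.pvalue <= 1)
        assert np.all(res.padj >= res.pvalue - 1e-15)
        np.testing.assert_allclose(
            res.corrected, cm.counts - res.expected, rtol=1e-12
        )

    def test_anndata_round_trip(self, small_sim, tmp_path):
        import anndata as ad

        from accessout.outlier import result_from_anndata

        cm, _ = small_sim
        _, res = run_epiout(cm, q=3)
        path = str(tmp_path / "res.h5ad")
        res.to_anndata().write_h5ad(path)
        back = result_from_anndata(ad.read_h5ad(path))
        np.testing.assert_allclose(back.pvalue, res.pvalue)
        np.testing.assert_array_equal(back.is_outlier, res.is_outlier)


class TestTuneBottleneck:
    def test_single_candidate_returned(self, small_sim):
        cm, _ = small_sim
        assert tune_bottleneck(cm, None, [7], seed=0) == 7

    def test_recovers_true_rank(self, small_sim):
        cm, truth = small_sim
        assert truth["q_true"] == 5
        assert tune_bottleneck(cm, None, [2, 5, 20], seed=1) == 5

    def test_reproducible(self, small_sim):
        cm, _ = small_sim
        a = tune_bottleneck(cm, None, [2, 5], seed=3)
        b = tune_bottleneck(cm, None, [2, 5], seed=3)
        assert a == b


class TestSampleCorrelation:
    def test_duplicated_rows_correlate_fully(self, rng):
        row = rng.integers(0, 100, size=50)
        corr, _ = sample_correlation(np.vstack([row, row, rng.integers(0, 100, 50)]))
        np.testing.assert_allclose(corr[0, 1], 1.0)

    def test_symmetric_unit_diagonal(self, rng):
        k = rng.integers(0, 100, size=(6, 40))
        corr, _ = sample_correlation(k)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_constant_row_reported_missing(self, rng):
        k = np.vstack([np.full(20, 7), rng.integers(0, 50, size=(2, 20))])
        with pytest.warns(UserWarning, match="constant"):
            corr, mean_off = sample_correlation(k)
        assert np.isnan(corr[0, 1])
        assert np.isfinite(mean_off)

    def test_correction_decorrelates(self, small_sim):
        cm, _ = small_sim
        _, res = run_epiout(cm, q=5)
        _, before = sample_correlation(cm.counts)
        _, after = sample_correlation(cm.counts, res.expected)
        assert abs(after) < abs(before)
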