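import numpy as np
import pytest
from scipy import integrate, stats

from ndnet.ggm import (
    PosteriorDraws,
    PriorSpec,
    bayesian_r2,
    beta_from_draws,
    calibrated_aux_df,
    convergence_report,
    partial_from_precision,
    pool_imputations,
    sample_posterior,
    sample_prior,
)


def standardize(x):
    return (x - x.mean(0)) / x.std(0, ddof=1)


def draws_from_thetas(thetas, labels=None, n_chains=1):
    thetas = np.asarray(thetas, dtype=float)
    rho = np.empty_like(thetas)
    for k, th in enumerate(thetas):
        rho[k] = partial_from_precision(th)
    labels = labels or tuple(f"v{i}" for i in range(thetas.shape[1]))
    return PosteriorDraws(
        theta=thetas, rho=rho, labels=tuple(labels), prior=PriorSpec(0.2),
        n_chains=n_chains,
    )


class TestPriorSpec:
    def test_delta_mapping(self):
        assert PriorSpec(0.2).delta == pytest.approx(24.0)
        assert PriorSpec(0.1).delta == pytest.approx(99.0)
        assert PriorSpec(0.5).delta == pytest.approx(3.0)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0)
        with pytest.raises(ValueError):
            PriorSpec(1.2)

    def test_pdf_normalizes(self):
        prior = PriorSpec(0.3)
        total, _ = integrate.quad(prior.pdf, -1, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pdf_at_zero_matches_quadrature_pdf(self):
        prior = PriorSpec(0.2)
        assert prior.pdf_at_zero() == pytest.approx(float(prior.pdf(0.0)), rel=1e-12)

    def test_marginal_sampler_matches_scale(self):
        rng = np.random.default_rng(0)
        for s in (0.1, 0.2, 0.4):
            draws = PriorSpec(s).sample_marginal(200_000, rng)
            assert abs(draws.std() - s) < 0.005


class TestPriorCalibration:
    @pytest.mark.parametrize("scale", [0.1, 0.2, 0.4])
    def test_forward_prior_sd_matches_scale(self, scale):
        prior = PriorSpec(scale)
        draws = sample_prior(prior, p=13, n_draws=10_000, seed=31)
        sd = draws.rho[:, 0, 1].std()
        assert abs(sd - scale) < 0.015

    def test_aux_df_cached_and_positive(self):
        prior = PriorSpec(0.2)
        a = calibrated_aux_df(prior, 13)
        b = calibrated_aux_df(prior, 13)
        assert a == b
        assert a > 12  # must keep the auxiliary Wishart proper


class TestPartialFromPrecision:
    def test_diagonal_gives_identity(self):
        rho = partial_from_precision(np.diag([2.0, 5.0, 1.0]))
        np.testing.assert_allclose(rho, np.eye(3))

    def test_two_by_two_formula(self):
        rho = partial_from_precision(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert rho[0, 1] == pytest.approx(0.5)

    def test_matches_conditional_covariance_oracle(self):
        # independent path: partial corr = correlation of the 2x2 conditional
        # covariance (Schur complement of the implied covariance matrix)
        rng = np.random.default_rng(8)
        a = rng.normal(size=(5, 5))
        theta = a @ a.T + 5 * np.eye(5)
        sigma = np.linalg.inv(theta)
        rho = partial_from_precision(theta)
        for i, j in [(0, 1), (2, 4), (1, 3)]:
            rest = [k for k in range(5) if k not in (i, j)]
            s_ij = sigma[np.ix_([i, j], [i, j])]
            s_ir = sigma[np.ix_([i, j], rest)]
            s_rr = sigma[np.ix_(rest, rest)]
            cond = s_ij - s_ir @ np.linalg.solve(s_rr, s_ir.T)
            oracle = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
            assert abs(rho[i, j] - oracle) < 1e-12

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            partial_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            partial_from_precision(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestSamplePosterior:
    def test_null_bivariate_centered_at_zero(self):
        rng = np.random.default_rng(17)
        x = standardize(rng.normal(size=(5000, 2)))
        draws = sample_posterior(x, PriorSpec(0.2), n_draws=2000, seed=1, burn_in=300)
        assert abs(draws.rho[:, 0, 1].mean()) < 0.03

    def test_three_node_recovery(self):
        theta_true = np.array(
            [[1.0, -0.3, 0.0], [-0.3, 1.0, -0.25], [0.0, -0.25, 1.0]]
        )
        rho_true = partial_from_precision(theta_true)
        rng = np.random.default_rng(18)
        sigma = np.linalg.inv(theta_true)
        x = rng.multivariate_normal(np.zeros(3), sigma, size=5000)
        draws = sample_posterior(
            standardize(x), PriorSpec(0.2), n_draws=2000, seed=2, burn_in=300
        )
        err = np.abs(draws.rho.mean(0) - rho_true)
        assert err.max() < 0.04

    def test_requires_standardized_columns(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(100, 3)) * 3.0
        with pytest.raises(ValueError, match="standardized"):
            sample_posterior(x, PriorSpec(0.2), n_draws=600, seed=0)

    def test_requires_enough_rows(self):
        x = standardize(np.random.default_rng(0).normal(size=(8, 3)))
        with pytest.raises(ValueError, match="rows"):
            sample_posterior(x[:2], PriorSpec(0.2), n_draws=600, seed=0)

    def test_rejects_missing(self):
        x = standardize(np.random.default_rng(0).normal(size=(100, 3)))
        x[3, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            sample_posterior(x, PriorSpec(0.2), n_draws=600, seed=0)

    def test_determinism(self):
        rng = np.random.default_rng(20)
        x = standardize(rng.normal(size=(300, 3)))
        a = sample_posterior(x, PriorSpec(0.2), n_draws=600, seed=5, burn_in=100)
        b = sample_posterior(x, PriorSpec(0.2), n_draws=600, seed=5, burn_in=100)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_small_draw_warning(self, caplog):
        rng = np.random.default_rng(21)
        x = standardize(rng.normal(size=(200, 3)))
        with caplog.at_level("WARNING", logger="ndnet.ggm"):
            sample_posterior(x, PriorSpec(0.2), n_draws=400, seed=0, burn_in=50)
        assert any("small" in r.message for r in caplog.records)

    def test_posterior_consistency_error_shrinks_with_n(self, paper_like_net):
        rho_true = paper_like_net.partials
        sigma = np.linalg.inv(paper_like_net.precision)
        rng = np.random.default_rng(22)
        med_errs = []
        for n in (2000, 20000):
            x = rng.multivariate_normal(np.zeros(13), sigma, size=n)
            draws = sample_posterior(
                standardize(x), PriorSpec(0.2), n_draws=1200, seed=3, burn_in=300
            )
            err = np.abs(draws.rho.mean(0) - rho_true)[np.triu_indices(13, 1)]
            med_errs.append(np.median(err))
        assert med_errs[1] < med_errs[0]

    def test_permutation_equivariance(self):
        theta_true = np.array(
            [[1.0, -0.3, 0.0], [-0.3, 1.0, -0.25], [0.0, -0.25, 1.0]]
        )
        rng = np.random.default_rng(23)
        x = rng.multivariate_normal(np.zeros(3), np.linalg.inv(theta_true), size=4000)
        x = standardize(x)
        perm = [2, 0, 1]
        a = sample_posterior(x, PriorSpec(0.2), n_draws=2000, seed=4, burn_in=300)
        b = sample_posterior(x[:, perm], PriorSpec(0.2), n_draws=2000, seed=4, burn_in=300)
        mean_a = a.rho.mean(0)[np.ix_(perm, perm)]
        mean_b = b.rho.mean(0)
        assert np.abs(mean_a - mean_b).max() < 0.02

    def test_importance_sampling_oracle_three_nodes(self):
        # brute-force evaluation of the posterior mean at small n by
        # importance sampling: the auxiliary scale integrates out of the
        # hierarchical prior in closed form,
        #   p(Theta) propto |Theta|^((d1-p-1)/2) |I+Theta|^(-(d1+nu0)/2),
        # so weights against a Wishart proposal are exactly evaluable
        from ndnet.ggm import calibrated_aux_df

        prior = PriorSpec(0.2)
        p, n = 3, 30
        d1 = prior.delta + p - 1
        nu0 = calibrated_aux_df(prior, p)
        theta_true = np.array(
            [[1.0, -0.35, 0.0], [-0.35, 1.0, -0.3], [0.0, -0.3, 1.0]]
        )
        rng = np.random.default_rng(55)
        x = rng.multivariate_normal(np.zeros(p), np.linalg.inv(theta_true), size=n)
        x = standardize(x)
        s = x.T @ x

        draws = sample_posterior(x, prior, n_draws=20_000, seed=6, burn_in=1000)
        gibbs_mean = draws.rho.mean(0)

        df_q = n + d1
        scale_q = np.linalg.inv(s + nu0 * np.eye(p))
        thetas = stats.wishart.rvs(df_q, scale_q, size=100_000, random_state=rng)
        _, ld = np.linalg.slogdet(thetas)
        _, ld_shift = np.linalg.slogdet(np.eye(p)[None] + thetas)
        tr_s = np.einsum("kij,ji->k", thetas, s)
        tr = np.einsum("kii->k", thetas)
        log_target = (
            0.5 * (d1 - p - 1) * ld - 0.5 * (d1 + nu0) * ld_shift
            + 0.5 * n * ld - 0.5 * tr_s
        )
        log_q = 0.5 * (df_q - p - 1) * ld - 0.5 * (tr_s + nu0 * tr)
        logw = log_target - log_q
        logw -= logw.max()
        w = np.exp(logw)
        ess = w.sum() ** 2 / (w**2).sum()
        assert ess > 1000  # sanity: the oracle itself must be usable
        dvec = np.sqrt(np.einsum("kii->ki", thetas))
        rho = -thetas / (dvec[:, :, None] * dvec[:, None, :])
        is_mean = np.einsum("k,kij->ij", w, rho) / w.sum()
        assert np.abs(gibbs_mean - is_mean)[np.triu_indices(p, 1)].max() < 0.02


class TestPoolImputations:
    def test_single_dataset_identity(self):
        d = draws_from_thetas([np.eye(3)] * 4)
        assert pool_imputations([d]) is d

    def test_identical_copies_preserve_mean(self):
        thetas = [np.eye(3) + 0.1 * np.eye(3)] * 5
        d = draws_from_thetas(thetas)
        pooled = pool_imputations([d, d, d])
        np.testing.assert_allclose(pooled.rho.mean(0), d.rho.mean(0))
        assert pooled.n_draws_total == 3 * d.n_draws_total

    def test_two_dataset_mixture_mean(self):
        t1 = np.array([[1.0, -0.4], [-0.4, 1.0]])
        t2 = np.array([[1.0, -0.2], [-0.2, 1.0]])
        d1 = draws_from_thetas([t1] * 10)
        d2 = draws_from_thetas([t2] * 10)
        pooled = pool_imputations([d1, d2])
        expected = (d1.rho.mean(0) + d2.rho.mean(0)) / 2
        np.testing.assert_allclose(pooled.rho.mean(0), expected, atol=1e-12)

    def test_mismatched_dimensions_error(self):
        d1 = draws_from_thetas([np.eye(2)] * 3)
        d2 = draws_from_thetas([np.eye(3)] * 3)
        with pytest.raises(ValueError, match="mismatch|labels"):
            pool_imputations([d1, d2])

    def test_mismatched_counts_error(self):
        d1 = draws_from_thetas([np.eye(2)] * 3)
        d2 = draws_from_thetas([np.eye(2)] * 4)
        with pytest.raises(ValueError, match="counts"):
            pool_imputations([d1, d2])


class TestBetaFromDraws:
    def test_equal_diagonals_give_beta_equals_rho(self):
        theta = np.array([[2.0, -0.6], [-0.6, 2.0]])
        d = draws_from_thetas([theta])
        b = beta_from_draws(d)
        assert b.beta[0, 0, 1] == pytest.approx(d.rho[0, 0, 1])

    def test_beta_ratio_identity(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(4, 4))
        theta = a @ a.T + 4 * np.eye(4)
        d = draws_from_thetas([theta])
        b = beta_from_draws(d).beta[0]
        for i in range(4):
            for j in range(i + 1, 4):
                assert b[i, j] / b[j, i] == pytest.approx(
                    theta[j, j] / theta[i, i], abs=1e-10
                )

    def test_posterior_mean_beta_matches_regression_oracle(self):
        # 4-variable standardized system: beta must match the coefficient of
        # node j in the all-others OLS regression for node i, from Sigma
        theta_true = np.array(
            [
                [1.0, -0.3, 0.0, -0.15],
                [-0.3, 1.0, -0.2, 0.0],
                [0.0, -0.2, 1.0, -0.25],
                [-0.15, 0.0, -0.25, 1.0],
            ]
        )
        sigma = np.linalg.inv(theta_true)
        dvec = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(dvec, dvec)
        theta_star = np.linalg.inv(corr)
        rng = np.random.default_rng(10)
        x = rng.multivariate_normal(np.zeros(4), corr, size=10_000)
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        draws = sample_posterior(x, PriorSpec(0.2), n_draws=2000, seed=8, burn_in=300)
        beta_mean = beta_from_draws(draws).beta.mean(0)
        for i in range(4):
            rest = [k for k in range(4) if k != i]
            coefs = np.linalg.solve(corr[np.ix_(rest, rest)], corr[np.ix_(rest, [i])])
            for pos, j in enumerate(rest):
                oracle = coefs[pos, 0]  # equals -theta*_ij / theta*_ii
                assert abs(beta_mean[i, j] - oracle) < 0.03
                assert abs(-theta_star[i, j] / theta_star[i, i] - oracle) < 1e-12


class TestBayesianR2:
    def test_diagonal_theta_gives_zero(self):
        d = draws_from_thetas([np.eye(3)] * 5)
        res = bayesian_r2(d, "v0")
        assert res.r2_mean == 0.0
        assert res.r2_cri == (0.0, 0.0)

    def test_two_node_matches_r_squared(self):
        r = 0.5
        rng = np.random.default_rng(11)
        x = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=8000)
        x = standardize(x)
        draws = sample_posterior(x, PriorSpec(0.2), n_draws=2000, seed=9, burn_in=300)
        res = bayesian_r2(draws, "v0")
        assert abs(res.r2_mean - r**2) < 0.03

    def test_cri_ordered_and_in_unit_interval(self):
        rng = np.random.default_rng(12)
        x = standardize(rng.normal(size=(500, 3)))
        draws = sample_posterior(x, PriorSpec(0.2), n_draws=1000, seed=10, burn_in=200)
        for node in draws.labels:
            res = bayesian_r2(draws, node)
            lo, hi = res.r2_cri
            assert 0 <= lo <= hi < 1
            assert lo <= res.r2_mean <= hi


class TestConvergence:
    def test_white_noise_rhat_near_one(self):
        rng = np.random.default_rng(13)
        thetas = np.tile(np.eye(3), (4000, 1, 1))
        thetas[:, 0, 1] = thetas[:, 1, 0] = rng.normal(scale=0.05, size=4000)
        thetas[:, 0, 0] = thetas[:, 1, 1] = 1.0
        d = draws_from_thetas(thetas, n_chains=2)
        rep = convergence_report(d, edges=[("v0", "v1")])
        val = rep.rhat[("v0", "v1")]
        assert 1.0 <= val <= 1.02
        assert not rep.flagged

    def test_linear_trend_flagged(self):
        thetas = np.tile(np.eye(3), (2000, 1, 1))
        drift = np.linspace(-0.4, 0.4, 2000)
        thetas[:, 0, 1] = thetas[:, 1, 0] = drift
        d = draws_from_thetas(thetas, n_chains=2)
        rep = convergence_report(d, edges=[("v0", "v1")])
        assert ("v0", "v1") in rep.flagged

    def test_trace_export_writes_one_file_per_edge(self, tmp_path):
        rng = np.random.default_rng(14)
        thetas = np.tile(np.eye(3), (400, 1, 1))
        thetas[:, 0, 1] = thetas[:, 1, 0] = rng.normal(scale=0.02, size=400)
        d = draws_from_thetas(thetas, n_chains=2)
        edges = [("v0", "v1"), ("v0", "v2")]
        convergence_report(d, edges=edges, outdir=tmp_path)
        files = sorted(f.name for f in tmp_path.iterdir())
        assert files == ["trace_v0__v1.png", "trace_v0__v2.png"]
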