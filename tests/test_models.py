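"""Gibbs engine vs closed-form oracles, the five models, posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from menvgp import (
    MCMCConfig,
    KernelTerm,
    blup_closed_form,
    fit_gblup_single_env,
    fit_gxc,
    fit_mtm,
    fit_mxe,
    genetic_correlations,
    gibbs_multikernel,
    heritability,
    variance_proportions,
)
from menvgp.models import build_gxc_terms, build_mxe_terms, mxe_ridge_blup, stack_records


def _psd_kernel(n, p, seed):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, p))
    W -= W.mean(axis=0)
    return W @ W.T / p, W


SHORT = MCMCConfig(n_iter=1500, burn_in=500, thin=1, seed=0)


class TestEngine:
    def test_intercept_only_constant_data(self):
        fit = gibbs_multikernel(np.array([3.0, 3.0, 3.0]), [],
                                MCMCConfig(n_iter=600, burn_in=100, thin=1, seed=1))
        assert fit.beta_samples.mean() == pytest.approx(3.0, abs=0.05)
        assert fit.fitted_mean == pytest.approx(3.0, abs=0.05)

    def test_fixed_variance_posterior_matches_closed_form_blup(self):
        K, _ = _psd_kernel(40, 60, 2)
        rng = np.random.default_rng(3)
        y = rng.multivariate_normal(np.zeros(40), K + 0.5 * np.eye(40))
        term = KernelTerm("g", kernel=K)
        mcmc = MCMCConfig(n_iter=5000, burn_in=1000, thin=1, seed=4)
        fit = gibbs_multikernel(y, [term], mcmc,
                                fixed_variances={"g": 1.0, "residual": 0.5})
        oracle = blup_closed_form(y, [KernelTerm("g", kernel=K)], {"g": 1.0}, 0.5)
        g_mc, g_cf = fit.effect_means["g"], oracle["effects"]["g"]
        assert np.corrcoef(g_mc, g_cf)[0, 1] > 0.999
        assert np.abs(g_mc - g_cf).max() < 0.02 * y.std()

    def test_same_seed_identical_chains(self):
        K, _ = _psd_kernel(20, 30, 5)
        y = np.random.default_rng(6).standard_normal(20)
        fits = [gibbs_multikernel(y, [KernelTerm("g", kernel=K)], SHORT)
                for _ in range(2)]
        np.testing.assert_array_equal(fits[0].varcomp_samples["g"],
                                      fits[1].varcomp_samples["g"])
        np.testing.assert_array_equal(fits[0].fitted_mean, fits[1].fitted_mean)

    def test_sample_count_follows_chain_settings(self):
        K, _ = _psd_kernel(10, 15, 7)
        y = np.random.default_rng(8).standard_normal(10)
        mcmc = MCMCConfig(n_iter=1000, burn_in=400, thin=3, seed=9)
        fit = gibbs_multikernel(y, [KernelTerm("g", kernel=K)], mcmc)
        assert fit.n_samples == (1000 - 400) // 3
        assert all((v >= 0).all() for v in fit.varcomp_samples.values())

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            gibbs_multikernel(np.array([1.0, 2.0]),
                              [KernelTerm("g", kernel=bad)], SHORT)

    def test_degenerate_phenotypes_rejected(self):
        K, _ = _psd_kernel(5, 8, 10)
        with pytest.raises(ValueError, match="zero variance"):
            gibbs_multikernel(np.full(5, 2.0), [KernelTerm("g", kernel=K)], SHORT)


class TestClosedFormBLUP:
    def test_identity_kernel_ridge_shrinks_by_half(self):
        # sigma2_g = sigma2_e and K = I: BLUP = deviations / 2
        y = np.array([1.0, 3.0, 5.0, 7.0])
        out = blup_closed_form(y, [KernelTerm("g", kernel=np.eye(4))],
                               {"g": 1.0}, 1.0)
        dev = y - y.mean()
        # intercept is GLS, equal to the mean here
        np.testing.assert_allclose(out["effects"]["g"], dev / 2.0, atol=1e-10)

    def test_infinite_signal_variance_interpolates(self):
        K, _ = _psd_kernel(15, 30, 11)
        y = np.random.default_rng(12).standard_normal(15)
        out = blup_closed_form(y, [KernelTerm("g", kernel=K)], {"g": 1e8}, 1.0)
        np.testing.assert_allclose(out["fitted"], y, atol=1e-4)

    def test_two_orthogonal_kernels_match_backfitting(self):
        # joint Henderson solution equals the fixed point of iterated
        # single-kernel fits when the kernels act on orthogonal subspaces
        n = 12
        P1 = np.zeros((n, n)); P1[:6, :6] = np.eye(6)
        P2 = np.zeros((n, n)); P2[6:, 6:] = np.eye(6)
        y = np.random.default_rng(13).standard_normal(n)
        terms = [KernelTerm("a", kernel=P1), KernelTerm("b", kernel=P2)]
        joint = blup_closed_form(y, terms, {"a": 2.0, "b": 0.7}, 1.0)
        # backfitting oracle
        X = np.ones((n, 1))
        u_a, u_b = np.zeros(n), np.zeros(n)
        beta = 0.0
        for _ in range(200):
            beta = np.mean(y - u_a - u_b)
            r_a = y - beta - u_b
            u_a = 2.0 * P1 @ np.linalg.solve(2.0 * P1 + np.eye(n), r_a)
            r_b = y - beta - u_a
            u_b = 0.7 * P2 @ np.linalg.solve(0.7 * P2 + np.eye(n), r_b)
        np.testing.assert_allclose(joint["effects"]["a"], u_a, atol=1e-8)
        np.testing.assert_allclose(joint["effects"]["b"], u_b, atol=1e-8)

    def test_variances_must_be_positive(self):
        with pytest.raises(ValueError):
            blup_closed_form(np.ones(3), [KernelTerm("g", kernel=np.eye(3))],
                             {"g": 0.0}, 1.0)


class TestSingleEnvGBLUP:
    def test_noise_free_signal_gives_high_heritability(self):
        # markers < lines: K has a null space, so residual and genetic
        # variance separate cleanly and h2 approaches 1 without noise
        K, _ = _psd_kernel(120, 60, 2)
        rng = np.random.default_rng(3)
        u = rng.multivariate_normal(np.zeros(120), K)
        y = pd.Series(u + rng.normal(0, 0.05, 120),
                      index=[f"L{i}" for i in range(120)])
        fit = fit_gblup_single_env(y, K, SHORT)
        assert heritability(fit) > 0.9

    def test_heritability_recovery_at_half(self, recovery_data):
        fit = fit_gblup_single_env(recovery_data["Y"]["E1"],
                                   recovery_data["K"], SHORT)
        assert heritability(fit) == pytest.approx(0.5, abs=0.1)

    def test_relabeling_invariance(self):
        K, _ = _psd_kernel(60, 200, 16)
        rng = np.random.default_rng(17)
        y = pd.Series(rng.multivariate_normal(np.zeros(60), K + np.eye(60)),
                      index=[f"L{i:02d}" for i in range(60)])
        mcmc = MCMCConfig(n_iter=3000, burn_in=1000, thin=1, seed=18)
        fit0 = fit_gblup_single_env(y, K, mcmc)
        perm = rng.permutation(60)
        from menvgp import GRM
        Kp = GRM(y.index.to_numpy()[perm], K[np.ix_(perm, perm)])
        fitp = fit_gblup_single_env(y.iloc[perm], Kp, mcmc)
        g0 = pd.Series(fit0.effect_means["g"], index=y.index)
        gp = pd.Series(fitp.effect_means["g"], index=y.index[perm])
        assert np.corrcoef(g0, gp[g0.index])[0, 1] > 0.98


class TestGxC:
    def test_same_env_hadamard_block_structure(self):
        # [Zg K Zg'] o [ZE ZE'] is block-diagonal by environment with K blocks
        K, _ = _psd_kernel(6, 10, 19)
        vals = pd.DataFrame(np.zeros((6, 2)), index=[f"L{i}" for i in range(6)],
                            columns=["a", "b"])
        terms = {t.label: t for t in build_gxc_terms(vals, K, np.eye(2))}
        full = terms["gE"].full_kernel()
        np.testing.assert_allclose(full[:6, :6], K, atol=1e-12)
        np.testing.assert_allclose(full[6:, 6:], K, atol=1e-12)
        np.testing.assert_allclose(full[:6, 6:], 0.0, atol=1e-12)

    def test_zero_gxe_concentrates_interaction_near_zero(self):
        # perfectly correlated environments: no genotype-by-environment
        # interaction variance to pick up
        K, _ = _psd_kernel(150, 600, 20)
        rng = np.random.default_rng(21)
        u = rng.multivariate_normal(np.zeros(150), K)
        Y = pd.DataFrame(
            {e: u + rng.normal(0, 0.7, 150) for e in ["a", "b", "c"]},
            index=[f"L{i}" for i in range(150)],
        )
        Om = np.eye(3) - 1 / 3  # any centered env kernel
        fit = fit_gxc(Y, K, Om + np.eye(3) * 1e-6, SHORT)
        means = fit.varcomp_means
        assert means["gE"] < 0.25 * means["g"]

    def test_variance_proportions_sum_to_one(self, recovery_data):
        fit = fit_gxc(recovery_data["Y"], recovery_data["K"],
                      np.eye(4) - 0.25 + np.eye(4) * 1e-6, SHORT)
        assert variance_proportions(fit).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_environment_rejected(self):
        from menvgp import EnvKernel
        K, _ = _psd_kernel(5, 8, 22)
        vals = pd.DataFrame(np.zeros((5, 2)), columns=["a", "zz"])
        Om = EnvKernel(np.array(["a", "b"]), np.eye(2))
        with pytest.raises(ValueError, match="absent"):
            build_gxc_terms(vals, K, Om)


class TestMxE:
    def test_parameterizations_agree_at_matched_variances(self):
        # marker-effect ridge and kernel GBLUP forms of the model are the
        # same model: predictions coincide at sigma2_u = p * sigma2_b
        rng = np.random.default_rng(23)
        n, p, J = 30, 50, 3
        D = 2.0 * (rng.random((n, p)) < rng.uniform(0.1, 0.5, p))
        W = (D - D.mean(0)) / D.std(0)
        K = W @ W.T / p
        vals = pd.DataFrame(rng.standard_normal((n, J)),
                            index=[f"L{i}" for i in range(n)],
                            columns=list("abc"))
        y, frame = stack_records(vals)
        s2b0, s2bj, s2e = 0.01, 0.005, 0.3
        ridge = mxe_ridge_blup(y, np.tile(W, (J, 1)), frame["env"].to_numpy(),
                               s2b0, s2bj, s2e)
        terms = build_mxe_terms(vals, K)
        variances = {"main": p * s2b0}
        variances.update({t.label: p * s2bj for t in terms[1:]})
        X = np.kron(np.eye(J), np.ones((n, 1)))
        gblup = blup_closed_form(y, terms, variances, s2e, X=X)
        np.testing.assert_allclose(ridge["fitted"], gblup["fitted"], atol=1e-6)

    def test_perfectly_correlated_envs_shrink_specific_variances(self):
        K, _ = _psd_kernel(120, 500, 24)
        rng = np.random.default_rng(25)
        u = rng.multivariate_normal(np.zeros(120), K)
        Y = pd.DataFrame({e: u + rng.normal(0, 0.6, 120) for e in "abc"},
                         index=[f"L{i}" for i in range(120)])
        fit = fit_mxe(Y, K, SHORT)
        props = variance_proportions(fit)
        assert props["main"] > 2 * props["specific"]

    def test_single_environment_rejected(self):
        K, _ = _psd_kernel(10, 20, 26)
        vals = pd.DataFrame(np.zeros((10, 1)), columns=["only"])
        with pytest.raises(ValueError, match="two environments"):
            fit_mxe(vals, K, SHORT)

    def test_ridge_parameterization_not_sampled(self):
        K, _ = _psd_kernel(10, 20, 27)
        vals = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="gblup"):
            fit_mxe(vals, K, SHORT, parameterization="ridge")


class TestMTM:
    def test_single_trait_degenerates_to_gblup(self):
        K, _ = _psd_kernel(150, 60, 28)
        rng = np.random.default_rng(29)
        u = rng.multivariate_normal(np.zeros(150), K)
        y = pd.Series(u + rng.normal(0, 1.0, 150),
                      index=[f"L{i}" for i in range(150)])
        mcmc = MCMCConfig(n_iter=4000, burn_in=1500, thin=1, seed=30)
        gb = fit_gblup_single_env(y, K, mcmc)
        mt = fit_mtm(y.to_frame("E1"), K, mcmc)
        h2_gb = heritability(gb)
        h2_mt = float(heritability(mt).iloc[0])
        assert h2_mt == pytest.approx(h2_gb, abs=0.08)

    def test_genetic_correlation_recovery(self, recovery_data):
        mcmc = MCMCConfig(n_iter=4000, burn_in=1500, thin=2, seed=0)
        fit = fit_mtm(recovery_data["Y"], recovery_data["K"], mcmc)
        corr = genetic_correlations(fit)
        off = corr.to_numpy()[np.triu_indices(4, 1)]
        assert abs(off.mean() - 0.8) < 0.15
        assert np.all(np.abs(off - 0.8) < 0.25)

    def test_duplicated_environment_detected_as_perfect_correlation(self):
        K, _ = _psd_kernel(100, 400, 31)
        rng = np.random.default_rng(32)
        u = rng.multivariate_normal(np.zeros(100), K)
        y = u + rng.normal(0, 0.5, 100)
        Y = pd.DataFrame({"a": y, "b": y}, index=[f"L{i}" for i in range(100)])
        fit = fit_mtm(Y, K, SHORT)
        corr = genetic_correlations(fit)
        assert corr.loc["a", "b"] > 0.95

    def test_correlation_matrix_properties(self, recovery_data):
        fit = fit_mtm(recovery_data["Y"], recovery_data["K"], SHORT)
        corr = genetic_correlations(fit).to_numpy()
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)

    def test_mtm2_with_suppressed_extra_component_matches_mtm1(self, recovery_data):
        Y, K = recovery_data["Y"], recovery_data["K"]
        m1 = fit_mtm(Y, K, SHORT, extra_component=False)
        m2 = fit_mtm(Y, K, SHORT, extra_component=True)
        # the extra line-level component competes with the residual; total
        # non-marker variance should agree between the two models
        res1 = m1.varcomp_means["residual"]
        res2 = m2.varcomp_means["residual"]
        extra2 = np.mean([v for k, v in m2.varcomp_means.items()
                          if k.startswith("extra_")])
        assert res2 + extra2 == pytest.approx(res1, rel=0.3)


class TestSummaries:
    def test_heritability_limits_under_fixed_variances(self):
        K = np.eye(30)
        y = np.random.default_rng(33).standard_normal(30)
        term = KernelTerm("g", kernel=K)
        f_hi = gibbs_multikernel(y, [term], SHORT,
                                 fixed_variances={"g": 1.0, "residual": 1e-12})
        f_lo = gibbs_multikernel(y, [KernelTerm("g", kernel=K)], SHORT,
                                 fixed_variances={"g": 1e-12, "residual": 1.0})
        assert heritability(f_hi) == pytest.approx(1.0, abs=1e-6)
        assert heritability(f_lo) == pytest.approx(0.0, abs=1e-6)

    def test_pure_noise_dominated_by_residual(self):
        K, _ = _psd_kernel(100, 50, 34)
        rng = np.random.default_rng(35)
        Y = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"),
                         index=[f"L{i}" for i in range(100)])
        fit = fit_mxe(Y, K, MCMCConfig(n_iter=3000, burn_in=1000, thin=1, seed=0))
        props = variance_proportions(fit)
        assert props.idxmax() == "residual"
        assert props["residual"] > 0.6
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
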