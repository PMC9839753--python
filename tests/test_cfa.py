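import numpy as np
import pytest

import latentdomains as ld


def two_factor_pattern(p_per=3, covs_free=True):
    mask = np.zeros((2 * p_per, 2), bool)
    mask[:p_per, 0] = True
    mask[p_per:, 1] = True
    names = [f"v{i}" for i in range(2 * p_per)]
    return ld.CfaPattern(free_mask=mask, variable_names=names, factor_covs_free=covs_free)


class TestPattern:
    def test_threshold_application(self):
        L = np.array([[0.46, 0.0], [0.44, 0.0], [0.5, 0.1], [0.0, 0.6], [0.2, -0.7], [0.1, 0.5]])
        sol = ld.FactorSolution(
            loadings=L, uniquenesses=np.full(6, 0.5), n_factors=2, rotated=True,
            variable_names=[f"v{i}" for i in range(6)],
        )
        pat = ld.pattern_from_efa(sol, threshold=0.45)
        assert pat.free_mask[0, 0] and not np.isin("v1", pat.variable_names)
        assert pat.dropped_variables == ["v1"]

    def test_free_parameter_count_by_enumeration(self):
        pat = two_factor_pattern(3)
        # 6 free loadings + 6 residuals + 1 factor covariance
        assert pat.n_free_parameters == 13
        assert pat.degrees_of_freedom() == 21 - 13  # == 8
        pat_orth = two_factor_pattern(3, covs_free=False)
        assert pat_orth.degrees_of_freedom() == 9

    def test_underidentified_factor_warns(self):
        L = np.array([[0.6, 0.0], [0.6, 0.0], [0.6, 0.0], [0.0, 0.6]])
        sol = ld.FactorSolution(
            loadings=L, uniquenesses=np.full(4, 0.5), n_factors=2, rotated=True,
            variable_names=list("abcd"),
        )
        with pytest.warns(UserWarning, match="fewer than 2 indicators"):
            ld.pattern_from_efa(sol, threshold=0.45)


class TestFitCfa:
    def test_true_model_recovery_with_standard_errors(self):
        L = ld.block_loadings(2, 4, 0.7)
        spec = ld.SyntheticSpec(2000, L, 1 - (L**2).sum(1), seed=13)
        table, _ = ld.generate_factor_data(spec)
        S = np.corrcoef(table.values.to_numpy(), rowvar=False)
        mask = L != 0
        pat = ld.CfaPattern(free_mask=mask, variable_names=table.variables)
        fit = ld.fit_cfa(S, pat, n_obs=2000, compute_se=True)
        assert fit.converged
        assert fit.fmin < 0.05
        est = fit.loadings[mask]
        se = fit.standard_errors[: mask.sum()]
        true = spec.loadings[mask]
        assert np.all(np.abs(est - true) < 2.5 * se)

    def test_df_arithmetic(self):
        pat = two_factor_pattern(3)
        L = ld.block_loadings(2, 3, 0.7)
        Sigma = L @ L.T + np.diag(1 - (L**2).sum(1))
        fit = ld.fit_cfa(Sigma, pat, n_obs=500)
        assert fit.df == 8
        assert fit.df == 6 * 7 // 2 - pat.n_free_parameters

    def test_exact_population_input_fits_perfectly(self):
        L = ld.block_loadings(2, 4, 0.7)
        Sigma = L @ L.T + np.diag(1 - (L**2).sum(1))
        pat = ld.CfaPattern(free_mask=L != 0, variable_names=[f"v{i}" for i in range(8)])
        fit = ld.fit_cfa(Sigma, pat, n_obs=600)
        assert fit.fmin < 1e-9
        assert fit.cfi == pytest.approx(1.0)
        assert fit.rmsea == pytest.approx(0.0)
        assert fit.srmr < 1e-5

    def test_not_improvable_by_independent_optimizer(self):
        from scipy import optimize
        from latentdomains.cfa import _fml_and_grad

        rng = np.random.default_rng(14)
        L = ld.block_loadings(2, 3, 0.7)
        X = rng.standard_normal((300, 2)) @ L.T + rng.standard_normal((300, 6)) * 0.7
        S = np.corrcoef(X, rowvar=False)
        pat = two_factor_pattern(3)
        fit = ld.fit_cfa(S, pat, n_obs=300)
        theta = np.concatenate(
            [fit.loadings[pat.free_mask], [fit.factor_cov[0, 1]], np.log(fit.residual_variances)]
        )
        sgn, logdet = np.linalg.slogdet(S)
        res = optimize.minimize(
            lambda t: _fml_and_grad(t, S, pat, logdet)[0],
            theta,
            method="Nelder-Mead",
            options={"maxiter": 20000, "fatol": 1e-14},
        )
        assert fit.fmin <= res.fun + 1e-7

    def test_misspecification_degrades_indices(self):
        # generator with heterogeneous cross-loadings that the CFA
        # pattern omits and the free factor covariance cannot absorb
        base = ld.block_loadings(2, 4, 0.7)
        fits = []
        for cross in (0.0, 0.3, 0.5):
            L = base.copy()
            L[:2, 1] = cross
            spec = ld.SyntheticSpec(800, L, np.full(8, 0.4), seed=16)
            table, _ = ld.generate_factor_data(spec)
            S = np.corrcoef(table.values.to_numpy(), rowvar=False)
            pat = ld.CfaPattern(free_mask=base != 0, variable_names=table.variables)
            fits.append(ld.fit_cfa(S, pat, n_obs=800))
        rmseas = [f.rmsea for f in fits]
        srmrs = [f.srmr for f in fits]
        assert rmseas == sorted(rmseas)
        assert srmrs == sorted(srmrs)


class TestBaseline:
    def test_diagonal_covariance_is_saturated(self):
        chi, df = ld.baseline_model(np.diag([1.0, 2.0, 3.0]), n_obs=100)
        assert chi == pytest.approx(0.0, abs=1e-10)
        assert df == 3

    def test_closed_form_two_variable_case(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi, df = ld.baseline_model(S, n_obs=101)
        assert chi == pytest.approx(100 * -np.log(0.75), rel=1e-12)  # ~28.77
        assert df == 1

    def test_singular_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            ld.baseline_model(np.ones((3, 3)), n_obs=50)


class TestFitIndices:
    def _fit(self, chi, df, chi_b=1000.0, df_b=60, n=101):
        return ld.CfaFit(
            pattern=None, loadings=None, factor_cov=None, residual_variances=None,
            chi_square=chi, df=df, baseline_chi_square=chi_b, baseline_df=df_b,
            n_obs=n, converged=True, fmin=chi / (n - 1),
        )

    def test_closed_form_values(self):
        fit = ld.fit_indices(self._fit(100.0, 50))
        assert fit.cfi == pytest.approx(1 - 50 / 940, abs=1e-4)  # ~0.9468
        assert fit.tli == pytest.approx((1000 / 60 - 2) / (1000 / 60 - 1), abs=1e-4)  # ~0.9362
        assert fit.rmsea == pytest.approx(0.1, abs=1e-12)

    def test_parsimony_truncation(self):
        fit = ld.fit_indices(self._fit(40.0, 50))
        assert fit.rmsea == 0.0
        assert fit.cfi == pytest.approx(1.0)

    def test_rmsea_ci_brackets_estimate_and_narrows_with_n(self):
        lo1, hi1 = ld.fit_indices(self._fit(100.0, 50, n=101)).rmsea_ci90
        assert lo1 <= 0.1 <= hi1
        lo2, hi2 = ld.fit_indices(self._fit(1000.0, 500, n=1001)).rmsea_ci90
        # same chi/df ratio, ten times the data: interval shrinks
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_perfect_reconstruction_srmr_zero(self):
        L = ld.block_loadings(2, 3, 0.7)
        Sigma = L @ L.T + np.diag(1 - (L**2).sum(1))
        pat = two_factor_pattern(3)
        fit = ld.fit_cfa(Sigma, pat, n_obs=200)
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)
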