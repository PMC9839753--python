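"""Confirmatory factor analysis with standard fit indices.

A CFA fixes which loadings are free (a pattern, typically derived
from an exploratory solution by thresholding |loadings|) and fits

    Sigma(theta) = Lambda Phi Lambda' + Theta

by maximum likelihood, where Lambda holds the free loadings, Phi is
the factor covariance matrix (variances fixed to 1; covariances free
by default) and Theta the diagonal residual variances. The fit
function is

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^{-1}) - p,

with chi^2 = (n - 1) * F_ML at the optimum. Fit is summarized by the
comparative fit index (CFI), Tucker–Lewis index (TLI), root mean
square error of approximation (RMSEA, parsimony-corrected, with a 90%
confidence interval from the noncentral chi^2 distribution) and the
standardized root mean square residual (SRMR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .efa import FactorSolution

CFA_LOADING_THRESHOLD = 0.45


@dataclass
class CfaPattern:
    """Which loadings are estimated freely; everything else is fixed to 0."""

    free_mask: np.ndarray  # variables × factors, bool
    variable_names: list[str]
    factor_covs_free: bool = True
    dropped_variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.free_mask = np.asarray(self.free_mask, bool)
        if self.free_mask.ndim != 2:
            raise ValueError("free_mask must be variables × factors")
        if self.free_mask.shape[0] != len(self.variable_names):
            raise ValueError("variable_names length mismatch")
        if not self.free_mask.any(axis=0).all():
            raise ValueError("every factor needs at least one free indicator")
        if not self.free_mask.any(axis=1).all():
            raise ValueError("variables without any free loading must be dropped from the pattern")

    @property
    def n_variables(self) -> int:
        return self.free_mask.shape[0]

    @property
    def n_factors(self) -> int:
        return self.free_mask.shape[1]

    @property
    def n_free_parameters(self) -> int:
        k = self.n_factors
        covs = k * (k - 1) // 2 if self.factor_covs_free else 0
        return int(self.free_mask.sum()) + self.n_variables + covs

    def degrees_of_freedom(self) -> int:
        p = self.n_variables
        return p * (p + 1) // 2 - self.n_free_parameters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.free_mask,
            index=self.variable_names,
            columns=[f"factor{j + 1}" for j in range(self.n_factors)],
        )


def pattern_from_efa(
    sol: FactorSolution,
    threshold: float = CFA_LOADING_THRESHOLD,
    factor_covs_free: bool = True,
) -> CfaPattern:
    """Indicator pattern from an exploratory solution.

    Variables with |loading| > threshold (default 0.45) on a factor
    become its free indicators; all other loadings are fixed to 0, and
    variables with no free loading are dropped from the CFA variable
    set (recorded in ``dropped_variables``).
    """
    if not sol.rotated and sol.n_factors > 1:
        warnings.warn("pattern derived from an unrotated solution", stacklevel=2)
    names = sol.variable_names or [f"var{i:03d}" for i in range(sol.n_variables)]
    mask = np.abs(sol.loadings) > threshold
    keep = mask.any(axis=1)
    dropped = [n for n, k in zip(names, keep) if not k]
    mask = mask[keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    if not mask.size or not mask.any(axis=0).all():
        bad = [j + 1 for j in range(mask.shape[1]) if not mask[:, j].any()]
        raise ValueError(f"factors without indicators at threshold {threshold}: {bad}")
    counts = mask.sum(axis=0)
    weak = [j + 1 for j, c in enumerate(counts) if c < 2]
    if weak:
        warnings.warn(
            f"factors with fewer than 2 indicators (model may be under-identified): {weak}",
            stacklevel=2,
        )
    return CfaPattern(
        free_mask=mask,
        variable_names=kept_names,
        factor_covs_free=factor_covs_free,
        dropped_variables=dropped,
    )


@dataclass
class CfaFit:
    """Estimates and fit statistics of one confirmatory model."""

    pattern: CfaPattern
    loadings: np.ndarray
    factor_cov: np.ndarray
    residual_variances: np.ndarray
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    n_obs: int
    converged: bool
    fmin: float
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None
    rmsea_ci90: tuple[float, float] | None = None
    srmr: float | None = None
    standard_errors: np.ndarray | None = None  # aligned with free parameter vector

    def implied_covariance(self) -> np.ndarray:
        return (
            self.loadings @ self.factor_cov @ self.loadings.T
            + np.diag(self.residual_variances)
        )

    def summary(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90) if self.rmsea_ci90 else None,
            "srmr": self.srmr,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def _unpack(theta: np.ndarray, pattern: CfaPattern) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p, k = pattern.n_variables, pattern.n_factors
    n_load = int(pattern.free_mask.sum())
    Lam = np.zeros((p, k))
    Lam[pattern.free_mask] = theta[:n_load]
    pos = n_load
    Phi = np.eye(k)
    if pattern.factor_covs_free:
        iu = np.triu_indices(k, 1)
        Phi[iu] = theta[pos : pos + len(iu[0])]
        Phi[(iu[1], iu[0])] = Phi[iu]
        pos += len(iu[0])
    theta_res = np.exp(theta[pos:])
    return Lam, Phi, theta_res


def _fml_and_grad(
    theta: np.ndarray, S: np.ndarray, pattern: CfaPattern, logdet_S: float
) -> tuple[float, np.ndarray]:
    p, k = pattern.n_variables, pattern.n_factors
    Lam, Phi, res = _unpack(theta, pattern)
    Sigma = Lam @ Phi @ Lam.T + np.diag(res)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0 or not np.isfinite(logdet):
        return 1e10 + float(np.sum(theta**2)), 2 * theta  # push back to sane region
    P = np.linalg.inv(Sigma)
    F = float(logdet - logdet_S + np.trace(S @ P) - p)
    G = P @ (Sigma - S) @ P  # dF/dSigma
    grad_lam_full = 2.0 * G @ Lam @ Phi
    parts = [grad_lam_full[pattern.free_mask]]
    if pattern.factor_covs_free:
        M = Lam.T @ G @ Lam
        iu = np.triu_indices(k, 1)
        parts.append(2.0 * M[iu])
    parts.append(np.diag(G) * res)  # log-parameterized residuals
    return F, np.concatenate(parts)


def fit_cfa(
    S: np.ndarray | pd.DataFrame,
    pattern: CfaPattern,
    n_obs: int,
    compute_indices: bool = True,
    compute_se: bool = False,
    start: np.ndarray | None = None,
) -> CfaFit:
    """Fit the confirmatory model to a covariance/correlation matrix.

    ``S`` must cover the pattern's variables (a labeled DataFrame is
    subset by name). Minimizes F_ML over the free parameters; the test
    statistic is chi^2 = (n_obs − 1)·F_ML. Non-convergence is reported,
    not raised.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[pattern.variable_names, pattern.variable_names].to_numpy(float)
    S = np.asarray(S, float)
    p, k = pattern.n_variables, pattern.n_factors
    if S.shape != (p, p):
        raise ValueError("S does not match the pattern's variable set")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("S must be positive definite on the modeled variables")
    if pattern.degrees_of_freedom() < 0:
        raise ValueError("model has negative degrees of freedom (not identified)")

    n_load = int(pattern.free_mask.sum())
    n_cov = k * (k - 1) // 2 if pattern.factor_covs_free else 0
    if start is None:
        start = np.concatenate(
            [np.full(n_load, 0.5), np.zeros(n_cov), np.log(np.full(p, 0.5))]
        )
    bounds = (
        [(None, None)] * n_load
        + [(-0.98, 0.98)] * n_cov
        + [(np.log(1e-4), None)] * p
    )
    res = optimize.minimize(
        _fml_and_grad,
        start,
        args=(S, pattern, logdet_S),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 5000, "ftol": 1e-13, "gtol": 1e-9},
    )
    Lam, Phi, theta_res = _unpack(res.x, pattern)
    fmin = float(res.fun)
    converged = bool(res.status in (0, 2)) and fmin < 1e9

    chi_b, df_b = baseline_model(S, n_obs)
    fit = CfaFit(
        pattern=pattern,
        loadings=Lam,
        factor_cov=Phi,
        residual_variances=theta_res,
        chi_square=(n_obs - 1) * fmin,
        df=pattern.degrees_of_freedom(),
        baseline_chi_square=chi_b,
        baseline_df=df_b,
        n_obs=n_obs,
        converged=converged,
        fmin=fmin,
    )
    if not converged:
        warnings.warn("CFA did not converge; fit indices may be meaningless", stacklevel=2)
    if compute_se:
        fit.standard_errors = _standard_errors(res.x, S, pattern, logdet_S, n_obs)
    if compute_indices:
        fit = fit_indices(fit, S=S)
    return fit


def _standard_errors(
    theta: np.ndarray, S: np.ndarray, pattern: CfaPattern, logdet_S: float, n_obs: int
) -> np.ndarray:
    """Asymptotic SEs from a finite-difference Hessian of F_ML.

    acov = (2 / (n − 1)) H^{-1}; entries follow the free-parameter
    layout (loadings, factor covariances, log residual variances —
    the residual SEs are back-transformed to the variance scale).
    """
    m = theta.size
    eps = 1e-5
    H = np.zeros((m, m))
    for i in range(m):
        tp = theta.copy()
        tp[i] += eps
        _, gp = _fml_and_grad(tp, S, pattern, logdet_S)
        tm = theta.copy()
        tm[i] -= eps
        _, gm = _fml_and_grad(tm, S, pattern, logdet_S)
        H[i] = (gp - gm) / (2 * eps)
    H = (H + H.T) / 2
    try:
        acov = 2.0 / (n_obs - 1) * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(acov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(m, np.nan)
    # delta method for log-parameterized residual variances
    p = pattern.n_variables
    res_vals = np.exp(theta[m - p :])
    se[m - p :] = se[m - p :] * res_vals
    return se


def baseline_model(S: np.ndarray, n_obs: int) -> tuple[float, int]:
    """Independence baseline: diagonal Sigma with free variances.

    chi^2_B = (n − 1)(ln|diag S| − ln|S|), df_B = p(p−1)/2; for a
    correlation matrix this is (n − 1)(−ln|R|).
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance matrix")
    logdet_diag = float(np.sum(np.log(np.diag(S))))
    chi = (n_obs - 1) * (logdet_diag - logdet_S)
    return float(max(chi, 0.0)), p * (p - 1) // 2


def fit_indices(fit: CfaFit, S: np.ndarray | None = None) -> CfaFit:
    """Populate CFI, TLI, RMSEA (+90% CI) and SRMR on a fitted model.

    CFI and TLI compare the model's noncentrality to the independence
    baseline; RMSEA is the parsimony-corrected misfit per degree of
    freedom with a CI from inverting the noncentral chi^2 CDF; SRMR is
    the RMS standardized residual over the p(p+1)/2 unique elements
    (requires ``S``).
    """
    chi_m, df_m = fit.chi_square, fit.df
    chi_b, df_b = fit.baseline_chi_square, fit.baseline_df
    n = fit.n_obs

    nc_m = max(chi_m - df_m, 0.0)
    nc_b = max(chi_b - df_b, 0.0)
    fit.cfi = 1.0 - nc_m / max(nc_b, nc_m, np.finfo(float).tiny)
    if df_b > 0 and df_m > 0 and chi_b / df_b != 1.0:
        tli = ((chi_b / df_b) - (chi_m / df_m)) / ((chi_b / df_b) - 1.0)
        fit.tli = min(tli, 1.0)
    else:
        fit.tli = None
    if df_m > 0:
        fit.rmsea = float(np.sqrt(nc_m / (df_m * (n - 1))))
        fit.rmsea_ci90 = _rmsea_ci(chi_m, df_m, n)
    else:
        fit.rmsea = 0.0
        fit.rmsea_ci90 = (0.0, 0.0)
        warnings.warn("saturated model (df = 0): RMSEA undefined, reported as 0", stacklevel=2)
    if S is not None:
        Sigma = fit.implied_covariance()
        S = np.asarray(S, float)
        d = np.sqrt(np.diag(S))
        std_resid = (S - Sigma) / np.outer(d, d)
        iu = np.triu_indices(S.shape[0])
        fit.srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    return fit


def _rmsea_ci(chi: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi^2 CDF for the RMSEA confidence bounds."""
    lo_q = (1 + level) / 2  # 0.95
    hi_q = (1 - level) / 2  # 0.05

    def bound(q: float) -> float:
        # find lambda with P(X_{df,lambda} <= chi) = q
        f = lambda lam: stats.ncx2.cdf(chi, df, lam) - q
        hi = max(10.0 * chi, 1.0)
        if f(0.0) < 0:  # even lambda=0 gives too little mass -> bound at 0
            return 0.0
        if f(hi) > 0:
            return hi
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))

    lam_lo = bound(lo_q)
    lam_hi = bound(hi_q)
    denom = df * (n - 1)
    return (float(np.sqrt(lam_lo / denom)), float(np.sqrt(lam_hi / denom)))
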