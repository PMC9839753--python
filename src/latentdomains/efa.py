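"""Maximum-likelihood exploratory factor analysis.

The common-factor model approximates a correlation/covariance matrix
``S`` by ``Sigma = L L' + U^2`` with ``L`` the variables × factors
loading matrix and ``U^2`` a diagonal matrix of uniquenesses. The
estimation target is the ML discrepancy

    E = 1/2 * tr( ((S - Sigma) Sigma^{-1})^2 ),

which is zero iff the reconstruction is exact. Fitting proceeds in two
stages: the classical profile-likelihood device (optimize uniquenesses
with conditionally-optimal loadings from the eigendecomposition of
``U^{-1} S U^{-1}``, Lawley–Maxwell) provides the starting point, and a
quasi-Newton polish of E over all parameters with its analytic
gradient delivers a stationary point of the discrepancy above.

Also here: varimax rotation, per-factor explained variance
``EV_f = sum_v l_vf^2``, covariance reconstruction and Bartlett
(weighted-least-squares) factor scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

UNIQUENESS_FLOOR = 0.005  # Heywood guard: smallest admissible uniqueness


@dataclass
class FactorSolution:
    """One fitted factor model: loadings, uniquenesses and bookkeeping."""

    loadings: np.ndarray  # variables × k
    uniquenesses: np.ndarray  # per-variable, diag of U^2
    n_factors: int
    rotated: bool = False
    converged: bool = True
    n_obs: int | None = None
    discrepancy: float | None = None
    variable_names: list[str] | None = None

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    @property
    def explained_variance(self) -> np.ndarray:
        return explained_variance(self.loadings)

    @property
    def percent_variance(self) -> np.ndarray:
        return self.explained_variance / self.n_variables * 100.0

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        names = self.variable_names or [f"var{i:03d}" for i in range(self.n_variables)]
        cols = [f"factor{j + 1}" for j in range(self.n_factors)]
        return pd.DataFrame(self.loadings, index=names, columns=cols)

    def replace(self, **kw) -> "FactorSolution":
        d = {f.name: getattr(self, f.name) for f in self.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        d.update(kw)
        return FactorSolution(**d)


# ---------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------

def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML error E = 1/2 tr(((S - Sigma) Sigma^{-1})^2); 0 iff S == Sigma."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("Sigma must be invertible (positive definite)")
    A = (S - Sigma) @ np.linalg.inv(Sigma)
    return 0.5 * float(np.trace(A @ A))


def _discrepancy_and_grad(
    theta: np.ndarray, S: np.ndarray, p: int, k: int
) -> tuple[float, np.ndarray]:
    """E and its gradient w.r.t. (L.ravel(), log psi)."""
    L = theta[: p * k].reshape(p, k)
    psi = np.exp(theta[p * k :])
    Sigma = L @ L.T + np.diag(psi)
    P = np.linalg.inv(Sigma)
    D = S - Sigma
    PD = P @ D
    E = 0.5 * float(np.trace(PD @ PD))
    M = PD @ P  # = P D P, symmetric
    G = -(M + M @ D @ P)  # dE/dSigma
    grad_L = 2.0 * G @ L
    grad_logpsi = np.diag(G) * psi
    return E, np.concatenate([grad_L.ravel(), grad_logpsi])


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

def _profile_objective(psi: np.ndarray, S: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Canonical ML fit function profiled over loadings, with gradient.

    For fixed uniquenesses the conditionally optimal loadings come from
    the top-k eigenpairs of psi^{-1/2} S psi^{-1/2}; the remaining
    eigenvalues carry the misfit.
    """
    sc = 1.0 / np.sqrt(psi)
    Sstar = (S * sc).T * sc
    vals, vecs = linalg.eigh(Sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    tail = vals[k:]
    f = float(np.sum(tail - np.log(np.clip(tail, 1e-12, None)) - 1.0))
    load = vecs[:, :k] * np.sqrt(np.clip(vals[:k] - 1.0, 0.0, None))
    load = (load.T * np.sqrt(psi)).T
    g = load @ load.T + np.diag(psi) - S
    return f, np.diag(g) / psi**2


def _conditional_loadings(psi: np.ndarray, S: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    Sstar = (S * sc).T * sc
    vals, vecs = linalg.eigh(Sstar)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    load = vecs[:, :k] * np.sqrt(np.clip(vals[:k] - 1.0, 0.0, None))
    return (load.T * np.sqrt(psi)).T


def fit_ml_factors(
    S: np.ndarray | pd.DataFrame,
    k: int,
    n_obs: int | None = None,
    polish: bool = True,
) -> FactorSolution:
    """Fit the k-factor model to a correlation-scaled covariance matrix.

    Returns the unrotated solution minimizing the ML discrepancy E,
    with uniquenesses floored at ``UNIQUENESS_FLOOR`` (Heywood guard)
    and ``converged`` reporting optimizer status.
    """
    names = list(S.columns) if isinstance(S, pd.DataFrame) else None
    S = np.asarray(S, float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be a symmetric matrix")
    if not 1 <= k < p:
        raise ValueError(f"number of factors must satisfy 1 <= k < {p}")

    # no shared variance at all (S effectively diagonal): the split of a
    # variable's variance between a single-indicator loading and its
    # uniqueness is then unidentified, so return the null solution
    f_ones, _ = _profile_objective(np.clip(np.diag(S), UNIQUENESS_FLOOR, None), S, k)
    if f_ones < 1e-12:
        return FactorSolution(
            loadings=np.zeros((p, k)),
            uniquenesses=np.clip(np.diag(S).astype(float), UNIQUENESS_FLOOR, None),
            n_factors=k,
            rotated=False,
            converged=True,
            n_obs=n_obs,
            discrepancy=ml_discrepancy(S, np.diag(np.clip(np.diag(S), UNIQUENESS_FLOOR, None))),
            variable_names=names,
        )

    # stage 1: profile likelihood over uniquenesses
    try:
        inv_diag = np.diag(np.linalg.pinv(S))
        psi0 = np.clip((1.0 - 0.5 * k / p) / np.clip(inv_diag, 1e-8, None), 0.05, 0.95)
    except np.linalg.LinAlgError:
        psi0 = np.full(p, 0.5)
    res1 = optimize.minimize(
        _profile_objective,
        psi0,
        args=(S, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(UNIQUENESS_FLOOR, 1.0)] * p,
        options={"maxiter": 500},
    )
    psi = np.clip(res1.x, UNIQUENESS_FLOOR, None)
    L = _conditional_loadings(psi, S, k)

    converged = bool(res1.success)
    if polish:
        # stage 2: minimize the discrepancy E itself over all parameters
        theta0 = np.concatenate([L.ravel(), np.log(psi)])
        bounds = [(None, None)] * (p * k) + [(np.log(UNIQUENESS_FLOOR), None)] * p
        res2 = optimize.minimize(
            _discrepancy_and_grad,
            theta0,
            args=(S, p, k),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        L = res2.x[: p * k].reshape(p, k)
        psi = np.exp(res2.x[p * k :])
        converged = converged and bool(res2.status in (0, 2))

    if np.any(psi <= UNIQUENESS_FLOOR + 1e-12):
        warnings.warn("Heywood case: uniqueness floored at "
                      f"{UNIQUENESS_FLOOR}", stacklevel=2)
    if not converged:
        warnings.warn("ML factor fit did not fully converge", stacklevel=2)

    sol = FactorSolution(
        loadings=L,
        uniquenesses=np.clip(psi, UNIQUENESS_FLOOR, None),
        n_factors=k,
        rotated=False,
        converged=converged,
        n_obs=n_obs,
        variable_names=names,
    )
    sol = canonicalize(sol)
    sol.discrepancy = ml_discrepancy(S, reconstruct_covariance(sol))
    return sol


def canonicalize(sol: FactorSolution) -> FactorSolution:
    """Order factors by decreasing explained variance; fix arbitrary signs.

    Each factor's sign is chosen so its largest-magnitude loading is
    positive (the sign of a factor's loadings is arbitrary under
    orthogonal rotation).
    """
    ev = explained_variance(sol.loadings)
    order = np.argsort(-ev, kind="stable")
    L = sol.loadings[:, order]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return sol.replace(loadings=L * signs)


# ---------------------------------------------------------------------
# rotation and summaries
# ---------------------------------------------------------------------

def varimax_rotate(
    L: np.ndarray, kaiser_normalize: bool = False, tol: float = 1e-12, max_iter: int = 1000
) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix.

    Maximizes the sum over factors of the variance of squared loadings
    (simple structure); row communalities are invariant. ``k = 1``
    returns the input unchanged.
    """
    L = np.asarray(L, float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    A = L.copy()
    h = None
    if kaiser_normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = A @ R
        B = A.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d_new = float(s.sum())
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    out = A @ R
    if kaiser_normalize:
        out = out * h[:, None]
    return out


def varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = np.asarray(L, float) ** 2
    return float(np.sum(sq.var(axis=0)))


def rotate_solution(sol: FactorSolution, kaiser_normalize: bool = False) -> FactorSolution:
    """Varimax-rotate a solution and re-canonicalize factor order/sign."""
    L = varimax_rotate(sol.loadings, kaiser_normalize=kaiser_normalize)
    return canonicalize(sol.replace(loadings=L, rotated=True))


def explained_variance(L: np.ndarray) -> np.ndarray:
    """EV_f = sum over variables of squared loadings, per factor."""
    return (np.asarray(L, float) ** 2).sum(axis=0)


def reconstruct_covariance(sol: FactorSolution) -> np.ndarray:
    """Model-implied covariance Sigma = L L' + U^2."""
    return sol.loadings @ sol.loadings.T + np.diag(sol.uniquenesses)


def bartlett_scores(data: np.ndarray | pd.DataFrame, sol: FactorSolution) -> pd.DataFrame:
    """Weighted-least-squares (Bartlett) factor scores, one row per subject.

    scores = X U^{-2} L (L' U^{-2} L)^{-1}: the unbiased GLS estimate of
    each subject's position on every latent dimension, computed from
    standardized data.
    """
    index = data.index if isinstance(data, pd.DataFrame) else None
    X = np.asarray(data, float)
    if X.shape[1] != sol.n_variables:
        raise ValueError("data variables do not match the solution")
    if np.any(sol.uniquenesses <= 0):
        raise ValueError("uniquenesses must be strictly positive")
    inv_psi = 1.0 / sol.uniquenesses
    middle = sol.loadings.T * inv_psi @ sol.loadings
    cond = np.linalg.cond(middle)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("L' U^-2 L is singular; scores undefined")
    W = (inv_psi[:, None] * sol.loadings) @ np.linalg.inv(middle)
    cols = [f"factor{j + 1}" for j in range(sol.n_factors)]
    return pd.DataFrame(X @ W, index=index, columns=cols)


def fit_efa(
    data: np.ndarray | pd.DataFrame,
    k: int,
    rotate: bool = True,
    kaiser_normalize: bool = False,
) -> FactorSolution:
    """Convenience front door: correlation matrix → ML fit → varimax.

    ``data`` is a subjects × variables matrix (ideally standardized
    upstream); the correlation matrix is analysed.
    """
    names = list(data.columns) if isinstance(data, pd.DataFrame) else None
    X = np.asarray(data, float)
    S = np.corrcoef(X, rowvar=False)
    sol = fit_ml_factors(pd.DataFrame(S, columns=names) if names else S, k, n_obs=X.shape[0])
    if rotate and k >= 2:
        sol = rotate_solution(sol, kaiser_normalize=kaiser_normalize)
    return sol
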