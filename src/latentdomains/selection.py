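"""Choosing the number of factors: fit, interpretability, robustness.

Three complementary diagnostics guide dimensionality:

* **Parallel analysis** — shared-variance values from the data are
  compared, factor by factor, with their averages over pure-noise
  matrices of identical shape; the crossover point bounds the number
  of factors worth considering.
* **Subsampling robustness** — factors are re-extracted on repeated
  80% subject subsamples, matched back to the full-data solution with
  the Hungarian algorithm (cost = 1 − |correlation|), and scored by the
  mean absolute pairwise correlation of each factor's loading vector
  across subsamples.
* **Interpretability** — a factor is interpretable when at least three
  variables load on it beyond a threshold (default |loading| > 0.4).

``evaluate_dimensionality`` assembles the three into one tidy report;
the final choice of k remains a judgment call for the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .efa import FactorSolution, explained_variance, fit_efa, fit_ml_factors, rotate_solution
from .synthetic import generate_null_matrix

INTERPRETABILITY_THRESHOLD = 0.4
INTERPRETABILITY_MIN_VARIABLES = 3


@dataclass
class ParallelAnalysisResult:
    """Real vs pure-noise shared variance, factor by factor."""

    real_values: np.ndarray
    null_means: np.ndarray
    n_reps: int
    crossover: int
    method: str = "eigen"

    def to_frame(self) -> pd.DataFrame:
        m = len(self.real_values)
        return pd.DataFrame(
            {
                "factor": np.arange(1, m + 1),
                "real": self.real_values,
                "null_mean": self.null_means[:m],
            }
        )


@dataclass
class RobustnessResult:
    """Mean |r| of each factor's loadings across subsample pairs, per k."""

    values: dict[int, np.ndarray]  # k -> per-factor mean |r|
    n_iterations: int
    subsample_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "factor": f + 1, "mean_abs_r": v}
            for k, vals in self.values.items()
            for f, v in enumerate(vals)
        ]
        return pd.DataFrame(rows)


def _corr_eigenvalues(X: np.ndarray) -> np.ndarray:
    S = np.corrcoef(X, rowvar=False)
    vals = np.linalg.eigvalsh(S)[::-1]
    return vals


def parallel_analysis(
    data: np.ndarray | pd.DataFrame,
    n_reps: int = 20,
    seed: int = 0,
    method: str = "eigen",
    k_max: int | None = None,
) -> ParallelAnalysisResult:
    """Compare the data's shared variance with size-matched noise.

    ``method="eigen"`` (default) compares correlation-matrix
    eigenvalues. ``method="ml"`` refits the ML factor model at each
    candidate k on the real data and on every null repetition, using
    the k-th factor's squared-loading sum EV_k as the value for index
    k (capped at ``k_max``, default min(p//2, 15), since ML fits at
    every k are expensive). The crossover is the number of leading
    factors whose real value exceeds the null mean.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    X = np.asarray(data, float)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    if method == "eigen":
        real = _corr_eigenvalues(X)
        nulls = np.stack(
            [
                _corr_eigenvalues(generate_null_matrix(n, p, int(rng.integers(2**31))))
                for _ in range(n_reps)
            ]
        )
        null_means = nulls.mean(axis=0)
    elif method == "ml":
        if k_max is None:
            k_max = min(p // 2, 15)
        k_max = max(1, min(k_max, p - 1))

        def ev_profile(M: np.ndarray) -> np.ndarray:
            S = np.corrcoef(M, rowvar=False)
            out = np.empty(k_max)
            for k in range(1, k_max + 1):
                sol = fit_ml_factors(S, k, n_obs=M.shape[0], polish=False)
                out[k - 1] = np.sort(explained_variance(sol.loadings))[0]
            return out

        real = ev_profile(X)
        nulls = np.stack(
            [
                ev_profile(generate_null_matrix(n, p, int(rng.integers(2**31))))
                for _ in range(n_reps)
            ]
        )
        null_means = nulls.mean(axis=0)
    else:
        raise ValueError(f"unknown parallel-analysis method: {method}")

    crossover = 0
    for r, nm in zip(real, null_means):
        if r > nm:
            crossover += 1
        else:
            break
    return ParallelAnalysisResult(
        real_values=real, null_means=null_means, n_reps=n_reps, crossover=crossover, method=method
    )


def match_factors(
    reference: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimally pair factors of two loading matrices.

    Solves the assignment problem with cost 1 − |corr(loading vectors)|
    (Hungarian algorithm). Returns ``(permutation, signs, matched_r)``
    such that ``other[:, permutation] * signs`` aligns with
    ``reference`` column by column and every matched correlation is
    nonnegative. Zero-variance columns correlate 0 by convention.
    """
    A = np.asarray(reference, float)
    B = np.asarray(other, float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have identical shape")
    k = A.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = _safe_corr(A[:, i], B[:, j])
    _, cols = linear_sum_assignment(1.0 - np.abs(corr))
    matched = corr[np.arange(k), cols]
    signs = np.where(matched < 0, -1.0, 1.0)
    return cols, signs, np.abs(matched)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float(xc @ yc / denom)


def robustness_subsampling(
    data: np.ndarray | pd.DataFrame,
    k_max: int,
    n_iter: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    k_values: list[int] | None = None,
) -> RobustnessResult:
    """Stability of each factor's loadings under subject subsampling.

    For every iteration a ``fraction`` of subjects is drawn without
    replacement; factors are extracted and varimax-rotated at each
    k, reordered/sign-aligned against the full-data solution at the
    same k (Hungarian matching), and the loading vectors stored. The
    robustness of factor f at dimensionality k is the mean absolute
    Pearson correlation of its loading vector over all pairs of
    subsamples.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = np.asarray(data, float)
    n, p = X.shape
    ks = list(k_values) if k_values is not None else list(range(1, k_max + 1))
    rng = np.random.default_rng(seed)
    n_sub = max(int(round(fraction * n)), 2)

    references = {k: fit_efa(X, k) for k in ks}
    stored: dict[int, list[np.ndarray]] = {k: [] for k in ks}
    for _ in range(n_iter):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub = X[idx]
        for k in ks:
            if n_sub <= k:
                warnings.warn(f"subsample of {n_sub} too small for k={k}; skipped", stacklevel=2)
                continue
            try:
                sol = fit_efa(sub, k)
            except (np.linalg.LinAlgError, ValueError) as err:  # degenerate subsample
                warnings.warn(f"fit failed on a subsample at k={k}: {err}", stacklevel=2)
                continue
            perm, signs, _ = match_factors(references[k].loadings, sol.loadings)
            stored[k].append(sol.loadings[:, perm] * signs)

    values: dict[int, np.ndarray] = {}
    for k in ks:
        mats = stored[k]
        out = np.full(k, np.nan)
        if len(mats) >= 2:
            arr = np.stack(mats)  # iterations × p × k
            for f in range(k):
                vecs = arr[:, :, f]  # iterations × p
                C = np.corrcoef(vecs)
                iu = np.triu_indices(len(mats), 1)
                out[f] = float(np.nanmean(np.abs(C[iu])))
        values[k] = out
    return RobustnessResult(values=values, n_iterations=n_iter, subsample_fraction=fraction)


def interpretability_counts(
    sol: FactorSolution,
    threshold: float = INTERPRETABILITY_THRESHOLD,
    min_variables: int = INTERPRETABILITY_MIN_VARIABLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Per factor: how many variables load beyond |threshold|, and pass/fail.

    A factor passes when at least ``min_variables`` (default 3)
    variables exceed the loading threshold in magnitude.
    """
    counts = (np.abs(sol.loadings) > threshold).sum(axis=0)
    return counts, counts >= min_variables


def compare_solutions(
    sol_a: FactorSolution, sol_b: FactorSolution
) -> tuple[pd.DataFrame, np.ndarray]:
    """Correlate loading vectors between two solutions on the same variables.

    Returns the full k_a × k_b correlation matrix and the matched
    diagonal (|r| per optimally paired factor) from Hungarian matching
    when the factor counts agree (otherwise greedy best matches).
    """
    if sol_a.variable_names is not None and sol_b.variable_names is not None:
        if list(sol_a.variable_names) != list(sol_b.variable_names):
            raise ValueError("solutions cover different variable sets")
    elif sol_a.n_variables != sol_b.n_variables:
        raise ValueError("solutions cover different numbers of variables")
    A, B = sol_a.loadings, sol_b.loadings
    mat = np.array([[_safe_corr(A[:, i], B[:, j]) for j in range(B.shape[1])] for i in range(A.shape[1])])
    frame = pd.DataFrame(
        mat,
        index=[f"a_factor{i + 1}" for i in range(A.shape[1])],
        columns=[f"b_factor{j + 1}" for j in range(B.shape[1])],
    )
    if A.shape[1] == B.shape[1]:
        _, _, matched = match_factors(A, B)
    else:
        matched = np.abs(mat).max(axis=1)
    return frame, matched


@dataclass
class DimensionalityReport:
    """Per-k fit, interpretability and robustness, with pass flags."""

    table: pd.DataFrame
    parallel: ParallelAnalysisResult
    robustness: RobustnessResult
    solutions: dict[int, FactorSolution] = field(default_factory=dict)

    def flagged_k(self) -> list[int]:
        per_k = self.table.groupby("k")["passes_all"].all()
        return [int(k) for k, ok in per_k.items() if ok]


def evaluate_dimensionality(
    data: np.ndarray | pd.DataFrame,
    k_max: int | None = None,
    n_pa_reps: int = 20,
    n_robustness_iter: int = 100,
    subsample_fraction: float = 0.8,
    robustness_threshold: float = 0.9,
    interpretability_threshold: float = INTERPRETABILITY_THRESHOLD,
    seed: int = 0,
) -> DimensionalityReport:
    """Assemble the three model-selection criteria into one report.

    ``k_max`` defaults to the parallel-analysis crossover. Each row of
    the report covers one (k, factor): its percent variance,
    interpretability count and robustness, plus per-row and per-k pass
    flags. The final choice of k is left to the user.
    """
    X = np.asarray(data, float)
    pa = parallel_analysis(X, n_reps=n_pa_reps, seed=seed)
    if k_max is None:
        k_max = max(pa.crossover, 1)
    k_max = min(k_max, X.shape[1] - 1)
    rob = robustness_subsampling(
        X, k_max, n_iter=n_robustness_iter, fraction=subsample_fraction, seed=seed + 1
    )
    rows = []
    solutions: dict[int, FactorSolution] = {}
    for k in range(1, k_max + 1):
        sol = fit_efa(X, k)
        solutions[k] = sol
        counts, passes = interpretability_counts(sol, threshold=interpretability_threshold)
        pct = sol.percent_variance
        rvals = rob.values[k]
        for f in range(k):
            rows.append(
                {
                    "k": k,
                    "factor": f + 1,
                    "percent_variance": pct[f],
                    "cumulative_percent_variance": float(pct.sum()),
                    "interpretable_count": int(counts[f]),
                    "interpretable": bool(passes[f]),
                    "robustness": float(rvals[f]) if np.isfinite(rvals[f]) else np.nan,
                    "robust": bool(rvals[f] > robustness_threshold)
                    if np.isfinite(rvals[f])
                    else False,
                }
            )
    table = pd.DataFrame(rows)
    table["passes_all"] = table["interpretable"] & table["robust"]
    return DimensionalityReport(table=table, parallel=pa, robustness=rob, solutions=solutions)
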