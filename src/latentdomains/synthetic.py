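"""Synthetic behavioral tables with planted latent structure.

Data are generated from an orthogonal common-factor model: each
variable is a weighted sum of independent standard-normal factor
scores plus Gaussian variable-specific noise,

    x_iv = sum_f  l_vf * F_fi  +  b_age_v * age_i + b_gender_v * gender_i + eps_iv,

with ``Var(eps_iv)`` the variable's uniqueness.  Because the planted
loadings, uniquenesses, confound effects, family structure and
missingness mechanism are all known, every downstream stage
(preprocessing, factor extraction, model selection, clustering,
confirmatory fits) can be validated by parameter recovery.

The module also produces pure-noise matrices of matched dimensions,
the null reference used by parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import BehavioralTable

_AGE_RANGE = (22, 37)  # young-adult cohort range; inclusive


def block_loadings(
    n_blocks: int,
    vars_per_block: int,
    loading: float = 0.7,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Simple-structure loading matrix: one block of variables per factor.

    Each variable loads ``loading`` (optionally jittered uniformly by
    ±``jitter``) on exactly one factor and 0 elsewhere.
    """
    p = n_blocks * vars_per_block
    L = np.zeros((p, n_blocks))
    vals = np.full(p, float(loading))
    if jitter:
        if rng is None:
            rng = np.random.default_rng(0)
        vals = vals + rng.uniform(-jitter, jitter, size=p)
    for b in range(n_blocks):
        sl = slice(b * vars_per_block, (b + 1) * vars_per_block)
        L[sl, b] = vals[sl]
    return L


def default_family_sizes(n_subjects: int, seed: int = 0) -> list[int]:
    """A mix of singletons and sibling pairs/triples summing to ``n_subjects``."""
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    left = n_subjects
    while left > 0:
        s = int(rng.choice([1, 1, 2, 2, 3]))
        s = min(s, left)
        sizes.append(s)
        left -= s
    return sizes


@dataclass
class SyntheticSpec:
    """Ground-truth parameters for one synthetic study.

    ``loadings`` is variables × factors; ``uniquenesses`` the
    per-variable noise variance (diagonal of U²). Together they define
    the confound-free population covariance Σ = LL' + U². With
    ``scale_to_unit`` (default) rows are rescaled so every variable has
    unit population variance, i.e. communality + uniqueness = 1.
    """

    n_subjects: int
    loadings: np.ndarray
    uniquenesses: np.ndarray
    confound_effects: np.ndarray | None = None  # variables × 2: (age, gender)
    missing_rate: float = 0.0
    family_sizes: list[int] | None = None
    seed: int = 0
    scale_to_unit: bool = True
    variable_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.uniquenesses = np.asarray(self.uniquenesses, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be a variables × factors matrix")
        p = self.loadings.shape[0]
        if self.uniquenesses.shape != (p,):
            raise ValueError("uniquenesses must have one entry per variable")
        if np.any(self.uniquenesses < 0):
            raise ValueError("uniquenesses must be nonnegative")
        if not (0 <= self.missing_rate < 0.10):
            raise ValueError("missing_rate must lie in [0, 0.10)")
        if self.confound_effects is not None:
            self.confound_effects = np.asarray(self.confound_effects, dtype=float)
            if self.confound_effects.shape != (p, 2):
                raise ValueError("confound_effects must be variables × 2 (age, gender)")
        if self.family_sizes is not None:
            if any(s <= 0 for s in self.family_sizes):
                raise ValueError("family sizes must be positive")
            if sum(self.family_sizes) != self.n_subjects:
                raise ValueError(
                    f"family_sizes sum to {sum(self.family_sizes)}, expected {self.n_subjects}"
                )
        if self.scale_to_unit:
            total = (self.loadings**2).sum(axis=1) + self.uniquenesses
            if np.any(total <= 0):
                raise ValueError("every variable needs positive total variance to rescale")
            scale = np.sqrt(total)
            self.loadings = self.loadings / scale[:, None]
            self.uniquenesses = self.uniquenesses / total
        if self.variable_names is None:
            self.variable_names = [f"var{i:03d}" for i in range(p)]
        elif len(self.variable_names) != p:
            raise ValueError("variable_names length mismatch")

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def population_covariance(self) -> np.ndarray:
        """Confound-free population covariance Σ = LL' + U²."""
        return self.loadings @ self.loadings.T + np.diag(self.uniquenesses)

    def block_labels(self) -> np.ndarray:
        """Per-variable block membership: the factor with the largest |loading|."""
        return np.argmax(np.abs(self.loadings), axis=1)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "confound_effects": None
            if self.confound_effects is None
            else self.confound_effects.tolist(),
            "missing_rate": self.missing_rate,
            "family_sizes": self.family_sizes,
            "seed": self.seed,
            "variable_names": self.variable_names,
        }


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    factor_scores: np.ndarray  # subjects × factors
    cluster_labels: np.ndarray  # per-variable block membership
    confounds: pd.DataFrame  # per-subject age, gender


def generate_factor_data(spec: SyntheticSpec) -> tuple[BehavioralTable, GroundTruth]:
    """Draw one table from the planted factor model.

    Factor scores and noise are i.i.d. Gaussian, so the population
    covariance of the confound-free part is exactly LL' + U².  Age is
    integer-uniform on [22, 37] and gender Bernoulli(0.5); both enter
    linearly through ``spec.confound_effects`` (zero effect if None,
    in which case the columns are still generated so the confound
    regression stage has predictors to work with).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_subjects, spec.n_variables, spec.n_factors

    F = rng.standard_normal((n, k))
    eps = rng.standard_normal((n, p)) * np.sqrt(spec.uniquenesses)
    age = rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1, size=n).astype(float)
    gender = rng.integers(0, 2, size=n).astype(float)

    X = F @ spec.loadings.T + eps
    if spec.confound_effects is not None:
        X = X + np.column_stack([age, gender]) @ spec.confound_effects.T

    subjects = pd.Index([f"sub{i:05d}" for i in range(n)], name="subject")
    confounds = pd.DataFrame({"age": age, "gender": gender}, index=subjects)
    family = _assign_families(spec.family_sizes, subjects)
    table = BehavioralTable(
        values=pd.DataFrame(X, index=subjects, columns=spec.variable_names),
        confounds=confounds,
        family_id=family,
    )
    truth = GroundTruth(factor_scores=F, cluster_labels=spec.block_labels(), confounds=confounds)
    if spec.missing_rate > 0:
        table = plant_missingness(table, spec.missing_rate, seed=spec.seed + 1)
    return table, truth


def _assign_families(family_sizes: list[int] | None, subjects: pd.Index) -> pd.Series | None:
    if family_sizes is None:
        return None
    labels = np.repeat(np.arange(len(family_sizes)), family_sizes)
    return pd.Series([f"fam{j:05d}" for j in labels], index=subjects, name="family_id")


def plant_missingness(table: BehavioralTable, rate: float, seed: int) -> BehavioralTable:
    """Apply an MCAR mask at the given overall rate.

    Mirrors the inclusion criterion that analysed variables carry under
    10% missing data: the per-variable missing count is capped strictly
    below 10% of subjects, so no column of the output would be excluded
    by that screen.
    """
    if not (0 <= rate < 0.10):
        raise ValueError("missing rate must lie in [0, 0.10)")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    values = table.values.to_numpy(copy=True)
    n, p = values.shape
    cap = int(np.ceil(0.10 * n)) - 1  # strictly below 10%
    mask = rng.random((n, p)) < rate
    for j in range(p):
        idx = np.flatnonzero(mask[:, j])
        if idx.size > cap:
            keep = rng.choice(idx, size=cap, replace=False)
            col = np.zeros(n, dtype=bool)
            col[keep] = True
            mask[:, j] = col
    values[mask] = np.nan
    out = table.copy()
    out.values = pd.DataFrame(values, index=table.values.index, columns=table.values.columns)
    return out


def generate_null_matrix(n_subjects: int, n_variables: int, seed: int) -> np.ndarray:
    """I.i.d. standard-normal matrix, the parallel-analysis null reference."""
    if n_subjects <= 0 or n_variables <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_subjects, n_variables))
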