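"""Preprocessing chain for behavioral tables.

Order of operations mirrors the study design: variable selection on
the raw table, a family-preserving discovery/replication split, then
per-subset chained imputation, linear confound removal (age, gender),
inversion of error measures such as reaction times, and z-scoring
across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .table import BehavioralTable

MISSING_THRESHOLD = 0.10
CORRELATION_THRESHOLD = 0.1


@dataclass
class SelectionReport:
    """Accounting of which variables survived selection and why others fell."""

    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"kept": self.kept, "dropped": [list(d) for d in self.dropped]}


def select_variables(table: BehavioralTable) -> tuple[BehavioralTable, SelectionReport]:
    """Apply the variable-inclusion criteria.

    A variable is retained when it is numeric, has under 10% missing
    values, is not a composite of other items, is not the
    age/gender-adjusted duplicate of a retained unadjusted variant, and
    correlates at |r| > 0.1 (pairwise-complete Pearson) with at least
    one other surviving candidate — i.e. it shares at least a small
    effect with the rest of the battery.
    """
    if table.n_variables == 0:
        raise ValueError("empty table")
    report = SelectionReport()
    meta = table.variable_meta
    candidates: list[str] = []
    for name in table.variables:
        col = table.values[name]
        if not is_numeric_dtype(col):
            report.dropped.append((name, "non_numeric"))
        elif col.isna().mean() >= MISSING_THRESHOLD:
            report.dropped.append((name, "missing_ge_10pct"))
        elif bool(meta.loc[name, "is_composite"]):
            report.dropped.append((name, "composite"))
        else:
            candidates.append(name)
    # adjusted duplicates: keep the unadjusted variant when both survive
    for name in list(candidates):
        base = meta.loc[name, "adjusted_of"]
        if base is not None and not pd.isna(base) and base in candidates:
            candidates.remove(name)
            report.dropped.append((name, "adjusted_duplicate"))
    # correlation screen among the remaining candidates
    if candidates:
        corr = table.values[candidates].corr(min_periods=2).abs()
        np.fill_diagonal(corr.values, np.nan)
        max_r = corr.max(axis=1, skipna=True).fillna(0.0)
        for name in list(candidates):
            if max_r[name] <= CORRELATION_THRESHOLD:
                candidates.remove(name)
                report.dropped.append((name, "no_correlation_gt_0.1"))
    report.kept = candidates
    if not candidates:
        raise ValueError(f"all variables dropped during selection: {report.dropped}")
    return table.subset_variables(candidates), report


def split_by_family(
    table: BehavioralTable, seed: int
) -> tuple[BehavioralTable, BehavioralTable]:
    """Split subjects into two near-equal subsets keeping families intact.

    Families are assigned whole (siblings never straddle the split) by a
    greedy balance: families are processed in decreasing size with
    seeded tie-breaking, each going to the currently smaller subset.
    """
    if table.family_id is None:
        raise ValueError("family_id required for a family-preserving split")
    rng = np.random.default_rng(seed)
    fam = table.family_id
    sizes = fam.value_counts()
    if sizes.max() > table.n_subjects / 2:
        warnings.warn(
            "one family holds more than half the subjects; split will be unbalanced",
            stacklevel=2,
        )
    order = sizes.sample(frac=1.0, random_state=rng.integers(2**31)).sort_values(
        ascending=False, kind="stable"
    )
    count_a = count_b = 0
    set_a: list[str] = []
    set_b: list[str] = []
    for family, size in order.items():
        if count_a < count_b or (count_a == count_b and rng.random() < 0.5):
            set_a.append(family)
            count_a += size
        else:
            set_b.append(family)
            count_b += size
    mask_a = fam.isin(set_a)
    return (
        table.subset_subjects(table.values.index[mask_a]),
        table.subset_subjects(table.values.index[~mask_a]),
    )


def impute_chained(
    table: BehavioralTable, n_iterations: int = 10, seed: int = 0
) -> BehavioralTable:
    """Fill missing values by chained-equations (MICE-style) imputation.

    Each incomplete variable is iteratively regressed on the others and
    the missing entries replaced by posterior draws, producing a single
    completed dataset. Observed entries are untouched; deterministic
    given the seed.
    """
    values = table.values
    if values.isna().all().any():
        fully = values.columns[values.isna().all()].tolist()
        raise ValueError(f"variables fully missing, cannot impute: {fully}")
    if not values.isna().any().any():
        return table
    imputer = IterativeImputer(
        max_iter=n_iterations,
        sample_posterior=True,
        random_state=int(seed) % (2**31),
        keep_empty_features=False,
    )
    filled = imputer.fit_transform(values.to_numpy())
    out = table.copy()
    out.values = pd.DataFrame(filled, index=values.index, columns=values.columns)
    return out


def regress_confounds(table: BehavioralTable) -> BehavioralTable:
    """Replace every variable by its residual from a linear fit on age and gender.

    The residual (observed minus predicted from intercept + age +
    gender) is orthogonal to both confounds by the normal equations.
    Constant confounds are dropped from the design with a warning.
    """
    if table.confounds is None:
        raise ValueError("confounds (age, gender) required")
    values = table.values
    if values.isna().any().any():
        raise ValueError("impute before regressing confounds")
    cols = []
    for c in table.confounds.columns:
        v = table.confounds[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"confound '{c}' is constant; dropped from the design", stacklevel=2)
        else:
            cols.append(v)
    design = np.column_stack([np.ones(table.n_subjects)] + cols)
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    out = table.copy()
    out.values = pd.DataFrame(resid, index=values.index, columns=values.columns)
    return out


def invert_error_measures(table: BehavioralTable) -> BehavioralTable:
    """Sign-flip reaction times and other error measures so larger = better.

    Flipping (rather than taking reciprocals) preserves linear
    correlation magnitudes, which is what the factor model consumes,
    and applying it twice restores the input. Set ``invert="reciprocal"``
    in :class:`~latentdomains.pipeline.PipelineConfig` for 1/x instead.
    """
    return _invert(table, mode="negate")


def _invert(table: BehavioralTable, mode: str) -> BehavioralTable:
    flags = table.variable_meta["is_error_measure"].astype(bool)
    out = table.copy()
    for name in table.variables:
        if flags[name]:
            if mode == "negate":
                out.values[name] = -out.values[name]
            elif mode == "reciprocal":
                out.values[name] = 1.0 / out.values[name]
            else:
                raise ValueError(f"unknown inversion mode: {mode}")
    return out


def zscore(table: BehavioralTable) -> BehavioralTable:
    """Standardize every variable to mean 0, sd 1 across subjects (ddof=1)."""
    values = table.values
    if values.isna().any().any():
        raise ValueError("impute before z-scoring")
    sd = values.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant variables cannot be z-scored: {constant}")
    out = table.copy()
    out.values = (values - values.mean()) / sd
    return out


def preprocess_subset(
    table: BehavioralTable,
    n_imputation_iterations: int = 10,
    seed: int = 0,
    invert: str = "negate",
) -> BehavioralTable:
    """Impute → regress confounds → invert error measures → z-score."""
    t = impute_chained(table, n_iterations=n_imputation_iterations, seed=seed)
    t = regress_confounds(t)
    t = _invert(t, mode=invert)
    return zscore(t)
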