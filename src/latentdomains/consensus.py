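"""Resampling consensus clustering of variables.

K-means is run on many subsamples of the variables (each variable
represented by its vector over subjects); the consensus index of a
variable pair is the fraction of runs in which they landed in the same
cluster, out of the runs that sampled both. A stable clustering drives
the indices toward 0 or 1.

Diagnostics per K: the empirical CDF of the indices and its area under
the curve (a near-step CDF signals consensus), per-cluster mean
consensus, and the consensus score

    CS = mean(indices above chance) - mean(indices at or below chance),

with chance level 1/K — near zero when co-clustering is random, 1 for
perfect consensus. Final labels come from K-means on the consensus
matrix itself, and partitions are compared with the adjusted Rand
index and adjusted mutual information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score


@dataclass
class ConsensusMatrix:
    """Pairwise consensus indices plus the co-sampling bookkeeping."""

    indices: np.ndarray  # variables × variables, in [0, 1], diagonal 1
    co_sample_counts: np.ndarray
    K: int
    n_iterations: int
    fraction: float
    variable_names: list[str] | None = None

    @property
    def n_variables(self) -> int:
        return self.indices.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_variables, 1)
        return self.indices[iu]

    def to_frame(self) -> pd.DataFrame:
        names = self.variable_names or [f"var{i:03d}" for i in range(self.n_variables)]
        return pd.DataFrame(self.indices, index=names, columns=names)


@dataclass
class ConsensusDiagnostics:
    """CDF/AUC, per-cluster consensus and the consensus score for one K."""

    K: int
    cdf: np.ndarray  # (value, cumulative fraction) pairs, sorted
    auc: float
    consensus_score: float
    chance_level: float
    cluster_consensus: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "auc": self.auc,
            "consensus_score": self.consensus_score,
            "chance_level": self.chance_level,
            "cluster_consensus": None
            if self.cluster_consensus is None
            else self.cluster_consensus.tolist(),
        }


def consensus_cluster(
    data: np.ndarray | pd.DataFrame,
    K: int,
    n_iter: int = 1000,
    fraction: float = 0.8,
    n_init: int = 10,
    seed: int = 0,
    feature_space: str = "subjects",
) -> ConsensusMatrix:
    """Build the consensus matrix for K clusters of variables.

    Per iteration a ``fraction`` of variables is drawn without
    replacement and K-means (``n_init`` centroid restarts, best
    inertia kept) clusters them as points in subject space
    (``feature_space="subjects"``, the default) or as rows of the
    correlation matrix (``feature_space="correlation"``). Indices are
    co-clustering counts normalized by co-sampling counts.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    names = list(data.columns) if isinstance(data, pd.DataFrame) else None
    X = np.asarray(data, float)
    p = X.shape[1]
    if feature_space == "subjects":
        features = X.T  # variables × subjects
    elif feature_space == "correlation":
        features = np.corrcoef(X, rowvar=False)
    else:
        raise ValueError(f"unknown feature space: {feature_space}")

    rng = np.random.default_rng(seed)
    m = max(int(round(fraction * p)), K)
    together = np.zeros((p, p))
    co_sampled = np.zeros((p, p))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(p, size=m, replace=False))
        km = KMeans(n_clusters=K, n_init=n_init, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(features[idx])
        co_sampled[np.ix_(idx, idx)] += 1.0
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        indices = np.where(co_sampled > 0, together / np.where(co_sampled > 0, co_sampled, 1), 0.0)
    never = (co_sampled == 0) & ~np.eye(p, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} variable pairs were never co-sampled; their index is 0",
            stacklevel=2,
        )
    np.fill_diagonal(indices, 1.0)
    return ConsensusMatrix(
        indices=indices,
        co_sample_counts=co_sampled,
        K=K,
        n_iterations=n_iter,
        fraction=fraction,
        variable_names=names,
    )


def consensus_cdf_auc(M: ConsensusMatrix) -> ConsensusDiagnostics:
    """Empirical CDF of the off-diagonal consensus indices and its AUC.

    The CDF is taken over the upper triangle (diagonal excluded). The
    AUC is the exact area under the right-continuous empirical CDF
    over [0, 1] — 0.5 when indices split evenly between 0 and 1, and
    approaching the fraction of never-co-clustered pairs as the CDF
    approaches a step function.
    """
    vals = M.upper_triangle()
    xs, counts = np.unique(vals, return_counts=True)
    cum = np.cumsum(counts) / vals.size
    cdf = np.column_stack([xs, cum])
    # integrate F over [0, 1]: F is 0 below xs[0], cum[i] on [xs[i], xs[i+1])
    grid = np.concatenate([xs, [1.0]]) if xs[-1] < 1.0 else xs.copy()
    heights = cum[: len(grid) - 1] if xs[-1] < 1.0 else cum[:-1]
    auc = float(np.sum(np.diff(grid) * heights))
    cs = consensus_score(M)
    return ConsensusDiagnostics(
        K=M.K, cdf=cdf, auc=auc, consensus_score=cs, chance_level=1.0 / M.K
    )


def delta_auc(aucs: list[float] | np.ndarray, mode: str = "relative") -> np.ndarray:
    """Change in AUC across consecutive K.

    First entry is the AUC at the smallest K; the rest are changes to
    the next K, relative by default ((a_k − a_{k−1}) / a_{k−1}) or
    absolute differences with ``mode="absolute"``.
    """
    a = np.asarray(aucs, float)
    out = np.empty_like(a)
    out[0] = a[0]
    if mode == "relative":
        out[1:] = np.diff(a) / a[:-1]
    elif mode == "absolute":
        out[1:] = np.diff(a)
    else:
        raise ValueError(f"unknown delta mode: {mode}")
    return out


def cluster_consensus(M: ConsensusMatrix, labels: np.ndarray) -> np.ndarray:
    """Mean within-cluster consensus index, one value per cluster.

    Singleton clusters have no within pairs and are defined as 1 (with
    a warning). Cluster ids follow the sorted unique labels.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != M.n_variables:
        raise ValueError("labels must cover all variables")
    if pd.isna(labels).any():
        raise ValueError("labels contain missing cluster ids")
    out = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 1:
            warnings.warn(f"cluster {lab!r} is a singleton; consensus defined as 1", stacklevel=2)
            out.append(1.0)
            continue
        sub = M.indices[np.ix_(members, members)]
        iu = np.triu_indices(members.size, 1)
        out.append(float(sub[iu].mean()))
    return np.asarray(out)


def consensus_score(M: ConsensusMatrix, chance_level: float | None = None) -> float:
    """CS = mean(indices > 1/K) − mean(indices ≤ 1/K) over variable pairs.

    Near zero when all indices scatter around chance, 1 for perfect
    consensus (indices all 0 or 1). An empty bin contributes 0. Ties
    at exactly chance level fall in the *below* bin.
    """
    if chance_level is None:
        chance_level = 1.0 / M.K
    vals = M.upper_triangle()
    above = vals[vals > chance_level]
    below = vals[vals <= chance_level]
    above_mean = float(above.mean()) if above.size else 0.0
    below_mean = float(below.mean()) if below.size else 0.0
    return above_mean - below_mean


def final_labels(M: ConsensusMatrix, K: int | None = None, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Final cluster labels: K-means on the rows of the consensus matrix.

    Each variable's consensus profile (its row of pairwise indices) is
    its feature vector; deterministic given seed and ``n_init``.
    """
    if K is None:
        K = M.K
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > M.n_variables:
        raise ValueError("more clusters than variables")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=int(seed) % (2**31))
    return km.fit_predict(M.indices)


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement (max 1)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))


def adjusted_mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted mutual information under the permutation model, max normalization."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def consensus_sweep(
    data: np.ndarray | pd.DataFrame,
    K_values: list[int],
    n_iter: int = 1000,
    fraction: float = 0.8,
    n_init: int = 10,
    seed: int = 0,
) -> tuple[dict[int, ConsensusMatrix], pd.DataFrame]:
    """Consensus matrices and diagnostics across a range of K.

    Returns the matrices and a tidy frame with AUC, ΔAUC and consensus
    score per K — the machinery behind choosing the cluster count.
    """
    matrices: dict[int, ConsensusMatrix] = {}
    diags = []
    for i, K in enumerate(K_values):
        M = consensus_cluster(
            data, K, n_iter=n_iter, fraction=fraction, n_init=n_init, seed=seed + i
        )
        matrices[K] = M
        d = consensus_cdf_auc(M)
        labels = final_labels(M, K, seed=seed + i)
        d.cluster_consensus = cluster_consensus(M, labels)
        diags.append(d)
    aucs = [d.auc for d in diags]
    table = pd.DataFrame(
        {
            "K": list(K_values),
            "auc": aucs,
            "delta_auc": delta_auc(aucs),
            "consensus_score": [d.consensus_score for d in diags],
            "min_cluster_consensus": [float(np.min(d.cluster_consensus)) for d in diags],
        }
    )
    return matrices, table
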