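"""End-to-end discovery/replication study orchestration.

``run_full_study`` wires the stages together in the study's order:
variable selection → family-preserving split → per-subset
preprocessing (imputation, confound regression, inversion, z-scoring)
→ parallel analysis → per-k factor extraction with robustness and
interpretability → factor hierarchy → consensus clustering on both
subsets → discovery/replication comparison (loading correlations,
ARI/AMI of cluster labels) → CFA of the discovery-derived indicator
patterns on the replication correlation matrix.

Every stochastic step draws its seed from the config, so reruns are
numerically identical; artifacts are returned in-memory and, when an
output directory is given, written as CSV/JSON with a manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cc
from .cfa import CFA_LOADING_THRESHOLD, CfaFit, fit_cfa, pattern_from_efa
from .efa import fit_efa
from .hierarchy import HierarchyFlow, build_hierarchy
from .preprocess import preprocess_subset, select_variables, split_by_family
from .selection import (
    INTERPRETABILITY_THRESHOLD,
    DimensionalityReport,
    compare_solutions,
    evaluate_dimensionality,
)
from .table import BehavioralTable


@dataclass
class PipelineConfig:
    """All tunables of the full study, with the analysis defaults.

    Iteration counts follow the reference procedure (1000 subsampling
    folds, 20 parallel-analysis repetitions, 10 K-means restarts, 80%
    subsample fractions, loading thresholds 0.4 for interpretability
    and 0.45 for CFA indicators); reduce them for quick runs.
    """

    seed: int = 0
    n_imputation_iterations: int = 10
    invert: str = "negate"  # or "reciprocal"
    n_pa_reps: int = 20
    pa_method: str = "eigen"
    n_robustness_iter: int = 1000
    subsample_fraction: float = 0.8
    robustness_threshold: float = 0.9
    interpretability_threshold: float = INTERPRETABILITY_THRESHOLD
    k_max: int | None = None  # None: use the parallel-analysis crossover
    n_consensus_iter: int = 1000
    consensus_fraction: float = 0.8
    kmeans_n_init: int = 10
    K_values: list[int] | None = None  # None: 2..max(k_max, 3)
    cfa_threshold: float = CFA_LOADING_THRESHOLD
    cfa_factor_covs_free: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyReport:
    """Everything the full pipeline computed, stage by stage."""

    config: PipelineConfig
    selection: object
    discovery: BehavioralTable
    replication: BehavioralTable
    dimensionality: DimensionalityReport
    hierarchy: HierarchyFlow | None
    consensus_tables: dict[str, pd.DataFrame]
    consensus_labels: dict[str, np.ndarray]
    chosen_K: int
    label_agreement: dict[str, float]
    factor_similarity: dict[int, np.ndarray]
    cfa_fits: dict[int, CfaFit]
    manifest: list[dict] = field(default_factory=list)


def run_full_study(
    table: BehavioralTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    candidate_k: list[int] | None = None,
) -> StudyReport:
    """Run the whole discovery/replication workflow on one table.

    ``candidate_k`` restricts which dimensionalities are carried into
    the replication comparison and CFA (default: the k values flagged
    by all three model-selection criteria, or the best-supported k if
    none pass every criterion). CFA patterns are derived from the
    discovery solutions only and evaluated on the replication
    correlation matrix — never refit on discovery.
    """
    cfg = config or PipelineConfig()
    manifest: list[dict] = []
    t0 = time.time()

    def stage(name: str, **extra) -> None:
        manifest.append({"stage": name, "elapsed_s": round(time.time() - t0, 2), **extra})

    selected, report = select_variables(table)
    stage("select_variables", kept=len(report.kept), dropped=len(report.dropped))

    disc_raw, repl_raw = split_by_family(selected, seed=cfg.seed)
    stage("split_by_family", discovery=disc_raw.n_subjects, replication=repl_raw.n_subjects)

    disc = preprocess_subset(
        disc_raw, cfg.n_imputation_iterations, seed=cfg.seed + 1, invert=cfg.invert
    )
    repl = preprocess_subset(
        repl_raw, cfg.n_imputation_iterations, seed=cfg.seed + 2, invert=cfg.invert
    )
    stage("preprocess")

    X_disc = disc.values.to_numpy()
    X_repl = repl.values.to_numpy()

    dim = evaluate_dimensionality(
        X_disc,
        k_max=cfg.k_max,
        n_pa_reps=cfg.n_pa_reps,
        n_robustness_iter=cfg.n_robustness_iter,
        subsample_fraction=cfg.subsample_fraction,
        robustness_threshold=cfg.robustness_threshold,
        interpretability_threshold=cfg.interpretability_threshold,
        seed=cfg.seed + 3,
    )
    k_max = int(dim.table["k"].max())
    stage("model_selection", crossover=dim.parallel.crossover, k_max=k_max)

    hier = build_hierarchy(X_disc, k_max) if k_max >= 2 else None
    stage("hierarchy")

    K_values = cfg.K_values or list(range(2, max(k_max, 3) + 1))
    cons_tables: dict[str, pd.DataFrame] = {}
    cons_labels: dict[str, np.ndarray] = {}
    matrices = {}
    for name, X in (("discovery", X_disc), ("replication", X_repl)):
        mats, diag = cc.consensus_sweep(
            X,
            K_values,
            n_iter=cfg.n_consensus_iter,
            fraction=cfg.consensus_fraction,
            n_init=cfg.kmeans_n_init,
            seed=cfg.seed + 4,
        )
        cons_tables[name] = diag
        matrices[name] = mats
    chosen_K = int(
        cons_tables["discovery"].loc[cons_tables["discovery"]["consensus_score"].idxmax(), "K"]
    )
    for name in ("discovery", "replication"):
        cons_labels[name] = cc.final_labels(
            matrices[name][chosen_K], chosen_K, seed=cfg.seed + 5, n_init=cfg.kmeans_n_init
        )
    agreement = {
        "ari": cc.adjusted_rand(cons_labels["discovery"], cons_labels["replication"]),
        "ami": cc.adjusted_mutual_info(cons_labels["discovery"], cons_labels["replication"]),
    }
    stage("consensus", chosen_K=chosen_K, **agreement)

    if candidate_k is None:
        flagged = dim.flagged_k()
        candidate_k = flagged or [k_max]
    factor_similarity: dict[int, np.ndarray] = {}
    cfa_fits: dict[int, CfaFit] = {}
    S_repl = pd.DataFrame(
        np.corrcoef(X_repl, rowvar=False), index=repl.variables, columns=repl.variables
    )
    for k in candidate_k:
        sol_d = dim.solutions.get(k) or fit_efa(disc.values, k)
        sol_d.variable_names = disc.variables
        sol_r = fit_efa(repl.values, k)
        _, matched = compare_solutions(sol_d, sol_r)
        factor_similarity[k] = matched
        try:
            pattern = pattern_from_efa(
                sol_d, threshold=cfg.cfa_threshold, factor_covs_free=cfg.cfa_factor_covs_free
            )
            cfa_fits[k] = fit_cfa(S_repl, pattern, n_obs=repl.n_subjects)
        except (ValueError, np.linalg.LinAlgError) as err:
            manifest.append({"stage": f"cfa_k{k}", "error": str(err)})
    stage("replication_comparison_and_cfa", candidate_k=list(candidate_k))

    study = StudyReport(
        config=cfg,
        selection=report,
        discovery=disc,
        replication=repl,
        dimensionality=dim,
        hierarchy=hier,
        consensus_tables=cons_tables,
        consensus_labels=cons_labels,
        chosen_K=chosen_K,
        label_agreement=agreement,
        factor_similarity=factor_similarity,
        cfa_fits=cfa_fits,
        manifest=manifest,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: StudyReport, out_dir: str | Path) -> None:
    """Write all tabular artifacts as CSV and summaries as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "selection_report.json").write_text(json.dumps(study.selection.to_dict(), indent=1))
    study.dimensionality.table.to_csv(out / "model_selection.csv", index=False)
    study.dimensionality.parallel.to_frame().to_csv(out / "parallel_analysis.csv", index=False)
    if study.hierarchy is not None:
        study.hierarchy.write(out)
    for name, tab in study.consensus_tables.items():
        tab.to_csv(out / f"consensus_{name}.csv", index=False)
    for name, labels in study.consensus_labels.items():
        pd.DataFrame(
            {"variable": study.discovery.variables, "cluster": labels}
        ).to_csv(out / f"labels_{name}.csv", index=False)
    for k, sol in study.dimensionality.solutions.items():
        sol.variable_names = study.discovery.variables
        sol.loadings_frame().to_csv(out / f"loadings_discovery_k{k}.csv")
    summary = {
        "config": study.config.to_dict(),
        "chosen_K": study.chosen_K,
        "label_agreement": study.label_agreement,
        "flagged_k": study.dimensionality.flagged_k(),
        "factor_similarity": {str(k): v.tolist() for k, v in study.factor_similarity.items()},
        "cfa": {str(k): f.summary() for k, f in study.cfa_fits.items()},
        "manifest": study.manifest,
    }
    (out / "study_summary.json").write_text(json.dumps(summary, indent=1))
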