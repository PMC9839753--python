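"""Factor hierarchy: flow of variance across factor solutions.

Solutions with k = 1..k_max factors are stacked into levels. Bartlett
factor scores are computed at every level and correlated between
consecutive levels; the absolute correlation between a factor at
level k and a factor at level k+1 is the "flow" of variance between
them — the raw material of a Sankey diagram (e.g. one broad factor
splitting into two narrower ones as k grows).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .efa import FactorSolution, bartlett_scores, fit_efa


@dataclass
class HierarchyFlow:
    """Levels (one FactorSolution per k) and weighted parent→child edges."""

    levels: dict[int, FactorSolution]
    scores: dict[int, pd.DataFrame]
    edges: pd.DataFrame  # columns: level, parent_factor, child_factor, weight

    def nodes_frame(self) -> pd.DataFrame:
        rows = []
        for k, sol in self.levels.items():
            for f, pct in enumerate(sol.percent_variance, start=1):
                rows.append(
                    {
                        "level": k,
                        "factor": f,
                        "percent_variance": float(pct),
                        "converged": sol.converged,
                    }
                )
        return pd.DataFrame(rows)

    def to_sankey_dict(self) -> dict:
        """Node/link structure directly consumable by Sankey plotting tools."""
        nodes = self.nodes_frame()
        node_ids = {
            (int(r.level), int(r.factor)): i for i, r in enumerate(nodes.itertuples())
        }
        links = [
            {
                "source": node_ids[(int(e.level), int(e.parent_factor))],
                "target": node_ids[(int(e.level) + 1, int(e.child_factor))],
                "value": float(e.weight),
            }
            for e in self.edges.itertuples()
        ]
        return {
            "nodes": [
                {
                    "id": i,
                    "label": f"k{int(r.level)}_f{int(r.factor)}",
                    "percent_variance": float(r.percent_variance),
                }
                for i, r in enumerate(nodes.itertuples())
            ],
            "links": links,
        }

    def write(self, out_dir: str | Path, stem: str = "hierarchy") -> None:
        out = Path(out_dir)
        self.nodes_frame().to_csv(out / f"{stem}_nodes.csv", index=False)
        self.edges.to_csv(out / f"{stem}_edges.csv", index=False)
        (out / f"{stem}_sankey.json").write_text(json.dumps(self.to_sankey_dict(), indent=1))


def build_hierarchy(data: np.ndarray | pd.DataFrame, k_max: int) -> HierarchyFlow:
    """Fit k = 1..k_max, score subjects, and link consecutive levels.

    Edge weight between factor f at level k and factor g at level k+1
    is |Pearson r| of the two Bartlett score vectors, a value in
    [0, 1]. Levels that fail to converge are kept but flagged, and
    their edges omitted.
    """
    if k_max < 2:
        raise ValueError("a hierarchy needs k_max >= 2")
    X = np.asarray(data, float)
    levels: dict[int, FactorSolution] = {}
    scores: dict[int, pd.DataFrame] = {}
    for k in range(1, k_max + 1):
        sol = fit_efa(X, k)
        levels[k] = sol
        if not sol.converged:
            warnings.warn(f"level k={k} did not converge; its edges are omitted", stacklevel=2)
            continue
        scores[k] = bartlett_scores((X - X.mean(0)) / X.std(0, ddof=1), sol)

    rows = []
    for k in range(1, k_max):
        if k not in scores or (k + 1) not in scores:
            continue
        a, b = scores[k].to_numpy(), scores[k + 1].to_numpy()
        for f in range(a.shape[1]):
            for g in range(b.shape[1]):
                w = abs(float(np.corrcoef(a[:, f], b[:, g])[0, 1]))
                rows.append(
                    {"level": k, "parent_factor": f + 1, "child_factor": g + 1, "weight": w}
                )
    edges = pd.DataFrame(rows, columns=["level", "parent_factor", "child_factor", "weight"])
    return HierarchyFlow(levels=levels, scores=scores, edges=edges)
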