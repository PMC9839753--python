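"""Container for behavioral-style subject × variable tables.

A :class:`BehavioralTable` couples the numeric data matrix with the
per-variable metadata the preprocessing stage consumes (error-measure,
composite and adjusted-variant flags), optional per-subject confounds
(age, gender) and family identifiers used by the family-preserving
splitter.  Missing values are represented as NaN in ``values``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns every table carries, with their fill values
META_COLUMNS = {
    "category": "",
    "is_error_measure": False,
    "is_composite": False,
    "adjusted_of": None,
}


def _normalize_meta(meta: pd.DataFrame | None, variables: pd.Index) -> pd.DataFrame:
    if meta is None:
        meta = pd.DataFrame(index=variables)
    meta = meta.reindex(variables)
    for col, default in META_COLUMNS.items():
        if col not in meta.columns:
            meta[col] = default
        elif default is not None:
            meta[col] = meta[col].fillna(default)
    return meta[list(META_COLUMNS)]


@dataclass
class BehavioralTable:
    """Subjects × variables numeric table with metadata and confounds.

    Parameters
    ----------
    values
        DataFrame, one row per subject, one column per variable; NaN
        marks a missing observation.
    variable_meta
        DataFrame indexed by variable name. Recognized columns:
        ``category`` (str), ``is_error_measure`` (bool; reaction times
        and other measures where larger = worse), ``is_composite``
        (bool; derived from other variables in the table) and
        ``adjusted_of`` (name of the unadjusted variant this variable
        duplicates, or None). Missing columns are filled with defaults.
    confounds
        Optional DataFrame with per-subject ``age`` and ``gender``.
    family_id
        Optional per-subject family/group label.
    """

    values: pd.DataFrame
    variable_meta: pd.DataFrame | None = None
    confounds: pd.DataFrame | None = None
    family_id: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable names: {dupes}")
        self.variable_meta = _normalize_meta(self.variable_meta, self.values.columns)
        if self.confounds is not None:
            self.confounds = self.confounds.reindex(self.values.index)
        if self.family_id is not None:
            self.family_id = self.family_id.reindex(self.values.index)

    # -- basic views ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where the observation is missing."""
        return self.values.isna()

    def copy(self) -> "BehavioralTable":
        return BehavioralTable(
            values=self.values.copy(),
            variable_meta=self.variable_meta.copy(),
            confounds=None if self.confounds is None else self.confounds.copy(),
            family_id=None if self.family_id is None else self.family_id.copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "BehavioralTable":
        """New table sharing metadata/confounds but with ``values`` replaced."""
        meta = self.variable_meta.reindex(values.columns)
        return BehavioralTable(
            values=values,
            variable_meta=meta,
            confounds=None if self.confounds is None else self.confounds.loc[values.index],
            family_id=None if self.family_id is None else self.family_id.loc[values.index],
        )

    def subset_subjects(self, index) -> "BehavioralTable":
        return self.with_values(self.values.loc[index])

    def subset_variables(self, names) -> "BehavioralTable":
        return self.with_values(self.values[list(names)])

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write values as CSV (subjects as rows) plus a JSON metadata sidecar."""
        path = Path(path)
        self.values.to_csv(path, index_label="subject")
        if sidecar is None:
            sidecar = path.with_suffix(".meta.json")
        payload = {
            "variable_meta": {
                name: {
                    k: (None if pd.isna(v) else v) if k == "adjusted_of" else bool(v) if isinstance(v, (bool, np.bool_)) else v
                    for k, v in row.items()
                }
                for name, row in self.variable_meta.to_dict(orient="index").items()
            },
            "confounds": None
            if self.confounds is None
            else {c: self.confounds[c].tolist() for c in self.confounds.columns},
            "family_id": None if self.family_id is None else self.family_id.tolist(),
            "subjects": [str(s) for s in self.values.index],
        }
        Path(sidecar).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "BehavioralTable":
        path = Path(path)
        values = pd.read_csv(path, index_col="subject")
        sep = Path(sidecar) if sidecar is not None else path.with_suffix(".meta.json")
        meta = confounds = family = None
        if sep.exists():
            payload = json.loads(sep.read_text())
            meta = pd.DataFrame.from_dict(payload.get("variable_meta") or {}, orient="index")
            raw_conf = payload.get("confounds")
            if raw_conf:
                confounds = pd.DataFrame(raw_conf, index=values.index)
            raw_fam = payload.get("family_id")
            if raw_fam is not None:
                family = pd.Series(raw_fam, index=values.index, name="family_id")
        return cls(values=values, variable_meta=meta, confounds=confounds, family_id=family)
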