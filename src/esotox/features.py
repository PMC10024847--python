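"""Patients x features table with provenance tags.

Provenance routes features into the four model variants compared in the
analysis: clinical-only (cf), dosiomics-only (df), radiomics-only (rf) and
hybrid (hf = union of all three).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "PROVENANCES", "MODEL_SETS"]

PROVENANCES = ("radiomic", "dosiomic", "clinical")

MODEL_SETS: dict[str, tuple[str, ...]] = {
    "cf": ("clinical",),
    "df": ("dosiomic",),
    "rf": ("radiomic",),
    "hf": ("clinical", "dosiomic", "radiomic"),
}


class FeatureTable:
    """Complete (no missing values) numeric feature matrix with one provenance
    tag per column."""

    def __init__(self, data: pd.DataFrame, provenance: Mapping[str, str]):
        data = data.copy()
        missing_tags = [c for c in data.columns if c not in provenance]
        if missing_tags:
            raise ValueError(f"columns without provenance: {missing_tags[:5]}")
        bad = {c: provenance[c] for c in data.columns if provenance[c] not in PROVENANCES}
        if bad:
            raise ValueError(f"unknown provenance tags: {bad}")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            cols = data.columns[~np.isfinite(values).all(axis=0)]
            raise ValueError(f"non-finite feature values in columns {list(cols)[:5]}")
        self.data = data.astype(float)
        self.provenance = {c: provenance[c] for c in data.columns}

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, tags: Iterable[str]) -> "FeatureTable":
        tags = set(tags)
        cols = [c for c in self.data.columns if self.provenance[c] in tags]
        return FeatureTable(self.data[cols], self.provenance)

    def model_set(self, name: str) -> "FeatureTable":
        """Feature subset for one of the cf/df/rf/hf model variants."""
        if name not in MODEL_SETS:
            raise KeyError(f"unknown model set {name!r}; expected one of {sorted(MODEL_SETS)}")
        return self.subset(MODEL_SETS[name])

    @classmethod
    def from_records(
        cls, rows: Iterable[Mapping[str, float]], provenance: Mapping[str, str],
        index: Iterable | None = None,
    ) -> "FeatureTable":
        df = pd.DataFrame(list(rows))
        if index is not None:
            df.index = list(index)
        return cls(df, provenance)

    def to_csv(self, path: str | Path) -> Path:
        """Write the table as CSV with a sidecar ``.schema.json`` mapping
        feature name to provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, index_label="patient_id")
        schema = path.with_suffix(".schema.json")
        schema.write_text(json.dumps(self.provenance, indent=1, sort_keys=True))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="patient_id")
        schema = path.with_suffix(".schema.json")
        provenance = json.loads(schema.read_text())
        return cls(df, provenance)
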