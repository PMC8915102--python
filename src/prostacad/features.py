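"""Named feature vectors and labeled feature tables.

These are the light in-memory containers every extraction stage emits and the
selection/classification stages consume.  A :class:`FeatureTable` is a thin,
validated wrapper around the obvious pandas layout (rows = cases, columns =
features) plus a per-feature provenance tag in {functional, texture, shape,
psa}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureVector", "FeatureTable", "infer_provenance"]

PROVENANCE_PREFIXES = {
    "adc_": "functional",
    "fo_": "texture",
    "glcm_": "texture",
    "glrlm_": "texture",
    "sh_": "shape",
    "psa": "psa",
}


def infer_provenance(name: str) -> str:
    for prefix, tag in PROVENANCE_PREFIXES.items():
        if name.startswith(prefix):
            return tag
    return "other"


@dataclass
class FeatureVector:
    """Ordered, named real-valued features for one case."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError(
                f"{len(self.names)} names but {self.values.size} values"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    @staticmethod
    def concat(parts: Sequence["FeatureVector"]) -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        values = np.concatenate([p.values for p in parts])
        return FeatureVector(names, values)


@dataclass
class FeatureTable:
    """Cases x features matrix with binary labels and provenance tags."""

    case_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: np.ndarray  # 1 = malignant (positive class), 0 = benign
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cases x features)")
        if self.matrix.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.case_ids)} cases x {len(self.feature_names)} features"
            )
        if self.labels.shape != (len(self.case_ids),):
            raise ValueError("one label per case required")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature table contains non-finite values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not self.provenance:
            self.provenance = [infer_provenance(n) for n in self.feature_names]
        elif len(self.provenance) != len(self.feature_names):
            raise ValueError("one provenance tag per feature required")

    @property
    def n_cases(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def sort_cases(self) -> "FeatureTable":
        """Canonically reorder rows by case_id."""
        order = np.argsort(self.case_ids)
        return FeatureTable(
            [self.case_ids[i] for i in order],
            list(self.feature_names),
            self.matrix[order],
            self.labels[order],
            list(self.provenance),
        )

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.case_ids),
            list(names),
            self.matrix[:, idx],
            self.labels.copy(),
            [self.provenance[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "case_id", self.case_ids)
        df.insert(1, "label", np.where(self.labels == 1, "malignant", "benign"))
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "FeatureTable":
        names = [c for c in df.columns if c not in ("case_id", "label")]
        labels = (df["label"].astype(str).str.lower() == "malignant").astype(int)
        return FeatureTable(
            df["case_id"].astype(str).tolist(),
            names,
            df[names].to_numpy(dtype=float),
            labels.to_numpy(),
        )

    @staticmethod
    def from_csv(path: str | Path) -> "FeatureTable":
        return FeatureTable.from_dataframe(pd.read_csv(path))
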