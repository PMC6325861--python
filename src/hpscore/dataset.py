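"""Labeled binary feature dataset container.

A :class:`LabeledDataset` holds an n x 9 matrix of binary feature scores,
one row per protein, optionally with a binary class label (1 = hypothetical
protein / positive, 0 = functional protein / negative). The Total
Reliability Score (TRS) of a row is the row sum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL_NAMES = {1: "positive", 0: "negative"}


def feature_columns(m: int = 9) -> list[str]:
    return [f"f{i}" for i in range(1, m + 1)]


@dataclass
class LabeledDataset:
    ids: list[str]
    X: np.ndarray                      # (n, 9) int8, entries in {0, 1}
    y: np.ndarray | None = None        # (n,) int8, 1=positive, 0=negative

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError(f"X must be (n, m>=1), got {self.X.shape}")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("feature scores must be binary")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids and X row count differ")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int8)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must match row count")
            if not np.isin(self.y, (0, 1)).all():
                raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def trs(self) -> np.ndarray:
        return self.X.sum(axis=1)

    @property
    def labeled(self) -> bool:
        return self.y is not None

    def subset_rows(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
        )

    def subset_features(self, feature_ids) -> "LabeledDataset":
        """Dataset restricted to 1-based feature ids (ascending order)."""
        cols = [fid - 1 for fid in sorted(feature_ids)]
        return LabeledDataset(ids=list(self.ids), X=self.X[:, cols], y=self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=feature_columns(self.X.shape[1]))
        df.insert(0, "protein_id", self.ids)
        df["trs"] = self.trs
        if self.y is not None:
            df["label"] = [LABEL_NAMES[int(v)] for v in self.y]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        cols = [c for c in df.columns if re.fullmatch(r"f\d+", str(c))]
        X = df[cols].to_numpy(dtype=np.int8)
        y = None
        if "label" in df.columns:
            y = np.array(
                [1 if v == "positive" else 0 for v in df["label"]], dtype=np.int8
            )
        return cls(ids=[str(v) for v in df["protein_id"]], X=X, y=y)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        if self.ids != other.ids or not np.array_equal(self.X, other.X):
            return False
        if (self.y is None) != (other.y is None):
            return False
        return self.y is None or np.array_equal(self.y, other.y)
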