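"""Jaccard similarity of binary feature profiles and one-way ANOVA.

The Jaccard index of two nine-bit profiles is M11 / (M11 + M10 + M01):
matches on 1s over positions where either profile is 1. Two all-zero
profiles are identical, so their similarity is defined as 1 (flagged,
since some conventions use 0). The complement 1 - J is a metric, so the
resulting distance matrix satisfies the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import LabeledDataset


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) Jaccard coefficients in [0, 1]

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.values


def jaccard_matrix(data: LabeledDataset) -> SimilarityMatrix:
    """Pairwise Jaccard similarity of all row profiles."""
    if len(data) < 1:
        raise ValueError("need at least one row")
    X = data.X.astype(float)
    m11 = X @ X.T
    row_sums = X.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - m11
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(union > 0, m11 / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(J, 1.0)
    return SimilarityMatrix(ids=list(data.ids), values=J)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    significant: bool | None
    alpha: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "p": self.p,
            "significant": self.significant,
            "alpha": self.alpha,
            "degenerate": self.degenerate,
        }


def anova_oneway(groups: list[np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    ``significant`` is p < alpha. Zero within-group variance makes F
    undefined; the result is returned with ``degenerate=True`` and NaN
    statistics rather than a spurious decision.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    n = sum(g.size for g in groups)
    df_between = k - 1
    df_within = n - k
    if df_within <= 0:
        raise ValueError("non-positive within-group degrees of freedom")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0.0:
        return AnovaResult(
            F=float("nan"), p=float("nan"), significant=None,
            alpha=alpha, degenerate=True,
        )
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), p=p, significant=bool(p < alpha), alpha=alpha)


def class_feature_groups(data: LabeledDataset, positive: bool) -> list[np.ndarray]:
    """Per-feature score columns of one class, the default ANOVA grouping."""
    if data.y is None:
        raise ValueError("grouping by class needs labels")
    mask = data.y == (1 if positive else 0)
    X = data.X[mask].astype(float)
    return [X[:, j] for j in range(X.shape[1])]
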