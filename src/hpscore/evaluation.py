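"""Confusion-matrix metrics and evaluation protocols.

Two protocols are provided, matching the study design: stratified k-fold
cross-validation (default k = 10) and repeated random train/test splits
(default 66 % training fraction, 1000 iterations) whose accuracies are
averaged, with min/max reported alongside.

Six metrics are computed from the confusion counts: accuracy, sensitivity
(recall), specificity, precision, F1, and Matthews correlation coefficient.
MCC uses the standard square-rooted denominator by default, which keeps it
in [-1, 1]; the unrooted variant is available for audit. Undefined ratios
(zero denominators) surface as NaN plus an entry in ``undefined`` — never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dataset import LabeledDataset

ClassifierFactory = Callable[[LabeledDataset], "object"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, truth: np.ndarray, pred: np.ndarray
                         ) -> "ConfusionCounts":
        truth = np.asarray(truth)
        pred = np.asarray(pred)
        return cls(
            tp=int(np.sum((truth == 1) & (pred == 1))),
            tn=int(np.sum((truth == 0) & (pred == 0))),
            fp=int(np.sum((truth == 0) & (pred == 1))),
            fn=int(np.sum((truth == 1) & (pred == 0))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    counts: ConfusionCounts
    undefined: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "undefined": sorted(self.undefined),
        }


def compute_metrics(
    counts: ConfusionCounts, mcc_sqrt_denominator: bool = True
) -> MetricsReport:
    """All six metrics from the confusion counts.

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)          specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)          F1 = 2 PR / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    ``mcc_sqrt_denominator=False`` drops the square root (an unnormalized
    variant that is not bounded in [-1, 1], kept for audit).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / counts.total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if math.isnan(precision) or math.isnan(sensitivity):
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = ratio(2 * precision * sensitivity, precision + sensitivity, "f1")
    den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        num = float(tp) * tn - float(fp) * fn
        mcc = num / (math.sqrt(den) if mcc_sqrt_denominator else den)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        counts=counts,
        undefined=frozenset(undefined),
    )


@dataclass(frozen=True)
class SplitPlan:
    protocol: str = "kfold"          # kfold | repeated_split
    k: int = 10
    train_fraction: float = 0.66
    iterations: int = 1000
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("kfold", "repeated_split"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "k": self.k,
            "train_fraction": self.train_fraction,
            "iterations": self.iterations,
            "stratified": self.stratified,
            "seed": self.seed,
        }


def kfold_indices(
    y: np.ndarray | None, n: int, k: int, stratified: bool, seed: int
) -> list[np.ndarray]:
    """Test-fold index arrays: pairwise disjoint, union = all rows.

    Stratified assignment shuffles within each class (seeded) and gives
    each fold floor(n_c / k) or one extra row of class c, steering the
    extras to the currently smallest folds — per-fold class proportions
    stay within one row of global, and fold sizes are as equal as possible
    (exactly n/k when k divides n).
    """
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    sizes = [0] * k

    def deal(idx: np.ndarray) -> None:
        rng.shuffle(idx)
        base, rem = divmod(idx.size, k)
        order = sorted(range(k), key=lambda f: (sizes[f], f))
        start = 0
        for pos, f in enumerate(order):
            take = base + (1 if pos < rem else 0)
            folds[f].extend(int(r) for r in idx[start:start + take])
            sizes[f] += take
            start += take

    if stratified and y is not None:
        for cls in (1, 0):
            idx = np.flatnonzero(y == cls)
            if 0 < idx.size < k:
                raise ValueError(
                    f"class {cls} has {idx.size} rows, fewer than k={k}"
                )
            deal(idx)
    else:
        deal(np.arange(n))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def stratified_kfold_cv(
    data: LabeledDataset,
    fit: ClassifierFactory,
    plan: SplitPlan | None = None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation; returns (per-fold reports, pooled report).

    The pooled report aggregates confusion counts over folds, so no test
    row is counted twice and the pooled accuracy is the fraction of all
    rows predicted correctly out of sample.
    """
    plan = plan or SplitPlan()
    if data.y is None:
        raise ValueError("cross-validation needs a labeled dataset")
    folds = kfold_indices(data.y, len(data), plan.k, plan.stratified, plan.seed)
    all_idx = np.arange(len(data))
    reports = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = fit(data.subset_rows(train_idx))
        pred = model.predict(data.X[test_idx])
        counts = ConfusionCounts.from_predictions(data.y[test_idx], pred)
        reports.append(compute_metrics(counts))
        pooled = pooled + counts
    return reports, compute_metrics(pooled)


@dataclass(frozen=True)
class RepeatedSplitResult:
    mean_accuracy: float
    max_accuracy: float
    min_accuracy: float
    trace: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "max_accuracy": self.max_accuracy,
            "min_accuracy": self.min_accuracy,
            "iterations": len(self.trace),
        }


def _split_once(
    y: np.ndarray, frac: float, stratified: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    if stratified:
        train_parts, test_parts = [], []
        for cls in (1, 0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_train = int(round(frac * idx.size))
            train_parts.append(idx[:n_train])
            test_parts.append(idx[n_train:])
        return np.sort(np.concatenate(train_parts)), np.sort(
            np.concatenate(test_parts)
        )
    idx = rng.permutation(n)
    n_train = int(round(frac * n))
    return np.sort(idx[:n_train]), np.sort(idx[n_train:])


def repeated_random_split_eval(
    data: LabeledDataset,
    fit: ClassifierFactory,
    plan: SplitPlan | None = None,
) -> RepeatedSplitResult:
    """Repeated random train/test splits, fresh model per iteration.

    Each iteration draws an independent seeded split at ``train_fraction``,
    trains from scratch, and measures accuracy on the held-out rows only;
    mean/max/min over the trace are returned.
    """
    plan = plan or SplitPlan(protocol="repeated_split")
    if plan.protocol != "repeated_split":
        raise ValueError("plan.protocol must be 'repeated_split'")
    if data.y is None:
        raise ValueError("evaluation needs a labeled dataset")
    rng = np.random.default_rng(plan.seed)
    trace = []
    for _ in range(plan.iterations):
        train_idx, test_idx = _split_once(
            data.y, plan.train_fraction, plan.stratified, rng
        )
        if train_idx.size == 0 or test_idx.size == 0:
            raise ValueError("train or test side of the split is empty")
        model = fit(data.subset_rows(train_idx))
        pred = model.predict(data.X[test_idx])
        trace.append(float(np.mean(pred == data.y[test_idx])))
    return RepeatedSplitResult(
        mean_accuracy=float(np.mean(trace)),
        max_accuracy=float(np.max(trace)),
        min_accuracy=float(np.min(trace)),
        trace=tuple(trace),
    )
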