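"""Feature ranking and subset selection over the nine-bit score matrix.

Implements the selection analyses run on the study data: correlation-based
feature selection (CFS) with best-first search, a PCA-based ranking of the
original features, exhaustive evaluation of all non-empty feature subsets
under a cross-validation plan, pairwise Pearson correlations between the
binary feature columns (the phi coefficient), and a single-feature impact
ranking with competition (tied) ranks.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import LabeledDataset
from .evaluation import ClassifierFactory, SplitPlan, stratified_kfold_cv, \
    repeated_random_split_eval


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cfs_merit(
    subset: tuple[int, ...], rcf: dict[int, float], rff: dict[tuple[int, int], float]
) -> float:
    """CFS merit: k * mean|r_fc| / sqrt(k + k(k-1) * mean|r_ff|)."""
    k = len(subset)
    mean_rcf = float(np.mean([abs(rcf[f]) for f in subset]))
    if k == 1:
        return mean_rcf
    pairs = list(itertools.combinations(sorted(subset), 2))
    mean_rff = float(np.mean([abs(rff[p]) for p in pairs]))
    return k * mean_rcf / math.sqrt(k + k * (k - 1) * mean_rff)


def cfs_select(data: LabeledDataset, patience: int = 5) -> set[int]:
    """Best-first forward search maximizing the CFS merit.

    Expansion starts from the empty set; subsets are expanded in
    best-merit-first order, children add one feature each; the search stops
    after ``patience`` consecutive expansions that fail to improve the best
    merit. Ties break lexicographically, so the result is deterministic.
    Constant feature columns are excluded up front (their correlation with
    anything is undefined) with a warning.
    """
    if data.y is None:
        raise ValueError("CFS needs class labels")
    X, y = data.X.astype(float), data.y.astype(float)
    m = X.shape[1]
    usable = []
    for j in range(m):
        if X[:, j].std() == 0:
            warnings.warn(
                f"feature f{j + 1} is constant; excluded from CFS",
                stacklevel=2,
            )
        else:
            usable.append(j + 1)
    if len(usable) < 1:
        raise ValueError("no non-constant features")
    rcf = {f: _safe_corr(X[:, f - 1], y) for f in usable}
    rff = {
        (a, b): _safe_corr(X[:, a - 1], X[:, b - 1])
        for a, b in itertools.combinations(usable, 2)
    }

    open_list: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    visited: set[tuple[int, ...]] = {()}
    best_subset: tuple[int, ...] = ()
    best_merit = -np.inf
    stale = 0
    while open_list and stale < patience:
        # pop the best-merit subset; ties -> lexicographically smallest
        open_list.sort(key=lambda t: (-t[0], t[1]))
        _, current = open_list.pop(0)
        improved = False
        for f in usable:
            if f in current:
                continue
            child = tuple(sorted(current + (f,)))
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, rcf, rff)
            open_list.append((merit, child))
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
        stale = 0 if improved else stale + 1
    return set(best_subset)


@dataclass(frozen=True)
class PCARanking:
    order: tuple[int, ...]              # feature ids, most important first
    weights: dict[int, float]           # variance-weighted |loading| sums
    variance_fractions: tuple[float, ...]
    loadings: np.ndarray                # (m, m) columns = components


def pca_rank(data: LabeledDataset) -> PCARanking:
    """Rank original features by variance-weighted PCA loadings.

    Principal components of the centered score matrix; each feature's
    weight is sum_c |loading_{feature,c}| * (variance fraction of c).
    Eigenvectors carry a deterministic sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if len(data) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = data.X.astype(float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    if np.allclose(cov, 0):
        raise ValueError("zero-variance matrix")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    for c in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, c]))
        if eigvecs[pivot, c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    fractions = eigvals / eigvals.sum()
    weights = np.abs(eigvecs) @ fractions
    m = X.shape[1]
    ranked = sorted(range(m), key=lambda j: (-weights[j], j))
    return PCARanking(
        order=tuple(j + 1 for j in ranked),
        weights={j + 1: float(weights[j]) for j in range(m)},
        variance_fractions=tuple(float(f) for f in fractions),
        loadings=eigvecs,
    )


@dataclass(frozen=True)
class SubsetResult:
    subset: tuple[int, ...]
    accuracy: float
    n_features: int


def _plan_accuracy(
    data: LabeledDataset, fit: ClassifierFactory, plan: SplitPlan
) -> float:
    if plan.protocol == "kfold":
        _, pooled = stratified_kfold_cv(data, fit, plan)
        return pooled.accuracy
    return repeated_random_split_eval(data, fit, plan).mean_accuracy


def exhaustive_subset_search(
    data: LabeledDataset,
    fit: ClassifierFactory,
    plan: SplitPlan | None = None,
) -> tuple[SubsetResult, list[SubsetResult]]:
    """Evaluate every non-empty feature subset under the plan.

    Returns the arg-max accuracy subset (ties resolve to the smaller
    subset, then lexicographically) and the full 2^m - 1 row table.
    """
    plan = plan or SplitPlan()
    m = data.X.shape[1]
    feature_ids = list(range(1, m + 1))
    table: list[SubsetResult] = []
    for size in range(1, m + 1):
        for subset in itertools.combinations(feature_ids, size):
            acc = _plan_accuracy(data.subset_features(subset), fit, plan)
            table.append(SubsetResult(subset, acc, size))
    best = min(table, key=lambda r: (-r.accuracy, r.n_features, r.subset))
    return best, table


@dataclass(frozen=True)
class CorrelationReport:
    pairs: tuple[tuple[int, int, float, float], ...]  # (i, j, r, p_two_tailed)

    def r(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        a, b = min(i, j), max(i, j)
        for pi, pj, r, _ in self.pairs:
            if (pi, pj) == (a, b):
                return r
        raise KeyError((i, j))


def pearson_feature_correlations(data: LabeledDataset) -> CorrelationReport:
    """All unordered feature-pair Pearson correlations with two-tailed p.

    On binary columns Pearson r is the phi coefficient; p-values come from
    the exact t-transform with n - 2 degrees of freedom. Constant columns
    yield NaN entries with a warning.
    """
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 rows for correlation p-values")
    X = data.X.astype(float)
    m = X.shape[1]
    pairs = []
    for i, j in itertools.combinations(range(m), 2):
        a, b = X[:, i], X[:, j]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(
                f"constant column in pair (f{i + 1}, f{j + 1}); r undefined",
                stacklevel=2,
            )
            pairs.append((i + 1, j + 1, float("nan"), float("nan")))
            continue
        r = _safe_corr(a, b)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        pairs.append((i + 1, j + 1, r, p))
    return CorrelationReport(pairs=tuple(pairs))


def rank_feature_impact(
    data: LabeledDataset,
    fit: ClassifierFactory,
    plan: SplitPlan | None = None,
) -> dict[int, int]:
    """Single-feature predictive impact with competition ranking.

    Each feature is evaluated alone under the plan; features are ranked by
    accuracy descending. Tied accuracies share the better rank and the
    following ranks are skipped (1, 2, 2, 4, ...), matching how tied
    impact ranks are conventionally reported.
    """
    plan = plan or SplitPlan()
    m = data.X.shape[1]
    accs = {
        f: _plan_accuracy(data.subset_features([f]), fit, plan)
        for f in range(1, m + 1)
    }
    ordered = sorted(accs, key=lambda f: (-accs[f], f))
    ranks: dict[int, int] = {}
    for pos, f in enumerate(ordered):
        if pos > 0 and accs[f] == accs[ordered[pos - 1]]:
            ranks[f] = ranks[ordered[pos - 1]]
        else:
            ranks[f] = pos + 1
    return ranks
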