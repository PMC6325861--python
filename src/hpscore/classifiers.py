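"""From-scratch classifiers over nine-bit feature vectors.

Four families, matching the study design:

* pocket perceptron — online perceptron with a unit-step activation that
  keeps ("pockets") the weight vector with the best training accuracy seen
  so far, so non-separable data still yields the best linear rule visited;
* Bernoulli naive Bayes with additive (Laplace) smoothing;
* decision tree with gain-ratio splits on binary features;
* soft-margin SVM trained by sequential minimal optimization (SMO).

All models share a small contract: ``predict`` maps any (n, m) binary
matrix to labels in {0, 1} (1 = positive / hypothetical protein), ties in
the decision rule resolve to the negative (majority) class, and fitted
state serializes to a JSON-compatible dict that round-trips to identical
predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset


@dataclass(frozen=True)
class PerceptronConfig:
    eta: float = 0.2              # positive learning-rate scale factor
    n_iterations: int = 1000      # number of single-example presentations
    include_bias: bool = False    # weight vector length 9 by default
    seed: int = 0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


class ClassifierModel:
    """Common surface of the four fitted-model families."""

    family: str = ""
    training_accuracy: float = float("nan")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    #: decision values this close to 0 count as ties (float-noise guard)
    TIE_EPS = 1e-9

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {0,1}; ties (decision value 0) go to the negative class."""
        X = np.atleast_2d(np.asarray(X))
        return (self.decision_values(X) > self.TIE_EPS).astype(np.int8)

    def to_dict(self) -> dict:
        raise NotImplementedError


def _training_accuracy(model: ClassifierModel, data: LabeledDataset) -> float:
    return float(np.mean(model.predict(data.X) == data.y))


# ---------------------------------------------------------------------------
# pocket perceptron


class PocketPerceptron(ClassifierModel):
    family = "perceptron"

    def __init__(self, weights: np.ndarray, include_bias: bool,
                 accuracy_trace: list[float] | None = None):
        self.weights = np.asarray(weights, dtype=float)
        self.include_bias = include_bias
        #: pocket training accuracy after each example presentation
        self.accuracy_trace = accuracy_trace or []
        if self.accuracy_trace:
            self.training_accuracy = self.accuracy_trace[-1]

    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.include_bias:
            return np.hstack([X, np.ones((X.shape[0], 1))])
        return np.asarray(X, dtype=float)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self._design(np.atleast_2d(X)) @ self.weights

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "weights": self.weights.tolist(),
            "include_bias": self.include_bias,
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PocketPerceptron":
        m = cls(np.array(d["weights"]), d["include_bias"])
        m.training_accuracy = d.get("training_accuracy", float("nan"))
        return m


def fit_pocket_perceptron(
    train: LabeledDataset, config: PerceptronConfig | None = None
) -> PocketPerceptron:
    """Online perceptron with the pocket rule.

    Updates w <- w + eta * (y - yhat) * x with unit-step activation
    (yhat = 1 iff w.x > 0), starting from a seeded standard-normal weight
    vector. Examples are presented in seeded-shuffled epoch order for
    ``n_iterations`` presentations; whenever an update improves training
    accuracy over the best seen, the weights are copied into the pocket.
    The returned model predicts with the pocket weights.
    """
    config = config or PerceptronConfig()
    if len(train) == 0 or train.y is None:
        raise ValueError("training set must be non-empty and labeled")
    rng = np.random.default_rng(config.seed)
    X = train.X.astype(float)
    if config.include_bias:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    y = train.y.astype(float)
    n, m = X.shape

    w = rng.standard_normal(m)
    pocket = w.copy()

    def acc(weights: np.ndarray) -> float:
        return float(np.mean((X @ weights > 0) == (y == 1)))

    best = acc(w)
    trace: list[float] = []
    order = np.empty(0, dtype=int)
    pos = 0
    for _ in range(config.n_iterations):
        if pos >= len(order):
            order = rng.permutation(n)
            pos = 0
        i = order[pos]
        pos += 1
        yhat = 1.0 if X[i] @ w > 0 else 0.0
        if yhat != y[i]:
            w = w + config.eta * (y[i] - yhat) * X[i]
            a = acc(w)
            if a > best:
                best = a
                pocket = w.copy()
        trace.append(best)

    model = PocketPerceptron(pocket, config.include_bias, accuracy_trace=trace)
    model.training_accuracy = best
    return model


# ---------------------------------------------------------------------------
# Bernoulli naive Bayes


class BernoulliNaiveBayes(ClassifierModel):
    family = "naive_bayes"

    def __init__(self, log_prior: np.ndarray, log_p1: np.ndarray,
                 log_p0: np.ndarray):
        # log_prior: (2,) for classes (negative, positive)
        # log_p1[c, j] = log P(f_j = 1 | class c); log_p0 the complement
        self.log_prior = np.asarray(log_prior, dtype=float)
        self.log_p1 = np.asarray(log_p1, dtype=float)
        self.log_p0 = np.asarray(log_p0, dtype=float)

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))
        for c in range(2):
            # selection instead of multiplication: a zero-probability
            # feature (alpha = 0) contributes -inf, never 0 * -inf = nan
            terms = np.where(X >= 0.5, self.log_p1[c][None, :],
                             self.log_p0[c][None, :])
            out[:, c] = self.log_prior[c] + terms.sum(axis=1)
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        jll = jll - jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        # tie (equal posteriors) -> 0 -> negative class
        return jll[:, 1] - jll[:, 0]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "log_prior": self.log_prior.tolist(),
            "log_p1": self.log_p1.tolist(),
            "log_p0": self.log_p0.tolist(),
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BernoulliNaiveBayes":
        m = cls(np.array(d["log_prior"]), np.array(d["log_p1"]),
                np.array(d["log_p0"]))
        m.training_accuracy = d.get("training_accuracy", float("nan"))
        return m


def fit_bernoulli_naive_bayes(
    train: LabeledDataset, laplace_alpha: float = 1.0
) -> BernoulliNaiveBayes:
    """Bernoulli event model with additive smoothing alpha on conditionals.

    P(f_j = 1 | c) = (count_1 + alpha) / (n_c + 2 alpha); class priors are
    unsmoothed relative frequencies. alpha = 0 is allowed: zero
    probabilities become -inf log-likelihood (a zero-probability
    short-circuit), which is well defined under argmax.
    """
    if laplace_alpha < 0:
        raise ValueError("laplace_alpha must be >= 0")
    if len(train) == 0 or train.y is None:
        raise ValueError("training set must be non-empty and labeled")
    X, y = train.X.astype(float), train.y
    n = len(train)
    with np.errstate(divide="ignore"):
        log_prior = np.log(
            np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float) / n
        )
        log_p1 = np.empty((2, X.shape[1]))
        log_p0 = np.empty((2, X.shape[1]))
        for c in range(2):
            Xc = X[y == c]
            nc = Xc.shape[0]
            p1 = (Xc.sum(axis=0) + laplace_alpha) / (nc + 2 * laplace_alpha)
            log_p1[c] = np.log(p1)
            log_p0[c] = np.log(1.0 - p1)
    model = BernoulliNaiveBayes(log_prior, log_p1, log_p0)
    model.training_accuracy = _training_accuracy(model, train)
    return model


# ---------------------------------------------------------------------------
# decision tree (gain-ratio splits on binary features)


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Node:
    feature: int | None = None      # 0-based column; None for a leaf
    prediction: int | None = None
    left: "_Node | None" = None     # feature value 0
    right: "_Node | None" = None    # feature value 1

    def to_dict(self) -> dict:
        if self.feature is None:
            return {"leaf": int(self.prediction)}
        return {
            "feature": self.feature,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "leaf" in d:
            return cls(prediction=d["leaf"])
        return cls(
            feature=d["feature"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


class DecisionTree(ClassifierModel):
    family = "decision_tree"

    def __init__(self, root: _Node):
        self.root = root

    def _predict_one(self, x: np.ndarray) -> int:
        node = self.root
        while node.feature is not None:
            node = node.right if x[node.feature] == 1 else node.left
        return node.prediction

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        return np.array([self._predict_one(x) for x in X], dtype=np.int8)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        # leaves are hard class assignments; expose +-1 for the shared API
        return self.predict(X).astype(float) * 2.0 - 1.0

    def depth(self) -> int:
        def d(node: _Node) -> int:
            if node.feature is None:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "root": self.root.to_dict(),
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        m = cls(_Node.from_dict(d["root"]))
        m.training_accuracy = d.get("training_accuracy", float("nan"))
        return m


def fit_decision_tree(
    train: LabeledDataset, min_leaf: int = 2, use_gain_ratio: bool = True
) -> DecisionTree:
    """Recursive binary splitting on 0/1 features.

    Splits maximize gain ratio (information gain divided by the split's own
    entropy) or plain information gain; features constant within a node are
    unusable. Recursion stops at pure nodes, nodes smaller than
    ``min_leaf``, or nodes with no usable feature. Leaves predict the
    majority class, ties going negative. Deterministic: equal-criterion
    splits resolve to the lowest feature index.
    """
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    if len(train) == 0 or train.y is None:
        raise ValueError("training set must be non-empty and labeled")
    X, y = train.X, train.y

    def majority(idx: np.ndarray) -> int:
        pos = int(np.sum(y[idx] == 1))
        neg = idx.size - pos
        return 1 if pos > neg else 0

    def build(idx: np.ndarray) -> _Node:
        labels = y[idx]
        if idx.size < min_leaf or len(np.unique(labels)) == 1:
            return _Node(prediction=majority(idx))
        parent_entropy = _entropy(np.bincount(labels, minlength=2))
        best_feat, best_crit = None, -np.inf
        for j in range(X.shape[1]):
            col = X[idx, j]
            n1 = int(col.sum())
            n0 = idx.size - n1
            if n0 == 0 or n1 == 0:
                continue  # constant here: split info zero, unusable
            h0 = _entropy(np.bincount(labels[col == 0], minlength=2))
            h1 = _entropy(np.bincount(labels[col == 1], minlength=2))
            gain = parent_entropy - (n0 * h0 + n1 * h1) / idx.size
            if use_gain_ratio:
                split_info = _entropy(np.array([n0, n1]))
                crit = gain / split_info
            else:
                crit = gain
            if crit > best_crit + 1e-12:
                best_crit, best_feat = crit, j
        if best_feat is None:
            return _Node(prediction=majority(idx))
        col = X[idx, best_feat]
        return _Node(
            feature=best_feat,
            left=build(idx[col == 0]),
            right=build(idx[col == 1]),
        )

    tree = DecisionTree(build(np.arange(len(train))))
    tree.training_accuracy = _training_accuracy(tree, train)
    return tree


# ---------------------------------------------------------------------------
# SVM via sequential minimal optimization


@dataclass(frozen=True)
class KernelSpec:
    name: str = "poly"         # linear | poly | rbf | normalized_poly
    degree: int = 1
    gamma: float = 0.5

    def __post_init__(self):
        if self.name not in ("linear", "poly", "rbf", "normalized_poly"):
            raise ValueError(f"unknown kernel {self.name!r}")

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        if self.name == "linear":
            return A @ B.T
        if self.name == "rbf":
            sq = (
                (A * A).sum(1)[:, None]
                - 2.0 * (A @ B.T)
                + (B * B).sum(1)[None, :]
            )
            return np.exp(-self.gamma * sq)
        K = (A @ B.T + 1.0) ** self.degree
        if self.name == "poly":
            return K
        ka = (np.einsum("ij,ij->i", A, A) + 1.0) ** self.degree
        kb = (np.einsum("ij,ij->i", B, B) + 1.0) ** self.degree
        return K / np.sqrt(ka[:, None] * kb[None, :])

    def to_dict(self) -> dict:
        return {"name": self.name, "degree": self.degree, "gamma": self.gamma}


class SVM(ClassifierModel):
    family = "svm"

    def __init__(self, support_X: np.ndarray, support_ay: np.ndarray,
                 b: float, kernel: KernelSpec):
        self.support_X = np.asarray(support_X, dtype=float)
        self.support_ay = np.asarray(support_ay, dtype=float)  # alpha_i * y_i
        self.b = float(b)
        self.kernel = kernel

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.support_X.shape[0] == 0:
            return np.full(X.shape[0], self.b)
        return self.kernel.gram(X, self.support_X) @ self.support_ay + self.b

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "support_X": self.support_X.tolist(),
            "support_ay": self.support_ay.tolist(),
            "b": self.b,
            "kernel": self.kernel.to_dict(),
            "training_accuracy": self.training_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVM":
        sx = np.array(d["support_X"], dtype=float)
        if sx.ndim != 2:
            sx = sx.reshape(0, 1)
        m = cls(sx, np.array(d["support_ay"]), d["b"], KernelSpec(**d["kernel"]))
        m.training_accuracy = d.get("training_accuracy", float("nan"))
        return m


def fit_svm_smo(
    train: LabeledDataset,
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    tol: float = 1e-3,
    max_passes: int = 10,
    max_iter: int = 20000,
    seed: int = 0,
) -> SVM:
    """Soft-margin SVM dual solved by simplified SMO.

    Optimizes pairs of multipliers until every example satisfies the KKT
    conditions within ``tol``. The dual constraints 0 <= alpha_i <= C and
    sum alpha_i y_i = 0 hold at every step by construction. Pair selection
    is seeded, so training is deterministic.
    """
    if len(train) == 0 or train.y is None:
        raise ValueError("training set must be non-empty and labeled")
    y01 = train.y
    if len(np.unique(y01)) < 2:
        raise ValueError("SVM training requires both classes")
    kernel = kernel or KernelSpec()
    rng = np.random.default_rng(seed)
    X = train.X.astype(float)
    y = y01.astype(float) * 2.0 - 1.0
    n = len(y)
    K = kernel.gram(X, X)
    alpha = np.zeros(n)
    b = 0.0
    passes = 0
    it = 0
    while passes < max_passes and it < max_iter:
        changed = 0
        for i in range(n):
            it += 1
            Ei = (alpha * y) @ K[:, i] + b - y[i]
            if (y[i] * Ei < -tol and alpha[i] < C) or (
                y[i] * Ei > tol and alpha[i] > 0
            ):
                j = int(rng.integers(0, n - 1))
                if j >= i:
                    j += 1
                Ej = (alpha * y) @ K[:, j] + b - y[j]
                ai_old, aj_old = alpha[i], alpha[j]
                if y[i] != y[j]:
                    L = max(0.0, aj_old - ai_old)
                    H = min(C, C + aj_old - ai_old)
                else:
                    L = max(0.0, ai_old + aj_old - C)
                    H = min(C, ai_old + aj_old)
                if H - L < 1e-12:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = aj_old - y[j] * (Ei - Ej) / eta
                aj = min(H, max(L, aj))
                if abs(aj - aj_old) < 1e-7:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alpha[i], alpha[j] = ai, aj
                b1 = (
                    b - Ei
                    - y[i] * (ai - ai_old) * K[i, i]
                    - y[j] * (aj - aj_old) * K[i, j]
                )
                b2 = (
                    b - Ej
                    - y[i] * (ai - ai_old) * K[i, j]
                    - y[j] * (aj - aj_old) * K[j, j]
                )
                if 0 < ai < C:
                    b = b1
                elif 0 < aj < C:
                    b = b2
                else:
                    b = (b1 + b2) / 2.0
                changed += 1
        passes = passes + 1 if changed == 0 else 0

    sv = alpha > 1e-8
    model = SVM(X[sv], alpha[sv] * y[sv], b, kernel)
    model.alphas_ = alpha
    model.training_accuracy = _training_accuracy(model, train)
    return model


# ---------------------------------------------------------------------------
# serialization dispatch

_FAMILIES = {
    "perceptron": PocketPerceptron,
    "naive_bayes": BernoulliNaiveBayes,
    "decision_tree": DecisionTree,
    "svm": SVM,
}


def model_from_dict(d: dict) -> ClassifierModel:
    try:
        cls = _FAMILIES[d["family"]]
    except KeyError:
        raise ValueError(f"unknown model family {d.get('family')!r}") from None
    return cls.from_dict(d)
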