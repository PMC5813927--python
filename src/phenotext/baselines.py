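"""Non-convolutional classifiers: n-gram/BoW logistic regression, multinomial
naive Bayes, random forests with gini-importance ranking, and the pooled
word-embedding logistic regression (averaged or max-pooled).

The logistic regression is trained by deterministic full-batch gradient
descent on the L2-regularized mean negative log-likelihood, so its loss
trajectory is monotone for small enough steps and runs are bit-reproducible.
Naive Bayes and random forests delegate to scikit-learn estimators behind
this module's interface; the forest exposes normalized gini importances for
global and per-document concept ranking.

The pooled-embedding model exists mainly to demonstrate a failure mode: with
one shared weight vector and length-normalized averaging, the signal from a
handful of indicator tokens is diluted by thousands of background tokens and
held-out discrimination collapses to chance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import MultinomialNB


# ---------------------------------------------------------------------------
# n-gram featurization

@dataclass
class NgramVectorizer:
    """Counts of contiguous token n-grams for n in [n_min, n_max].

    The feature index is fit deterministically: n-grams ordered by descending
    training frequency, ties lexicographic, truncated to ``max_features``.
    BoW is the ``n_min = n_max = 1`` case.
    """

    n_min: int = 1
    n_max: int = 1
    max_features: int = 200_000
    feature_index: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.n_min <= self.n_max <= 5:
            raise ValueError("require 1 <= n_min <= n_max <= 5")

    @staticmethod
    def extract(tokens: Sequence[str], n_min: int, n_max: int
                ) -> Counter:
        """All contiguous n-grams; a length-L note yields max(L-n+1, 0)
        instances for each n."""
        grams: Counter = Counter()
        L = len(tokens)
        for n in range(n_min, n_max + 1):
            for i in range(L - n + 1):
                grams[tuple(tokens[i:i + n])] += 1
        return grams

    def fit(self, token_lists: Sequence[Sequence[str]]) -> "NgramVectorizer":
        totals: Counter = Counter()
        for toks in token_lists:
            totals.update(self.extract(toks, self.n_min, self.n_max))
        ranked = sorted(totals, key=lambda g: (-totals[g], g))[: self.max_features]
        self.feature_index = {g: i for i, g in enumerate(ranked)}
        return self

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def feature_names(self) -> list[str]:
        names = [""] * self.n_features
        for gram, i in self.feature_index.items():
            names[i] = " ".join(gram)
        return names

    def transform(self, token_lists: Sequence[Sequence[str]]) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for r, toks in enumerate(token_lists):
            for gram, c in self.extract(toks, self.n_min, self.n_max).items():
                col = self.feature_index.get(gram)
                if col is not None:
                    rows.append(r)
                    cols.append(col)
                    vals.append(c)
        return sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)),
            shape=(len(token_lists), max(self.n_features, 1)))


def featurize_ngrams(tokens: Sequence[str], n_min: int, n_max: int) -> Counter:
    """Convenience: n-gram counts of a single note as a sparse mapping."""
    if not 1 <= n_min <= n_max <= 5:
        raise ValueError("require 1 <= n_min <= n_max <= 5")
    return NgramVectorizer.extract(tokens, n_min, n_max)


# ---------------------------------------------------------------------------
# Logistic regression (full-batch gradient descent)

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1p_exp(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for large |x|
    return np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))),
                    np.log1p(np.exp(np.minimum(x, 0))))


@dataclass
class LinearModel:
    """Weights and bias of y = sigmoid(w·x + b), plus the training-loss
    trajectory for descent diagnostics."""

    w: np.ndarray
    b: float
    loss_history: list[float] = field(default_factory=list)

    def decision(self, X) -> np.ndarray:
        return np.asarray(X @ self.w).ravel() + self.b

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.decision(X))


def train_logistic(X, y: np.ndarray, l2: float = 1e-4, lr: float = 0.5,
                   epochs: int = 300) -> LinearModel:
    """Minimize mean NLL + (l2/2)·||w||² by full-batch gradient descent.

    Weights start at zero, so symmetric relabelings produce exactly negated
    weights. Requires both classes in ``y``.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    history: list[float] = []
    Xs = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
    for _ in range(epochs):
        z = np.asarray(Xs @ w).ravel() + b
        # mean NLL: mean(log(1+e^z) - y z)
        loss = float(np.mean(_log1p_exp(z) - y * z) + 0.5 * l2 * (w @ w))
        history.append(loss)
        g = (_sigmoid(z) - y) / n
        grad_w = np.asarray(Xs.T @ g).ravel() + l2 * w
        grad_b = float(g.sum())
        w -= lr * grad_w
        b -= lr * grad_b
    z = np.asarray(Xs @ w).ravel() + b
    history.append(float(np.mean(_log1p_exp(z) - y * z) + 0.5 * l2 * (w @ w)))
    return LinearModel(w=w, b=b, loss_history=history)


# ---------------------------------------------------------------------------
# Naive Bayes and random forest (scikit-learn backed)

def train_naive_bayes(X, y: np.ndarray, alpha: float = 1.0) -> MultinomialNB:
    """Multinomial NB with Laplace smoothing ``alpha`` on count features."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    model = MultinomialNB(alpha=alpha)
    model.fit(X, y)
    return model


@dataclass
class ForestModel:
    forest: RandomForestClassifier
    feature_names: list[str]

    @property
    def importances(self) -> np.ndarray:
        return self.forest.feature_importances_

    def predict_proba(self, X) -> np.ndarray:
        proba = self.forest.predict_proba(X)
        pos = list(self.forest.classes_).index(1)
        return proba[:, pos]


def train_forest(X, y: np.ndarray, n_trees: int = 200,
                 max_depth: int | None = None, seed: int = 0,
                 feature_names: Sequence[str] | None = None) -> ForestModel:
    """Random forest on bootstrap samples with gini splits and sqrt-features
    per split; importances are normalized impurity decreases."""
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, max_features="sqrt",
        criterion="gini", random_state=seed, n_jobs=1)
    forest.fit(X.toarray() if sp.issparse(X) else X, y)
    names = list(feature_names) if feature_names is not None else [
        str(i) for i in range(X.shape[1])]
    return ForestModel(forest=forest, feature_names=names)


def rank_features_gini(model: ForestModel,
                       present: Sequence[str] | None = None
                       ) -> list[tuple[str, float]]:
    """Features sorted by descending gini importance. With ``present`` given,
    the global ranking is restricted to those features (the per-document
    variant). Degenerate forests (no split anywhere) yield an empty ranking."""
    imp = model.importances
    if not np.any(imp > 0):
        return []
    keep = set(present) if present is not None else None
    pairs = [(name, float(s)) for name, s in zip(model.feature_names, imp)
             if keep is None or name in keep]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


# ---------------------------------------------------------------------------
# Pooled-embedding logistic regression

@dataclass
class EmbeddingPoolModel:
    """Shared-weight embedding classifier.

    Score of a note with embeddings x_1..x_n is (1/n)·Σ w·x_i when pooling
    by mean (length-normalized), or max_i w·x_i when pooling by max; the
    prediction is sigmoid(score + b).
    """

    w: np.ndarray
    b: float
    pooling: str = "mean"  # "mean" | "max"

    def score(self, note_embeddings: np.ndarray) -> float:
        if note_embeddings.shape[0] == 0:
            raise ValueError("cannot score an empty note")
        per_token = note_embeddings @ self.w
        return float(per_token.mean() if self.pooling == "mean" else per_token.max())

    def predict_proba(self, notes: Sequence[np.ndarray]) -> np.ndarray:
        return _sigmoid(np.array([self.score(e) + self.b for e in notes]))


def train_embedding_pool(notes: Sequence[np.ndarray], y: np.ndarray,
                         pooling: str = "mean", l2: float = 1e-4,
                         lr: float = 0.5, epochs: int = 200) -> EmbeddingPoolModel:
    """Fit the shared weight vector by full-batch (sub)gradient descent.

    For mean pooling this is exactly logistic regression on mean-embedding
    features. For max pooling the pooled token is recomputed each epoch and
    the subgradient flows through it alone.
    """
    if pooling not in ("mean", "max"):
        raise ValueError("pooling must be 'mean' or 'max'")
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    k = notes[0].shape[1]
    if pooling == "mean":
        feats = np.stack([e.mean(axis=0) for e in notes])
        lm = train_logistic(feats, y, l2=l2, lr=lr, epochs=epochs)
        return EmbeddingPoolModel(w=lm.w, b=lm.b, pooling="mean")
    w = np.zeros(k)
    b = 0.0
    n = len(notes)
    for _ in range(epochs):
        feats = np.stack([e[int(np.argmax(e @ w))] for e in notes])
        z = feats @ w + b
        g = (_sigmoid(z) - y) / n
        w -= lr * (feats.T @ g + l2 * w)
        b -= lr * float(g.sum())
    return EmbeddingPoolModel(w=w, b=b, pooling="max")
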