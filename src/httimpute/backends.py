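"""Classifier backends.

Two tiers are provided for each of the three backend families (SVM-like,
random-forest-like, neural-network-like):

* ``make_classifier`` returns a full scikit-learn estimator used for the
  per-target consensus models (SVC with RBF kernel, 100-tree random forest,
  single-hidden-layer MLP).
* ``make_search_scorer`` returns a fast multi-output model used inside the
  greedy search's cross-validated objective, where thousands of refits are
  needed per round: a ridge readout (linear, SVM-like), a small multi-output
  random forest, and a random-tanh-feature network with a ridge readout
  (ANN-like).  Scorers map continuous outputs back to the nearest ternary
  class.
"""
from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

BACKENDS = ("svm", "rf", "ann")


def make_classifier(backend: str, seed: int = 0, **overrides):
    """Full per-target classifier for consensus training."""
    if backend == "svm":
        params = dict(kernel="rbf", C=1.0)
        params.update(overrides)
        return SVC(**params)
    if backend == "rf":
        params = dict(n_estimators=100, random_state=seed)
        params.update(overrides)
        return RandomForestClassifier(**params)
    if backend == "ann":
        # ternary inputs are bounded, so a faster initial learning rate is
        # safe and keeps early stopping from triggering before any learning
        params = dict(
            hidden_layer_sizes=(64,),
            early_stopping=True,
            n_iter_no_change=20,
            max_iter=500,
            learning_rate_init=0.01,
            random_state=seed,
        )
        params.update(overrides)
        return MLPClassifier(**params)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


def _round_ternary(pred: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(pred, -1, 1)).astype(np.int8)


class RidgeScorer:
    """Multi-output linear model with an L2-regularised closed-form fit;
    continuous predictions are rounded to the nearest class."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._w: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RidgeScorer":
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != X.shape[0]:
            Y = Y.T
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        gram = Xb.T @ Xb
        reg = self.alpha * np.eye(Xb.shape[1])
        reg[-1, -1] = 0.0  # no penalty on the intercept
        self._w = np.linalg.solve(gram + reg, Xb.T @ Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xb = np.hstack([X, np.ones((X.shape[0], 1))])
        return _round_ternary(Xb @ self._w)


class ForestScorer:
    """Small multi-output random forest (one fit covers all targets)."""

    def __init__(self, n_estimators: int = 10, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed
        self._rf: RandomForestClassifier | None = None
        self._single = False

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ForestScorer":
        Y = np.atleast_2d(np.asarray(Y))
        if Y.shape[0] != np.asarray(X).shape[0]:
            Y = Y.T
        self._single = Y.shape[1] == 1
        self._rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        )
        self._rf.fit(X, Y.ravel() if self._single else Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred = self._rf.predict(X)
        if self._single:
            pred = pred.reshape(-1, 1)
        return np.asarray(pred, dtype=np.int8)


class RandomFeatureScorer:
    """Single hidden layer of fixed random tanh units with a ridge readout
    (an extreme-learning-machine style network)."""

    def __init__(self, n_hidden: int = 64, alpha: float = 1.0, seed: int = 0):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.seed = seed
        self._proj: tuple[np.ndarray, np.ndarray] | None = None
        self._readout = RidgeScorer(alpha=alpha)

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        W, b = self._proj
        return np.tanh(np.asarray(X, dtype=float) @ W + b)

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RandomFeatureScorer":
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        W = rng.normal(0.0, 1.0 / np.sqrt(max(d, 1)), size=(d, self.n_hidden))
        b = rng.normal(0.0, 0.1, size=self.n_hidden)
        self._proj = (W, b)
        self._readout.fit(self._hidden(X), Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._readout.predict(self._hidden(X))


def make_search_scorer(backend: str, seed: int = 0, **overrides):
    """Fast multi-output scorer for the greedy search objective."""
    if backend == "svm":
        return RidgeScorer(**overrides)
    if backend == "rf":
        params = dict(n_estimators=10, seed=seed)
        params.update(overrides)
        return ForestScorer(**params)
    if backend == "ann":
        params = dict(n_hidden=32, seed=seed)
        params.update(overrides)
        return RandomFeatureScorer(**params)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")


def make_multioutput_model(backend: str, seed: int = 0, **overrides):
    """Multi-output model for fast consensus training at desk scale: same
    families as the search scorers but at full capacity."""
    if backend == "svm":
        return RidgeScorer(**overrides)
    if backend == "rf":
        params = dict(n_estimators=100, seed=seed)
        params.update(overrides)
        return ForestScorer(**params)
    if backend == "ann":
        params = dict(n_hidden=64, seed=seed)
        params.update(overrides)
        return RandomFeatureScorer(**params)
    raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
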