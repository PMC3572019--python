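"""The two discriminant models behind a uniform train/predict contract.

* :class:`NeuralNetClassifier` — a single-hidden-layer feed-forward network
  (logistic hidden units, softmax outputs, L2 weight decay) fitted by BFGS
  with analytic gradients.  Weights are initialized uniformly in
  [-range, range]; the defaults (range 0.1, decay 5e-4, 200 iterations)
  follow the regime classically used for small biomarker panels.
* :class:`RBFSVMClassifier` — an RBF-kernel support vector machine whose
  gamma/cost pair is chosen by inner cross-validated grid search and refitted
  on the full training set.

Both are scikit-learn estimators (fit/predict, get_params/set_params,
fitted attributes with trailing underscores) and are deterministic for a
fixed ``random_state``.  The module-level :func:`train` / :func:`predict`
wrappers add probe-ID feature alignment on top.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-6, 3))
DEFAULT_COST_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-2, 7))


def _check_two_per_class(y: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate training set: only one class present")
    if counts.min() < 2:
        raise ValueError("degenerate training set: every class needs >=2 "
                         "samples")
    return classes


class NeuralNetClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer neural network classifier.

    Parameters
    ----------
    hidden_units : int, default 5
        Size of the single hidden layer.
    weight_init_range : float, default 0.1
        Initial weights drawn uniformly from [-range, range].
    decay : float, default 5e-4
        L2 penalty on all weights and biases.
    max_iter : int, default 200
        BFGS iteration cap.
    random_state : int or None
        Seeds the weight initialization; fixing it makes fits reproducible.
    """

    def __init__(self, hidden_units: int = 5, weight_init_range: float = 0.1,
                 decay: float = 5e-4, max_iter: int = 200,
                 random_state: int | None = None):
        self.hidden_units = hidden_units
        self.weight_init_range = weight_init_range
        self.decay = decay
        self.max_iter = max_iter
        self.random_state = random_state

    # -- parameter packing -------------------------------------------------
    def _shapes(self, d: int, k: int):
        h = self.hidden_units
        return [(d, h), (h,), (h, k), (k,)]

    def _unpack(self, theta: np.ndarray, d: int, k: int):
        out, pos = [], 0
        for shape in self._shapes(d, k):
            size = int(np.prod(shape))
            out.append(theta[pos:pos + size].reshape(shape))
            pos += size
        return out

    def _loss_grad(self, theta, X, Y):
        n, d = X.shape
        k = Y.shape[1]
        W1, b1, W2, b2 = self._unpack(theta, d, k)
        H = expit(X @ W1 + b1)
        P = softmax(H @ W2 + b2, axis=1)
        eps = 1e-12
        loss = -float((Y * np.log(P + eps)).sum())
        loss += self.decay * float((theta ** 2).sum())
        dZ = P - Y
        dW2 = H.T @ dZ + 2 * self.decay * W2
        db2 = dZ.sum(axis=0) + 2 * self.decay * b2
        dH = dZ @ W2.T
        dA = dH * H * (1.0 - H)
        dW1 = X.T @ dA + 2 * self.decay * W1
        db1 = dA.sum(axis=0) + 2 * self.decay * b1
        grad = np.concatenate([g.ravel() for g in (dW1, db1, dW2, db2)])
        return loss, grad

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self.classes_ = _check_two_per_class(y)
        k = len(self.classes_)
        n, d = X.shape
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        rng = np.random.default_rng(self.random_state)
        n_params = sum(int(np.prod(s)) for s in self._shapes(d, k))
        theta0 = rng.uniform(-self.weight_init_range, self.weight_init_range,
                             size=n_params)
        res = minimize(self._loss_grad, theta0, args=(X, Y), jac=True,
                       method="BFGS",
                       options={"maxiter": self.max_iter, "gtol": 1e-8})
        self.coef_ = res.x
        self.n_iter_ = int(res.nit)
        self.loss_ = float(res.fun)
        self.n_features_in_ = d
        return self

    def _forward(self, X):
        d, k = self.n_features_in_, len(self.classes_)
        W1, b1, W2, b2 = self._unpack(self.coef_, d, k)
        H = expit(X @ W1 + b1)
        return softmax(H @ W2 + b2, axis=1)

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return self._forward(X)

    def predict(self, X):
        # the output unit with the largest value decides the class
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class RBFSVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with inner-CV grid search over gamma and cost.

    The (gamma, cost) pair maximizing inner cross-validated accuracy is
    selected (first in grid order on ties) and the model is refitted on the
    full training set with it.

    Attributes
    ----------
    best_gamma_, best_cost_ : float
        The selected hyperparameters.
    """

    def __init__(self, gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 cost_grid: Sequence[float] = DEFAULT_COST_GRID,
                 cv: int = 5, random_state: int | None = None):
        self.gamma_grid = gamma_grid
        self.cost_grid = cost_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self.classes_ = _check_two_per_class(y)
        _, counts = np.unique(y, return_counts=True)
        folds = int(min(self.cv, counts.min()))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=self.random_state)
        splits = [(tr, te) for tr, te in splitter.split(X, y)]
        best_score, best_pair = -np.inf, None
        scores = {}
        for gamma in self.gamma_grid:
            for cost in self.cost_grid:
                fold_acc = []
                for tr, te in splits:
                    model = SVC(kernel="rbf", gamma=gamma, C=cost)
                    model.fit(X[tr], y[tr])
                    fold_acc.append(float(np.mean(model.predict(X[te])
                                                  == y[te])))
                scores[(gamma, cost)] = float(np.mean(fold_acc))
                # strictly-greater keeps the first grid pair on ties
                if scores[(gamma, cost)] > best_score:
                    best_score = scores[(gamma, cost)]
                    best_pair = (gamma, cost)
        self.best_gamma_, self.best_cost_ = (float(best_pair[0]),
                                             float(best_pair[1]))
        self.grid_scores_ = scores
        self.estimator_ = SVC(kernel="rbf", gamma=self.best_gamma_,
                              C=self.best_cost_).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = check_array(X)
        return self.estimator_.predict(X)


# ---------------------------------------------------------------------------
# Declarative-config wrappers with probe-ID feature alignment
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Declarative model configuration; ``build`` yields a fresh estimator."""

    model_kind: str = "NNET"  # "NNET" | "SVM"
    hidden_units: int = 5
    weight_init_range: float = 0.1
    weight_decay: float = 5e-4
    max_iterations: int = 200
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    cv_folds: int = 5
    standardize: bool = False
    random_state: int | None = None

    def __post_init__(self):
        if self.model_kind not in ("NNET", "SVM"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.weight_decay < 0:
            raise ValueError("decay must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.gamma_grid or not self.cost_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    def with_seed(self, random_state: int | None) -> "ClassifierSpec":
        return replace(self, random_state=random_state)

    def build(self) -> BaseEstimator:
        if self.model_kind == "NNET":
            return NeuralNetClassifier(
                hidden_units=self.hidden_units,
                weight_init_range=self.weight_init_range,
                decay=self.weight_decay,
                max_iter=self.max_iterations,
                random_state=self.random_state)
        return RBFSVMClassifier(gamma_grid=self.gamma_grid,
                                cost_grid=self.cost_grid,
                                cv=self.cv_folds,
                                random_state=self.random_state)


@dataclass
class TrainedModel:
    """A fitted model bound to an ordered probe feature list."""

    model_kind: str
    estimator: BaseEstimator
    feature_ids: list[str]
    classes: list[str]
    standardize: bool = False
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None

    @property
    def best_hyperparameters(self) -> dict:
        if hasattr(self.estimator, "best_gamma_"):
            return {"gamma": self.estimator.best_gamma_,
                    "cost": self.estimator.best_cost_}
        return {}


def train(features: pd.DataFrame, labels: pd.Series,
          spec: ClassifierSpec) -> TrainedModel:
    """Fit a model on a samples x markers DataFrame (columns = probe IDs)."""
    labels = pd.Series(labels).loc[features.index]
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y = labels.to_numpy(dtype=object)
    means = sds = None
    if spec.standardize:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
        X = (X - means) / sds
    est = spec.build().fit(X, y)
    return TrainedModel(model_kind=spec.model_kind, estimator=est,
                        feature_ids=list(features.columns),
                        classes=[str(c) for c in est.classes_],
                        standardize=spec.standardize,
                        feature_means=means, feature_sds=sds)


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.Series:
    """Predict labels; columns are aligned to the training feature list by ID."""
    missing = [f for f in model.feature_ids if f not in features.columns]
    extra = [f for f in features.columns if f not in model.feature_ids]
    if missing or extra:
        raise ValueError(
            f"feature mismatch: missing probes {missing[:5]}, "
            f"unexpected probes {extra[:5]}")
    X = features[model.feature_ids].to_numpy(dtype=float)
    if model.standardize:
        X = (X - model.feature_means) / model.feature_sds
    yhat = model.estimator.predict(X)
    return pd.Series(yhat, index=features.index, name="predicted")
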