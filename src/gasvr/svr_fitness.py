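"""RBF-kernel support-vector regression and the cross-validated-MSE fitness.

The regression model is epsilon-insensitive SVR with the Gaussian kernel

    K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2)

and prediction f(x) = sum_i (alpha_i - alpha_i*) K(x_i, x) + b over the
support vectors. The quadratic program is solved by scikit-learn's libsvm
binding; :class:`TrainedSVRModel` stores the support vectors, the dual
coefficient differences and the bias and re-evaluates the kernel expansion
itself, so the prediction contract is independent of the solver object.

Model quality is scored by the mean squared error of k-fold cross
validation (10 folds by default), which is also the fitness minimized by
the genetic algorithm. Fold membership is keyed to sample identifiers, not
row positions, so reordering the rows of a table never changes the score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from .datakit import FeatureTable
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SVMParams",
    "TrainedSVRModel",
    "rbf_kernel",
    "train_svr",
    "mse",
    "r_squared",
    "make_folds",
    "cv_predict",
    "cv_mse",
    "grid_search",
    "default_grid",
]


@dataclass(frozen=True)
class SVMParams:
    """SVR hyperparameters: regularization C, RBF width gamma, tube half-width epsilon."""

    C: float
    gamma: float
    epsilon: float

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValidationError("C must be > 0")
        if not self.gamma > 0:
            raise ValidationError("gamma must be > 0")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")


def rbf_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> float:
    """Gaussian similarity exp(-gamma * ||a - b||^2) between two vectors."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("vector length mismatch")
    return float(np.exp(-gamma * np.sum((a - b) ** 2)))


@dataclass(frozen=True)
class _ScalerState:
    """Per-feature centering and scale learned on training data only."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def _fit_scaler(X: np.ndarray) -> _ScalerState:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return _ScalerState(mean=mean, scale=sd)


@dataclass(frozen=True)
class TrainedSVRModel:
    """A fitted SVR model as an explicit kernel expansion.

    ``predict`` evaluates sum_i dual_coef[i] * K(sv_i, x) + bias directly
    from the stored state; ``_estimator`` keeps the fitted solver around
    for cross-checks but is never needed for prediction.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    params: SVMParams
    feature_indices: tuple[int, ...] | None
    scaler: _ScalerState | None
    _estimator: SVR | None = None

    def __post_init__(self) -> None:
        if self.support_vectors.shape[0] != self.dual_coef.shape[0]:
            raise ValidationError("dual_coef must have one entry per support vector")
        if np.any(np.abs(self.dual_coef) > self.params.C * (1 + 1e-9)):
            raise ValidationError("|alpha_i - alpha_i*| must not exceed C")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_indices is not None and X.shape[1] != self.support_vectors.shape[1]:
            X = X[:, list(self.feature_indices)]
        if self.scaler is not None:
            X = self.scaler.transform(X)
        sv = self.support_vectors
        d2 = (
            (X * X).sum(axis=1)[:, None]
            + (sv * sv).sum(axis=1)[None, :]
            - 2.0 * (X @ sv.T)
        )
        K = np.exp(-self.params.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.bias


#: SMO iteration cap for the default trainer. Hostile hyperparameter corners
#: (very large C with a near-zero tube) can otherwise cost two orders of
#: magnitude more solver time than useful regions for a negligible change in
#: the fitted function; pass ``max_iter=-1`` for an uncapped exact solve.
DEFAULT_MAX_ITER = 10_000


def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    feature_indices: Sequence[int] | None = None,
    standardize: bool = True,
    max_iter: int = DEFAULT_MAX_ITER,
) -> TrainedSVRModel:
    """Fit epsilon-SVR with the RBF kernel.

    Features are z-scored (statistics learned on this training data) before
    fitting unless ``standardize=False``; the scaler travels with the model.
    SMO iterations are capped at ``max_iter`` (-1 for no cap).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must have equal numbers of rows")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    idx = None
    if feature_indices is not None:
        idx = tuple(int(i) for i in feature_indices)
        X = X[:, list(idx)]
    scaler = _fit_scaler(X) if standardize else None
    Z = scaler.transform(X) if scaler is not None else X
    est = SVR(
        kernel="rbf", C=params.C, gamma=params.gamma, epsilon=params.epsilon,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Z, y)
    return TrainedSVRModel(
        support_vectors=est.support_vectors_.copy(),
        dual_coef=est.dual_coef_.ravel().copy(),
        bias=float(est.intercept_[0]),
        params=params,
        feature_indices=idx,
        scaler=scaler,
        _estimator=est,
    )


def mse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean squared error (1/n) * sum (yhat_i - y_i)^2."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValidationError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValidationError("need at least one value")
    return float(np.mean((p - o) ** 2))


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Squared Pearson correlation between predictions and observations.

    This is the r^2 conventionally reported in QSAR tables; it is blind to
    the sign and affine calibration of the predictions. A constant
    prediction vector has no linear association and scores 0.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValidationError("predicted and observed must have equal length")
    if p.size < 2:
        raise ValidationError("need at least two values")
    if o.max() == o.min():
        raise ValidationError("observed vector is constant; r^2 undefined")
    if p.max() == p.min():
        return 0.0
    r = float(np.corrcoef(p, o)[0, 1])
    return r * r


def make_folds(
    sample_ids: Sequence[str],
    n_folds: int,
    seed: int | None,
) -> list[np.ndarray]:
    """Seeded k-fold assignment keyed to sample ids.

    Sample ids are put in sorted order, shuffled with the seeded RNG and cut
    into ``n_folds`` contiguous blocks. Because the shuffle acts on the
    id-sorted sequence, two tables holding the same samples in different row
    orders get identical id-level folds.
    """
    n = len(sample_ids)
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if n < n_folds:
        raise ConfigurationError("need at least n_folds samples")
    order = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
    rng = np.random.default_rng(seed)
    canonical = order[rng.permutation(n)]
    return [np.asarray(f, dtype=int) for f in np.array_split(canonical, n_folds)]


_Trainer = Callable[[np.ndarray, np.ndarray, SVMParams], object]


def _default_trainer(X: np.ndarray, y: np.ndarray, params: SVMParams):
    return train_svr(X, y, params, standardize=True)


def cv_predict(
    table: FeatureTable,
    feature_indices: Sequence[int],
    params: SVMParams,
    n_folds: int = 10,
    seed: int | None = 0,
    folds: list[np.ndarray] | None = None,
    trainer: _Trainer | None = None,
) -> np.ndarray:
    """Out-of-fold predictions for every sample, aligned to table rows.

    For each fold the model is trained on the remaining samples (feature
    scaling fit on that training portion only inside the trainer) and
    applied to the held-out fold.
    """
    idx = [int(i) for i in feature_indices]
    for i in idx:
        if not 0 <= i < table.n_features:
            raise ValidationError(f"feature index {i} out of range")
    if folds is None:
        folds = make_folds(table.sample_ids, n_folds, seed)
    trainer = trainer or _default_trainer
    Xf = table.X[:, idx]
    out = np.empty(table.n_samples, dtype=float)
    for k, hold in enumerate(folds):
        train_rows = np.concatenate([f for j, f in enumerate(folds) if j != k])
        model = trainer(Xf[train_rows], table.y[train_rows], params)
        out[hold] = np.asarray(model.predict(Xf[hold]), dtype=float).ravel()
    return out


def cv_mse(
    table: FeatureTable,
    feature_indices: Sequence[int],
    params: SVMParams,
    n_folds: int = 10,
    seed: int | None = 0,
    folds: list[np.ndarray] | None = None,
    trainer: _Trainer | None = None,
) -> float:
    """Pooled k-fold cross-validation MSE — the GA's fitness (lower is better).

    Residuals are pooled in canonical fold order so the value is exactly
    invariant to row permutations of the table.
    """
    if folds is None:
        folds = make_folds(table.sample_ids, n_folds, seed)
    pred = cv_predict(table, feature_indices, params, folds=folds, trainer=trainer)
    pooled = np.concatenate(folds)
    return mse(pred[pooled], table.y[pooled])


def default_grid() -> dict[str, list[float]]:
    """Conventional log2-spaced baseline grid for (C, gamma, epsilon)."""
    return {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
        "epsilon": [2.0**e for e in range(-8, 0)],
    }


def grid_search(
    table: FeatureTable,
    feature_indices: Sequence[int],
    grid: dict[str, list[float]] | None = None,
    n_folds: int = 10,
    seed: int | None = 0,
) -> tuple[SVMParams, float]:
    """Exhaustive grid search minimizing cross-validated MSE.

    Evaluates every (C, gamma, epsilon) combination on a fold assignment
    fixed once for the whole search; returns the first grid point attaining
    the minimum, with its cv_mse.
    """
    grid = grid if grid is not None else default_grid()
    for axis in ("C", "gamma", "epsilon"):
        if not grid.get(axis):
            raise ConfigurationError(f"grid axis {axis!r} is empty")
    folds = make_folds(table.sample_ids, n_folds, seed)
    best: tuple[SVMParams, float] | None = None
    for C, g, e in itertools.product(grid["C"], grid["gamma"], grid["epsilon"]):
        params = SVMParams(C=float(C), gamma=float(g), epsilon=float(e))
        score = cv_mse(table, feature_indices, params, folds=folds)
        if best is None or score < best[1]:
            best = (params, score)
    assert best is not None
    return best
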