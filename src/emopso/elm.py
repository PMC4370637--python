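"""Kernel extreme learning machine.

A regularized least-squares classifier in kernel form: with Gaussian Gram
matrix ``Omega`` over the training rows and one-vs-all +/-1 targets ``T``,
the output weights solve ``(I/eps + Omega) alpha = T`` and a new point is
scored as ``k(x, X_train) @ alpha``. ``eps`` is the positive regularization
coefficient of the diagonal loading (larger ``eps`` -> weaker
regularization), and the kernel is ``k(u, v) = exp(-||u - v||^2 / gamma)``
with width parameter ``gamma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable

log = logging.getLogger(__name__)

__all__ = ["KernelELM", "PredictionSet", "train", "predict", "tune", "DEFAULT_GRID"]

DEFAULT_GRID = tuple(2.0**p for p in range(-5, 16))


@dataclass(frozen=True)
class PredictionSet:
    scores: np.ndarray  # (n_samples, n_classes)
    labels: np.ndarray


class KernelELM:
    """Closed-form kernel ELM classifier (scikit-learn-ish fit/predict).

    ``kernel_width=None`` uses the median-pairwise-squared-distance
    heuristic of the training rows at fit time (deterministic).
    """

    def __init__(self, reg: float = 1.0, kernel_width: float | None = None):
        if reg <= 0 or (kernel_width is not None and kernel_width <= 0):
            raise ValueError("reg and kernel_width must be positive")
        self.reg = float(reg)
        self.kernel_width = None if kernel_width is None else float(kernel_width)

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return np.exp(-cdist(A, B, "sqeuclidean") / self.width_)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelELM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("training features must be a finite 2-D array")
        if self.kernel_width is None:
            sq = cdist(X, X, "sqeuclidean")
            med = float(np.median(sq[np.triu_indices_from(sq, k=1)]))
            self.width_ = med if med > 0 else 1.0
        else:
            self.width_ = self.kernel_width
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        T = np.where(y[:, None] == self.classes_[None, :], 1.0, -1.0)
        omega = self._kernel(X, X)
        A = omega + np.eye(len(X)) / self.reg
        self.alpha_ = cho_solve(cho_factor(A), T)
        self.X_train_ = X
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.X_train_.shape[1]:
            raise ValueError("prediction rows do not match the training dimensionality")
        return self._kernel(X, self.X_train_) @ self.alpha_

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax takes the lowest class index on exact ties
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train(table: FeatureTable, reg: float = 1.0, kernel_width: float | None = None) -> KernelELM:
    return KernelELM(reg, kernel_width).fit(table.X, table.y)


def predict(model: KernelELM, rows: np.ndarray) -> PredictionSet:
    scores = model.decision_function(rows)
    return PredictionSet(scores, model.classes_[np.argmax(scores, axis=1)])


def tune(
    table: FeatureTable,
    reg_grid=DEFAULT_GRID,
    width_grid=DEFAULT_GRID,
    n_folds: int = 3,
    seed: int | None = None,
) -> tuple[float, float]:
    """Cross-validated grid search maximizing G-mean.

    Ties go to the smaller regularization coefficient, then smaller width.
    """
    from .selection import gmean  # local import: selection depends on elm

    reg_grid = sorted(reg_grid)
    width_grid = sorted(width_grid)
    if not reg_grid or not width_grid:
        raise ValueError("grids must be non-empty")
    X, y = table.X, table.y
    classes = np.unique(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (-np.inf, None)
    for reg, width in product(reg_grid, width_grid):
        conf = np.zeros((len(classes), len(classes)))
        for tr, te in folds:
            clf = KernelELM(reg, width).fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            for yt, yp in zip(y[te], pred):
                conf[np.searchsorted(classes, yt), np.searchsorted(classes, yp)] += 1
        g = gmean(conf)
        if g > best[0]:  # strict: earlier (smaller) grid points win ties
            best = (g, (reg, width))
    return best[1]
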