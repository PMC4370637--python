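"""Cluster-center attribute weighting via PSO clustering.

A swarm searches for the K cluster centers (K = number of emotion classes)
that minimize the summed Euclidean distance of every sample to its nearest
center. The per-dimension ratio of the data mean to the mean of the K center
coordinates is then used as a multiplicative weight on that feature column,
stretching dimensions where the cluster structure is compact relative to the
data spread and thereby increasing between-class separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "SwarmConfig",
    "ClusterModel",
    "WeightVector",
    "pso_cluster",
    "compute_weights",
    "apply_weights",
    "fisher_ratio",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Shared PSO control parameters (clustering and selection swarms)."""

    n_particles: int = 30
    max_iter: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w0: float = 0.9  # clustering inertia start; selection uses 1.4
    decay: float = 0.85  # w(t+1) = decay * w(t)
    seed: int | None = None
    stagnation_patience: int = 10

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration constants must be positive")


@dataclass(frozen=True)
class ClusterModel:
    centers: np.ndarray  # (K, D)
    K: int
    objective: float

    def __post_init__(self) -> None:
        if self.K < 1 or not np.all(np.isfinite(self.centers)):
            raise ValueError("invalid cluster model")


@dataclass(frozen=True)
class WeightVector:
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not (np.all(np.isfinite(w)) and np.all(w > 0)):
            raise ValueError("weights must be positive and finite")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)


def _as_matrix(table) -> np.ndarray:
    return table.X if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)


def _objective(X: np.ndarray, centers: np.ndarray) -> float:
    """Quantization error: sum over samples of distance to the nearest center."""
    return float(cdist(X, centers).min(axis=1).sum())


def pso_cluster(table, K: int, cfg: SwarmConfig | None = None) -> ClusterModel:
    """Swarm search for K centers minimizing the quantization error.

    Particles encode K candidate centers each, initialized from randomly
    chosen data rows. Inertia starts at ``cfg.w0`` (0.9) and is multiplied by
    ``cfg.decay`` (0.85) each iteration; on stagnation of the global best for
    ``stagnation_patience`` iterations, velocities are zeroed and every
    particle except the best is re-drawn from the data.
    """
    cfg = cfg or SwarmConfig()
    X = _as_matrix(table)
    n, d = X.shape
    if K < 1 or n < K:
        raise ValueError("need at least K rows")
    if np.unique(X, axis=0).shape[0] < K:
        raise ValueError("need at least K distinct rows")
    rng = np.random.default_rng(cfg.seed)

    def random_centers(count):
        return np.stack(
            [X[rng.choice(n, size=K, replace=False)] for _ in range(count)]
        )  # (count, K, D)

    pos = random_centers(cfg.n_particles)
    vel = np.zeros_like(pos)
    fit = np.array([_objective(X, p) for p in pos])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    w = cfg.w0
    stale = 0
    for _ in range(cfg.max_iter):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = w * vel + cfg.c1 * r1 * (pbest - pos) + cfg.c2 * r2 * (gbest[None] - pos)
        pos = pos + vel
        fit = np.array([_objective(X, p) for p in pos])
        improved = fit < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        meaningful = pbest_fit[g] < gbest_fit * (1.0 - 1e-6)
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        if meaningful:
            stale = 0
        else:
            stale += 1
            if stale >= cfg.stagnation_patience:
                # escape + refine: half the non-best particles restart from
                # data rows, half perturb the incumbent best locally
                vel[:] = 0.0
                others = [i for i in range(cfg.n_particles) if i != g]
                half = len(others) // 2
                pos[others[:half]] = random_centers(half)
                scale = 0.1 * X.std(axis=0)
                for i in others[half:]:
                    pos[i] = gbest + scale * rng.standard_normal((K, d))
                stale = 0
        w *= cfg.decay
    return ClusterModel(gbest, K, gbest_fit)


def compute_weights(model: ClusterModel, table) -> WeightVector:
    """weight_d = |mean_d(data) / mean_k(center_{k,d})|, guarded to stay positive.

    Degenerate ratios (center-mean ~ 0, non-finite, or ~0 data mean) fall
    back to a neutral weight of 1.
    """
    X = _as_matrix(table)
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError("model and table are dimensionally inconsistent")
    data_mean = X.mean(axis=0)
    center_mean = model.centers.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(data_mean / center_mean)
    bad = (np.abs(center_mean) < 1e-12) | ~np.isfinite(ratio) | (ratio < 1e-12)
    ratio[bad] = 1.0
    if bad.any():
        log.debug("compute_weights: %d dimension(s) fell back to weight 1", int(bad.sum()))
    return WeightVector(ratio)


def apply_weights(table: FeatureTable, w: WeightVector) -> FeatureTable:
    """Scale each feature column by its weight; labels/speakers untouched."""
    if table.n_features != len(w.weights):
        raise ValueError("weight vector does not match table dimensionality")
    scaled = table.features * w.weights
    return FeatureTable(scaled, table.labels, table.speakers, table.sex)


def fisher_ratio(table: FeatureTable) -> float:
    """Mean over dimensions of between-class / within-class variance.

    The separability summary used to judge whether attribute weighting has
    improved the class geometry of a table.
    """
    X, y = table.X, table.y
    classes = np.unique(y)
    overall = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        between += len(Xc) * (Xc.mean(axis=0) - overall) ** 2
        within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    between /= len(X)
    within /= len(X)
    ratio = between / np.maximum(within, 1e-300)
    return float(ratio.mean())
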