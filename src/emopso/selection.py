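"""Wrapper feature selection with a binary particle swarm.

Each particle is a boolean mask over the feature columns. Fitness trades the
classification quality of a kernel-ELM wrapper (measured by the geometric
mean of per-class recalls under internal stratified cross-validation)
against parsimony:

    fitness = alpha * (1 - Gmean) + (1 - alpha) * n_selected / n_features

with alpha = 0.8 — lower is better. The swarm uses a mixed initialization
(half the particles start at ~10% of the features, half at ~60%), a v-shaped
transfer function T(v) = |(2/pi) atan((pi/2) v)| that converts velocity to a
bit-flip probability, an inertia weight that decays from 1.4 via
w <- (w - 0.4)(t_max - t)/(t_max + 0.4), and a two-situation personal/global
best rule: a candidate replaces the incumbent only if it improves G-mean
without adding features, or sheds features without losing G-mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .elm import KernelELM
from .enhancement import SwarmConfig
from .features import FeatureTable, family_of

log = logging.getLogger(__name__)

__all__ = [
    "FitnessConfig",
    "SelectionMask",
    "ParticleSwarm",
    "SelectionEnsemble",
    "init_particles",
    "gmean",
    "fitness",
    "transfer",
    "inertia_step",
    "update_pbest_gbest",
    "run_selection",
    "run_selection_repeated",
]

VELOCITY_CLAMP = 6.0


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness parameters: Eq-8 tradeoff and the internal CV classifier."""

    alpha: float = 0.8
    eval_folds: int = 3
    reg: float = 100.0
    kernel_width: float | None = None  # None -> median-distance heuristic
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")


@dataclass(frozen=True)
class SelectionMask:
    """A feature subset plus the search history that produced it."""

    selected: np.ndarray  # boolean per feature
    fitness: float
    gmean: float
    history: np.ndarray = field(repr=False)  # gbest fitness per iteration
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        if sel.sum() < 1:
            raise ValueError("a selection mask must keep at least one feature")
        sel.setflags(write=False)
        object.__setattr__(self, "selected", sel)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def per_family_counts(self) -> dict[str, int]:
        """Table-2-style bookkeeping: selected features per stream/family."""
        if self.names is None:
            raise ValueError("mask carries no feature names")
        counts: dict[str, int] = {}
        for name, keep in zip(self.names, self.selected):
            if keep:
                fam = family_of(name)
                key = f"{name.split('.')[0]}.{fam}" if "." in name else fam
                counts[key] = counts.get(key, 0) + 1
        return counts


def transfer(v) -> np.ndarray:
    """V-shaped transfer: T(v) = |(2/pi) atan((pi/2) v)|, in [0, 1)."""
    return np.abs((2.0 / np.pi) * np.arctan((np.pi / 2.0) * np.asarray(v, dtype=float)))


def inertia_step(w: float, t: int, t_max: int) -> float:
    """One adaptive inertia update: (w - 0.4)(t_max - t)/(t_max + 0.4)."""
    return (w - 0.4) * (t_max - t) / (t_max + 0.4)


def gmean(confusion: np.ndarray) -> float:
    """Geometric mean of per-class recalls from a class x class count matrix."""
    conf = np.asarray(confusion, dtype=float)
    totals = conf.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("every true class needs at least one sample")
    recalls = np.diag(conf) / totals
    if np.any(recalls == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(recalls))))


def init_particles(D: int, n: int, seed=None, small: float = 0.10, large: float = 0.60):
    """Mixed initialization: half the swarm ~10% of features, half ~60%.

    Returns (positions (n, D) bool, velocities (n, D) float zeros).
    """
    if n < 2:
        raise ValueError("need at least 2 particles")
    if D < 2:
        raise ValueError("need at least 2 features")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = np.zeros((n, D), dtype=bool)
    for i in range(n):
        frac = small if i < n // 2 else large
        k = max(1, round(frac * D))
        positions[i, rng.choice(D, size=k, replace=False)] = True
    return positions, np.zeros((n, D))


class _FitnessEvaluator:
    """G-mean/fitness of a mask via stratified CV of the kernel ELM; memoized."""

    def __init__(self, table: FeatureTable, cfg: FitnessConfig):
        self.X = table.X
        self.y = table.y
        self.classes = np.unique(self.y)
        self.cfg = cfg
        self.D = table.n_features
        skf = StratifiedKFold(n_splits=cfg.eval_folds, shuffle=True, random_state=cfg.seed)
        self.folds = list(skf.split(self.X, self.y))
        self._cache: dict[bytes, tuple[float, float, int]] = {}

    def __call__(self, mask: np.ndarray) -> tuple[float, float, int]:
        """Returns (fitness, gmean, n_selected)."""
        mask = np.asarray(mask, dtype=bool)
        n_sel = int(mask.sum())
        if n_sel < 1:
            raise ValueError("fitness is undefined for an empty mask")
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        Xm = self.X[:, mask]
        conf = np.zeros((len(self.classes), len(self.classes)))
        try:
            for tr, te in self.folds:
                clf = KernelELM(self.cfg.reg, self.cfg.kernel_width).fit(Xm[tr], self.y[tr])
                pred = clf.predict(Xm[te])
                for yt, yp in zip(self.y[te], pred):
                    conf[np.searchsorted(self.classes, yt), np.searchsorted(self.classes, yp)] += 1
            g = gmean(conf)
            fit = self.cfg.alpha * (1.0 - g) + (1.0 - self.cfg.alpha) * n_sel / self.D
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            warnings.warn(f"wrapper classifier failed ({exc}); assigning worst fitness")
            g, fit = 0.0, 1.0
        out = (float(fit), float(g), n_sel)
        self._cache[key] = out
        return out


def fitness(mask, table: FeatureTable, cfg: FitnessConfig | None = None) -> float:
    """Eq-8 fitness of one mask (lower is better)."""
    cfg = cfg or FitnessConfig()
    sel = mask.selected if isinstance(mask, SelectionMask) else np.asarray(mask, dtype=bool)
    return _FitnessEvaluator(table, cfg)(sel)[0]


def update_pbest_gbest(
    cand_g: float, cand_n: int, best_g: float, best_n: int
) -> bool:
    """Two-situation acceptance rule for pbest/gbest replacement.

    Situation 1: strictly better G-mean with a feature count not larger.
    Situation 2: strictly fewer features with G-mean the same or better.
    """
    return (cand_g > best_g and cand_n <= best_n) or (cand_n < best_n and cand_g >= best_g)


@dataclass
class ParticleSwarm:
    """State of the binary swarm (exposed for stepwise tests)."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest: np.ndarray
    pbest_g: np.ndarray
    pbest_n: np.ndarray
    pbest_fit: np.ndarray


def _repair(mask: np.ndarray, rng: np.random.Generator) -> None:
    if not mask.any():
        mask[rng.integers(len(mask))] = True


def run_selection(
    table: FeatureTable,
    cfg: SwarmConfig | None = None,
    fcfg: FitnessConfig | None = None,
) -> SelectionMask:
    """Full binary-PSO wrapper search; returns the global-best mask.

    The global best's Eq-8 fitness is non-increasing over iterations; the
    returned history records it per iteration.
    """
    cfg = cfg or SwarmConfig(w0=1.4)
    fcfg = fcfg or FitnessConfig()
    rng = np.random.default_rng(cfg.seed)
    evaluate = _FitnessEvaluator(table, fcfg)
    D = table.n_features

    pos, vel = init_particles(D, cfg.n_particles, rng)
    evals = [evaluate(p) for p in pos]
    pbest = pos.copy()
    pbest_fit = np.array([e[0] for e in evals])
    pbest_g = np.array([e[1] for e in evals])
    pbest_n = np.array([e[2] for e in evals], dtype=int)

    # initial gbest follows the two-situation preference: best G-mean first,
    # ties to the smaller subset (a fitness-minimal tiny mask could otherwise
    # strand the search, since the rule never accepts a larger subset)
    gi = int(np.lexsort((pbest_n, -pbest_g))[0])
    gbest = pbest[gi].copy()
    gbest_fit, gbest_g, gbest_n = float(pbest_fit[gi]), float(pbest_g[gi]), int(pbest_n[gi])

    w = 1.4
    history = []
    stale = 0
    for t in range(cfg.max_iter):
        w = inertia_step(w, t, cfg.max_iter)
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        xf = pos.astype(float)
        vel = (
            w * vel
            + cfg.c1 * r1 * (pbest.astype(float) - xf)
            + cfg.c2 * r2 * (gbest.astype(float)[None] - xf)
        )
        np.clip(vel, -VELOCITY_CLAMP, VELOCITY_CLAMP, out=vel)
        flip = rng.random(pos.shape) < transfer(vel)
        pos = np.where(flip, ~pos, pos)
        for mask in pos:
            _repair(mask, rng)

        improved_g = False
        for i in range(cfg.n_particles):
            f, g, ns = evaluate(pos[i])
            if update_pbest_gbest(g, ns, pbest_g[i], pbest_n[i]):
                pbest[i] = pos[i]
                pbest_fit[i], pbest_g[i], pbest_n[i] = f, g, ns
                if update_pbest_gbest(g, ns, gbest_g, gbest_n):
                    gbest = pos[i].copy()
                    gbest_fit, gbest_g, gbest_n = f, g, ns
                    improved_g = True
        history.append(gbest_fit)
        if improved_g:
            stale = 0
        else:
            stale += 1
            if stale >= cfg.stagnation_patience:
                vel[:] = 0.0
                fresh, _ = init_particles(D, cfg.n_particles, rng)
                keep = np.array([np.array_equal(p, gbest) for p in pbest])
                pos = np.where(keep[:, None], pos, fresh)
                stale = 0
    return SelectionMask(
        gbest,
        gbest_fit,
        gbest_g,
        np.asarray(history),
        tuple(table.feature_names),
    )


@dataclass(frozen=True)
class SelectionEnsemble:
    """Aggregate of R independent selection runs."""

    masks: tuple[SelectionMask, ...]
    frequencies: np.ndarray  # per-feature selection frequency in [0, 1]
    names: tuple[str, ...]

    @property
    def most_frequent(self) -> np.ndarray:
        """Features selected in more than half of the runs."""
        return self.frequencies > 0.5

    def top_k(self, k: int) -> np.ndarray:
        """Indices of the k most frequently selected features (ties: lower index)."""
        order = np.lexsort((np.arange(len(self.frequencies)), -self.frequencies))
        return order[:k]


def run_selection_repeated(
    table: FeatureTable,
    cfg: SwarmConfig | None = None,
    fcfg: FitnessConfig | None = None,
    runs: int = 25,
    seed: int | None = None,
) -> SelectionEnsemble:
    """R independent swarm runs with derived seeds; reports selection frequency."""
    cfg = cfg or SwarmConfig(w0=1.4)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    masks = []
    for _ in range(runs):
        run_cfg = SwarmConfig(
            n_particles=cfg.n_particles,
            max_iter=cfg.max_iter,
            c1=cfg.c1,
            c2=cfg.c2,
            w0=cfg.w0,
            decay=cfg.decay,
            seed=int(rng.integers(2**31 - 1)),
            stagnation_patience=cfg.stagnation_patience,
        )
        masks.append(run_selection(table, run_cfg, fcfg))
    freq = np.mean([m.selected for m in masks], axis=0)
    return SelectionEnsemble(tuple(masks), freq, tuple(table.feature_names))
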