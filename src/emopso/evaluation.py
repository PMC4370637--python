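"""Experiment protocols: speaker-dependent / -independent / gender-dependent.

Every fold refits the whole pipeline — cluster-center weighting, wrapper
selection and the kernel-ELM classifier — on the training rows only, so no
held-out statistic ever leaks into the fitted transforms. Confusion matrices
are accumulated over folds and reported row-normalized in percent; the
average recognition rate is the unweighted mean of the per-class recalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .elm import KernelELM
from .enhancement import SwarmConfig, apply_weights, compute_weights, pso_cluster
from .features import FeatureTable
from .selection import FitnessConfig, gmean, run_selection, run_selection_repeated

log = logging.getLogger(__name__)

__all__ = [
    "Protocol",
    "PipelineConfig",
    "EvaluationReport",
    "make_splits",
    "evaluate",
    "paired_ttest",
]

PROTOCOL_NAMES = ("SD", "SI", "GD-male", "GD-female")


@dataclass(frozen=True)
class Protocol:
    """SD = stratified k-fold over utterances; SI = leave-one-speaker-out;
    GD = SD restricted to one sex (requires a per-row sex attribute)."""

    name: str = "SD"
    n_folds: int = 10
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"protocol must be one of {PROTOCOL_NAMES}")


@dataclass(frozen=True)
class PipelineConfig:
    """Which stages run per training fold and with what budgets."""

    stage: str = "selected"  # raw | weighted | selected
    cluster_cfg: SwarmConfig = field(default_factory=lambda: SwarmConfig(n_particles=10, max_iter=20))
    selection_cfg: SwarmConfig = field(default_factory=lambda: SwarmConfig(n_particles=10, max_iter=15, w0=1.4))
    fitness_cfg: FitnessConfig = field(default_factory=FitnessConfig)
    selection_runs: int = 1  # >1: aggregate runs, keep most-frequently-selected
    reg: float = 100.0
    kernel_width: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "weighted", "selected"):
            raise ValueError("stage must be raw, weighted or selected")


@dataclass(frozen=True)
class EvaluationReport:
    protocol: str
    classes: tuple
    confusion_counts: np.ndarray
    confusion_percent: pd.DataFrame  # rows sum to 100
    avg_rate: float  # mean per-class recall, percent
    gmean: float
    per_fold_rates: np.ndarray  # macro recall per fold, percent

    def summary(self) -> str:
        lines = [
            f"protocol: {self.protocol}",
            f"average recognition rate: {self.avg_rate:.2f}%",
            f"G-mean: {self.gmean:.4f}",
            "confusion (row %):",
            self.confusion_percent.round(2).to_string(),
        ]
        return "\n".join(lines)


def make_splits(table: FeatureTable, protocol: Protocol, seed: int | None = None):
    """Fold (train_idx, test_idx) pairs into the table's rows."""
    y = table.y
    if protocol.name == "SI":
        speakers = table.speakers.to_numpy()
        uniq = pd.unique(speakers)
        if len(uniq) < 2:
            raise ValueError("speaker-independent evaluation needs >= 2 speakers")
        folds = []
        for spk in uniq:
            test = np.flatnonzero(speakers == spk)
            train = np.flatnonzero(speakers != spk)
            folds.append((train, test))
        return folds
    if protocol.name.startswith("GD"):
        if table.sex is None:
            raise ValueError("gender-dependent protocols need a sex attribute")
        want = "M" if protocol.name.endswith("male") and not protocol.name.endswith("female") else "F"
        rows = np.flatnonzero(table.sex.to_numpy() == want)
        if rows.size == 0:
            raise ValueError(f"no rows with sex {want!r}")
        sub_y = y[rows]
    else:
        rows = np.arange(len(y))
        sub_y = y
    n_folds = min(protocol.n_folds, int(np.min(np.unique(sub_y, return_counts=True)[1])))
    if n_folds < 2:
        raise ValueError("not enough samples per class for stratified folding")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(rows[tr], rows[te]) for tr, te in skf.split(np.zeros(len(sub_y)), sub_y)]


def _fit_fold(train: FeatureTable, test: FeatureTable, cfg: PipelineConfig, seed: int):
    """Fit enhancement/selection/classifier on train only; predict test."""
    if cfg.stage in ("weighted", "selected"):
        ccfg = SwarmConfig(
            n_particles=cfg.cluster_cfg.n_particles,
            max_iter=cfg.cluster_cfg.max_iter,
            seed=seed,
            stagnation_patience=cfg.cluster_cfg.stagnation_patience,
        )
        model = pso_cluster(train, K=train.n_classes, cfg=ccfg)
        w = compute_weights(model, train)
        train = apply_weights(train, w)
        test = apply_weights(test, w)
    if cfg.stage == "selected":
        scfg = SwarmConfig(
            n_particles=cfg.selection_cfg.n_particles,
            max_iter=cfg.selection_cfg.max_iter,
            w0=1.4,
            seed=seed + 1,
            stagnation_patience=cfg.selection_cfg.stagnation_patience,
        )
        fcfg = FitnessConfig(
            alpha=cfg.fitness_cfg.alpha,
            eval_folds=cfg.fitness_cfg.eval_folds,
            reg=cfg.fitness_cfg.reg,
            kernel_width=cfg.fitness_cfg.kernel_width,
            seed=seed + 2,
        )
        if cfg.selection_runs > 1:
            ens = run_selection_repeated(
                train, scfg, fcfg, runs=cfg.selection_runs, seed=seed + 1
            )
            selected = ens.most_frequent
            if not selected.any():  # no majority: best single run wins
                best = min(ens.masks, key=lambda m: m.fitness)
                selected = best.selected
        else:
            selected = run_selection(train, scfg, fcfg).selected
        train = train.select_columns(selected)
        test = test.select_columns(selected)
    clf = KernelELM(cfg.reg, cfg.kernel_width).fit(train.X, train.y)
    return clf.predict(test.X)


def summarize_confusion(counts: np.ndarray, classes) -> tuple[pd.DataFrame, float]:
    """Row-normalized percentages and the macro-average recognition rate."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    percent = pd.DataFrame(100.0 * counts / np.maximum(totals, 1), index=classes, columns=classes)
    avg_rate = float(100.0 * np.mean(np.diag(counts) / np.maximum(totals[:, 0], 1)))
    return percent, avg_rate


def evaluate(
    table: FeatureTable,
    protocol: Protocol,
    pipeline: PipelineConfig | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Run a protocol end to end and report pooled confusion and rates."""
    pipeline = pipeline or PipelineConfig()
    classes = np.unique(table.y)
    conf = np.zeros((len(classes), len(classes)))
    per_fold = []
    rng = np.random.default_rng(seed)
    for train_idx, test_idx in make_splits(table, protocol, seed):
        fold_seed = int(rng.integers(2**31 - 3))
        pred = _fit_fold(table.subset(train_idx), table.subset(test_idx), pipeline, fold_seed)
        truth = table.y[test_idx]
        fold_conf = np.zeros_like(conf)
        for yt, yp in zip(truth, pred):
            fold_conf[np.searchsorted(classes, yt), np.searchsorted(classes, yp)] += 1
        conf += fold_conf
        fold_totals = fold_conf.sum(axis=1)
        present = fold_totals > 0
        recalls = np.diag(fold_conf)[present] / fold_totals[present]
        per_fold.append(100.0 * recalls.mean())
    percent, avg_rate = summarize_confusion(conf, classes)
    return EvaluationReport(
        protocol=protocol.name,
        classes=tuple(classes),
        confusion_counts=conf,
        confusion_percent=percent,
        avg_rate=avg_rate,
        gmean=gmean(conf),
        per_fold_rates=np.asarray(per_fold),
    )


def paired_ttest(rates_a, rates_b, level: float = 0.05):
    """Two-sided paired t-test; returns (statistic, p-value, significant)."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if np.allclose(a - b, 0.0):
        raise ValueError("no variance: all paired differences are zero")
    stat, p = stats.ttest_rel(a, b)
    return float(stat), float(p), bool(p < level)
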