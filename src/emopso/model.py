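"""Model/Results front end for the full enhancement-selection-ELM pipeline.

``EmotionPSO`` is constructed from a labelled feature table (or a tidy
DataFrame) and ``fit()`` runs the configured stages — PSO cluster-center
weighting, binary-PSO wrapper selection, kernel-ELM training — returning an
``EmotionPSOResults`` that carries the fitted weights, the selected feature
subset, search diagnostics and a ``summary()`` table, and that can predict
new rows or cross-validate itself under the SD/SI/GD protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elm import KernelELM
from .enhancement import SwarmConfig, WeightVector, apply_weights, compute_weights, pso_cluster
from .evaluation import EvaluationReport, PipelineConfig, Protocol, evaluate
from .features import FeatureTable
from .selection import FitnessConfig, SelectionMask, run_selection

__all__ = ["EmotionPSO", "EmotionPSOResults"]


class EmotionPSO:
    """Speech-emotion recognition pipeline as a fittable model.

    Parameters
    ----------
    table:
        Labelled sample x feature table (emotion label + speaker per row).
    stage:
        ``"raw"`` (classifier only), ``"weighted"`` (adds cluster-center
        attribute weighting) or ``"selected"`` (adds wrapper feature
        selection on the weighted table).
    """

    def __init__(
        self,
        table: FeatureTable,
        stage: str = "selected",
        cluster_cfg: SwarmConfig | None = None,
        selection_cfg: SwarmConfig | None = None,
        fitness_cfg: FitnessConfig | None = None,
        reg: float = 100.0,
        kernel_width: float | None = None,
    ):
        if stage not in ("raw", "weighted", "selected"):
            raise ValueError("stage must be raw, weighted or selected")
        self.table = table
        self.stage = stage
        self.cluster_cfg = cluster_cfg or SwarmConfig(n_particles=15, max_iter=30)
        self.selection_cfg = selection_cfg or SwarmConfig(n_particles=12, max_iter=20, w0=1.4)
        self.fitness_cfg = fitness_cfg or FitnessConfig()
        self.reg = reg
        self.kernel_width = kernel_width

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        speaker_col: str = "speaker",
        sex_col: str | None = "sex",
        **kwargs,
    ) -> "EmotionPSO":
        return cls(FeatureTable.from_dataframe(df, label_col, speaker_col, sex_col), **kwargs)

    def fit(self, seed: int | None = None) -> "EmotionPSOResults":
        table = self.table
        weights = None
        mask = None
        if self.stage in ("weighted", "selected"):
            ccfg = _with_seed(self.cluster_cfg, seed)
            cluster = pso_cluster(table, K=table.n_classes, cfg=ccfg)
            weights = compute_weights(cluster, table)
            table = apply_weights(table, weights)
        if self.stage == "selected":
            scfg = _with_seed(self.selection_cfg, None if seed is None else seed + 1)
            fcfg = FitnessConfig(
                alpha=self.fitness_cfg.alpha,
                eval_folds=self.fitness_cfg.eval_folds,
                reg=self.fitness_cfg.reg,
                kernel_width=self.fitness_cfg.kernel_width,
                seed=None if seed is None else seed + 2,
            )
            mask = run_selection(table, scfg, fcfg)
            table = table.select_columns(mask.selected)
        clf = KernelELM(self.reg, self.kernel_width).fit(table.X, table.y)
        return EmotionPSOResults(model=self, weights=weights, mask=mask, classifier=clf, seed=seed)


def _with_seed(cfg: SwarmConfig, seed: int | None) -> SwarmConfig:
    return SwarmConfig(
        n_particles=cfg.n_particles,
        max_iter=cfg.max_iter,
        c1=cfg.c1,
        c2=cfg.c2,
        w0=cfg.w0,
        decay=cfg.decay,
        seed=cfg.seed if seed is None else seed,
        stagnation_patience=cfg.stagnation_patience,
    )


@dataclass
class EmotionPSOResults:
    """Fitted pipeline: weights, selected subset, classifier, diagnostics."""

    model: EmotionPSO
    weights: WeightVector | None
    mask: SelectionMask | None
    classifier: KernelELM
    seed: int | None = None

    # -- prediction --------------------------------------------------------
    def predict(self, rows) -> np.ndarray:
        """Predict emotion labels for raw-scale feature rows."""
        if isinstance(rows, pd.DataFrame):
            rows = rows.to_numpy(dtype=float)
        X = np.asarray(rows, dtype=float)
        if self.weights is not None:
            X = X * self.weights.weights
        if self.mask is not None:
            X = X[:, self.mask.selected]
        return self.classifier.predict(X)

    def cross_validate(self, protocol: Protocol | str = "SD", seed: int | None = None) -> EvaluationReport:
        """Re-run the configured pipeline under an evaluation protocol."""
        if isinstance(protocol, str):
            protocol = Protocol(protocol)
        m = self.model
        pipe = PipelineConfig(
            stage=m.stage,
            cluster_cfg=m.cluster_cfg,
            selection_cfg=m.selection_cfg,
            fitness_cfg=m.fitness_cfg,
            reg=m.reg,
            kernel_width=m.kernel_width,
        )
        return evaluate(m.table, protocol, pipe, seed=self.seed if seed is None else seed)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Emotion recognition pipeline (PSO weighting + selection + kernel ELM)",
            "=" * 68,
            f"stage:           {m.stage}",
            f"samples:         {len(m.table.labels)}",
            f"features:        {m.table.n_features}",
            f"classes:         {m.table.n_classes} "
            f"({', '.join(map(str, pd.unique(m.table.labels)))})",
            "kernel ELM:      reg=%g, width=%s"
            % (m.reg, "median heuristic" if m.kernel_width is None else f"{m.kernel_width:g}"),
        ]
        if self.weights is not None:
            w = self.weights.weights
            lines.append(f"weights:         min={w.min():.3g} median={np.median(w):.3g} max={w.max():.3g}")
        if self.mask is not None:
            lines += [
                f"selected:        {self.mask.n_selected}/{m.table.n_features} features",
                f"wrapper G-mean:  {self.mask.gmean:.4f}",
                f"final fitness:   {self.mask.fitness:.6f}",
            ]
            counts = self.mask.per_family_counts()
            if any("." in name for name in self.mask.names):
                lines.append("selected per stream/family:")
                lines += [f"  {key:<18s} {cnt}" for key, cnt in sorted(counts.items())]
            else:
                names = [n for n, k in zip(self.mask.names, self.mask.selected) if k]
                shown = ", ".join(names[:8]) + (", ..." if len(names) > 8 else "")
                lines.append(f"selected columns: {shown}")
        return "\n".join(lines)
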