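"""Synthetic corpora with known ground truth.

Two generators stand in for licensed emotional-speech corpora:

* a source-filter vowel synthesizer — a raised-cosine glottal-flow pulse
  train (with jitter/shimmer perturbations and additive noise) driving a
  cascade of formant resonators — whose true glottal source is returned for
  inverse-filtering oracles;
* a Gaussian-cluster feature-table generator with a known set of informative
  dimensions and a controllable inter-class separation, for clustering,
  weighting and selection oracles.

"Emotion classes" vary the source (f0, jitter, shimmer, energy); "speakers"
vary the vocal tract (formant positions). Everything is fully determined by
the seeds carried in the specs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .features import FeatureTable
from .glottal import GlottalWaveform
from .preprocess import TARGET_RATE, AudioSignal, write_wav

__all__ = ["VowelSpec", "ClusterSpec", "synth_vowel", "synth_corpus", "synth_table", "SyntheticTable"]

_DEFAULT_FORMANTS = ((730.0, 90.0), (1090.0, 110.0), (2440.0, 170.0))  # vowel /a/


@dataclass(frozen=True)
class VowelSpec:
    """Parameters of one synthetic vowel utterance."""

    f0: float = 120.0  # fundamental, Hz
    formants: tuple = _DEFAULT_FORMANTS  # ((center, bandwidth), ...) in Hz
    jitter: float = 0.01  # fractional cycle-to-cycle f0 perturbation
    shimmer: float = 0.05  # fractional cycle-to-cycle amplitude perturbation
    noise_snr: float = 30.0  # dB
    duration: float = 1.0  # s
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 50.0 <= self.f0 <= 400.0:
            raise ValueError("f0 must lie in [50, 400] Hz")
        if self.duration < 0.5:
            raise ValueError("duration must be >= 0.5 s")


@dataclass(frozen=True)
class ClusterSpec:
    """Parameters of a synthetic Gaussian-cluster feature table."""

    n_classes: int = 4
    n_per_class: int = 30
    n_informative: int = 5
    n_noise: int = 45
    separation: float = 4.0  # inter-class mean distance, within-class sigma units
    baseline: float = 8.0  # per-dimension mean offset scale (0 -> centered table)
    n_speakers: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1 or self.separation < 0:
            raise ValueError("invalid cluster spec")


def synth_vowel(spec: VowelSpec) -> tuple[AudioSignal, GlottalWaveform]:
    """Render one vowel; returns (audio, true glottal flow).

    The flow pulse is a raised cosine over the open phase (open quotient
    0.6); its first difference excites the formant cascade. Noise is added
    at ``spec.noise_snr`` dB relative to the clean signal power.
    """
    rng = np.random.default_rng(spec.seed)
    rate = TARGET_RATE
    n = int(round(spec.duration * rate))
    flow = np.zeros(n)
    pos = 0
    open_q = 0.6
    while pos < n:
        period = rate / (spec.f0 * (1.0 + spec.jitter * rng.standard_normal()))
        period = max(int(round(period)), 8)
        amp = spec.amplitude * (1.0 + spec.shimmer * rng.standard_normal())
        n_open = max(int(round(open_q * period)), 2)
        t = np.arange(min(n_open, n - pos))
        flow[pos : pos + len(t)] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / n_open))
        pos += period
    source = np.diff(flow, prepend=0.0)
    speech = source
    for fc, bw in spec.formants:
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * fc / rate
        speech = lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], speech)
    if np.isfinite(spec.noise_snr):
        p_sig = np.mean(speech**2)
        p_noise = p_sig / (10.0 ** (spec.noise_snr / 10.0))
        speech = speech + rng.standard_normal(n) * np.sqrt(p_noise)
    peak = np.max(np.abs(speech))
    if peak > 0:
        speech = 0.9 * speech / peak
    return AudioSignal(speech, rate), GlottalWaveform(flow, lp_order=0)


def default_class_specs(n_classes: int = 4) -> dict[str, VowelSpec]:
    """Emotion-like classes differing in source statistics.

    Loosely styled after arousal differences: higher f0 / jitter / energy for
    high-arousal classes, low and breathy for low-arousal ones.
    """
    all_specs = {
        "angry": VowelSpec(f0=220.0, jitter=0.03, shimmer=0.10, amplitude=1.4, noise_snr=25.0),
        "happy": VowelSpec(f0=180.0, jitter=0.02, shimmer=0.06, amplitude=1.1, noise_snr=30.0),
        "neutral": VowelSpec(f0=120.0, jitter=0.01, shimmer=0.04, amplitude=1.0, noise_snr=35.0),
        "sad": VowelSpec(f0=90.0, jitter=0.005, shimmer=0.02, amplitude=0.7, noise_snr=30.0),
    }
    names = list(all_specs)[:n_classes]
    return {k: all_specs[k] for k in names}


def synth_corpus(
    out_dir: str | Path,
    classes: dict[str, VowelSpec] | None = None,
    speakers: int = 4,
    per_speaker: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a WAV corpus plus manifest (path, label, speaker, sex).

    Speaker identity scales the formant frequencies (shorter vocal tracts —
    the second half of the speakers, tagged F — sit above 1.0); class
    identity carries the source parameters from ``classes``.
    """
    if classes is None:
        classes = default_class_specs()
    if len(classes) < 2 or speakers < 2:
        raise ValueError("need >= 2 classes and >= 2 speakers")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    factors = np.linspace(0.88, 1.15, speakers)
    rows = []
    for s, factor in enumerate(factors):
        sex = "M" if factor <= 1.0 else "F"
        for label, base in classes.items():
            for r in range(per_speaker):
                formants = tuple((fc * factor, bw) for fc, bw in base.formants)
                spec = replace(
                    base, formants=formants, seed=int(rng.integers(2**31 - 1))
                )
                audio, _ = synth_vowel(spec)
                fname = f"{label}_spk{s}_{r:02d}.wav"
                write_wav(out_dir / fname, audio)
                rows.append({"path": fname, "label": label, "speaker": f"spk{s}", "sex": sex})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps({"seed": seed, "speakers": speakers, "per_speaker": per_speaker,
                    "classes": sorted(classes)}, indent=2)
    )
    return manifest


@dataclass(frozen=True)
class SyntheticTable:
    """A generated feature table plus its ground truth."""

    table: FeatureTable
    informative: np.ndarray  # indices of the informative dimensions
    class_means: np.ndarray  # (n_classes, n_informative)


def synth_table(spec: ClusterSpec) -> SyntheticTable:
    """Gaussian class clusters with known informative dimensions.

    Class means live in the informative subspace with mean pairwise distance
    equal to ``spec.separation`` (within-class sigma = 1); the noise
    dimensions are label-independent unit-variance normal. Every column
    additionally carries a fixed baseline offset drawn once from
    ``N(baseline, (baseline/4)^2)`` — real acoustic features (log energies,
    cepstra, entropies) sit on strong nonzero baselines, and the
    ratio-of-means attribute weighting is only meaningful in that regime.
    Offsets leave all pairwise distances (hence clustering, the Gaussian
    kernel and selection) untouched; ``baseline=0`` gives a centered table.
    """
    rng = np.random.default_rng(spec.seed)
    K, m = spec.n_classes, spec.n_informative
    means = rng.standard_normal((K, m))
    means -= means.mean(axis=0)
    if K > 1 and spec.separation > 0:
        dists = [np.linalg.norm(means[i] - means[j]) for i in range(K) for j in range(i + 1, K)]
        means *= spec.separation / np.mean(dists)
    elif spec.separation == 0:
        means[:] = 0.0
    n = K * spec.n_per_class
    X = np.empty((n, m + spec.n_noise))
    labels = np.empty(n, dtype=object)
    for k in range(K):
        sl = slice(k * spec.n_per_class, (k + 1) * spec.n_per_class)
        X[sl, :m] = means[k] + rng.standard_normal((spec.n_per_class, m))
        labels[sl] = f"class{k}"
    X[:, m:] = rng.standard_normal((n, spec.n_noise))
    if spec.baseline:
        X += rng.normal(spec.baseline, abs(spec.baseline) / 4.0, size=X.shape[1])
    perm = rng.permutation(m + spec.n_noise)
    X = X[:, perm]
    informative = np.flatnonzero(np.isin(perm, np.arange(m)))
    cols = [f"f{j:03d}" for j in range(X.shape[1])]
    speakers = np.array([f"spk{i % spec.n_speakers}" for i in range(n)])
    sex = np.array(["M" if int(s[3:]) < spec.n_speakers / 2 else "F" for s in speakers])
    table = FeatureTable(pd.DataFrame(X, columns=cols), pd.Series(labels), pd.Series(speakers), pd.Series(sex))
    return SyntheticTable(table, informative, means)
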