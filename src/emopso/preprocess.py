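"""Audio ingestion: WAV reading, resampling to 8 kHz, pre-emphasis, voicing.

The front end mirrors the classic emotional-speech recipe: every recording is
down-sampled to 8 kHz, cut into non-overlapping 32 ms (256-sample) frames,
low-energy (unvoiced/silence) frames are discarded and the survivors are
concatenated, and the result is spectrally flattened with the first-order
pre-emphasis filter H(z) = 1 - a z^-1 (a = 15/16 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

TARGET_RATE = 8000
DEFAULT_FRAME_LEN = 256  # 32 ms at 8 kHz
DEFAULT_ENERGY_FRAC = 0.1


class NoVoicedContentError(ValueError):
    """Raised when every frame falls below the voicing energy threshold."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono amplitude sequence with its sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("AudioSignal requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class PreEmphasisConfig:
    """Coefficient of the pre-emphasis filter H(z) = 1 - a z^-1; 0.9 <= a <= 1."""

    a: float = 0.9375

    def __post_init__(self) -> None:
        if not 0.9 <= self.a <= 1.0:
            raise ValueError("pre-emphasis coefficient must satisfy 0.9 <= a <= 1.0")


@dataclass(frozen=True)
class VoicedSignal:
    """Concatenation of the energy-retained frames of an 8 kHz signal."""

    samples: np.ndarray
    kept_frames: np.ndarray = field(repr=False)
    frame_len: int = DEFAULT_FRAME_LEN

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        kept = np.asarray(self.kept_frames, dtype=int)
        if len(samples) % self.frame_len:
            raise ValueError("voiced length must be a multiple of frame_len")
        if kept.size and np.any(np.diff(kept) <= 0):
            raise ValueError("kept_frames must be strictly increasing")
        samples.setflags(write=False)
        kept.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "kept_frames", kept)

    @property
    def rate(self) -> int:
        return TARGET_RATE


def read_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF/WAV file; integer PCM is scaled to [-1, 1], stereo averaged."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return AudioSignal(data.astype(float), int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    wavfile.write(str(path), signal.rate, signal.samples.astype(np.float32))


def resample_to_8k(signal: AudioSignal) -> AudioSignal:
    """Polyphase anti-aliased resampling to 8 kHz (identity at 8 kHz)."""
    if signal.rate == TARGET_RATE:
        return signal
    frac = Fraction(TARGET_RATE, signal.rate)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, TARGET_RATE)


def pre_emphasize(signal: AudioSignal, cfg: PreEmphasisConfig | None = None) -> AudioSignal:
    """y(n) = x(n) - a x(n-1) with y(0) = x(0) (x(-1) = 0 convention)."""
    cfg = cfg or PreEmphasisConfig()
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - cfg.a * x[:-1]
    return AudioSignal(y, signal.rate)


def select_voiced(
    signal: AudioSignal,
    frame_len: int = DEFAULT_FRAME_LEN,
    threshold_frac: float = DEFAULT_ENERGY_FRAC,
) -> VoicedSignal:
    """Keep non-overlapping frames whose energy >= threshold_frac x mean energy.

    The trailing partial frame is dropped; frames are concatenated in order.
    Raises NoVoicedContentError when nothing survives.
    """
    if signal.rate != TARGET_RATE:
        raise ValueError("select_voiced expects an 8 kHz signal; resample first")
    if frame_len < 1:
        raise ValueError("frame_len must be >= 1")
    n_frames = len(signal.samples) // frame_len
    if n_frames == 0:
        raise NoVoicedContentError("signal shorter than one frame")
    frames = signal.samples[: n_frames * frame_len].reshape(n_frames, frame_len)
    energies = np.sum(frames**2, axis=1)
    kept = np.flatnonzero(energies >= threshold_frac * energies.mean())
    if kept.size == 0:
        raise NoVoicedContentError("no frame passes the voicing energy threshold")
    log.debug("select_voiced: kept %d/%d frames", kept.size, n_frames)
    return VoicedSignal(frames[kept].reshape(-1), kept, frame_len)


def preprocess_audio(
    signal: AudioSignal,
    cfg: PreEmphasisConfig | None = None,
    frame_len: int = DEFAULT_FRAME_LEN,
    threshold_frac: float = DEFAULT_ENERGY_FRAC,
) -> VoicedSignal:
    """Full front end: resample -> voiced-frame selection -> pre-emphasis."""
    voiced = select_voiced(resample_to_8k(signal), frame_len, threshold_frac)
    emphasized = pre_emphasize(AudioSignal(voiced.samples, TARGET_RATE), cfg)
    return VoicedSignal(emphasized.samples, voiced.kept_frames, frame_len)
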