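"""Glottal waveform estimation by linear-prediction inverse filtering.

A two-pass, IAIF-flavoured scheme run frame by frame on the pre-emphasized
voiced signal: a low-order (2) LP fit captures the residual glottal spectral
tilt, its inverse removes that tilt before the vocal-tract LP fit (order 12
by default), the original frame is inverse-filtered by the vocal-tract model
and the residual is leakily integrated (coefficient 0.99) to approximate the
glottal flow. Frames are Hamming-weighted and overlap-added back to the full
signal length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .preprocess import VoicedSignal

log = logging.getLogger(__name__)

__all__ = ["GlottalWaveform", "estimate_glottal", "lpc"]


@dataclass(frozen=True)
class GlottalWaveform:
    """Estimated glottal flow at 8 kHz, same length as its source signal."""

    samples: np.ndarray
    lp_order: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("glottal samples must be finite")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)


def lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LP via Levinson-Durbin.

    Returns the error-filter polynomial ``A = [1, a_1, ..., a_p]`` such that
    ``lfilter(A, 1, x)`` is the prediction residual, or ``None`` for a
    degenerate (all-zero / numerically singular) frame.
    """
    x = np.asarray(frame, dtype=float)
    n = len(x)
    if order >= n:
        raise ValueError("lp order must be smaller than the frame length")
    r = np.correlate(x, x, mode="full")[n - 1 : n + order]
    if r[0] <= 0.0:
        return None
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[1:i][::-1]
        k = -acc / err
        a[1 : i + 1] = a[1 : i + 1] + k * a[i - 1 :: -1][: i]
        err *= 1.0 - k * k
        if err <= 0.0 or not np.isfinite(err):
            return None
    return a


def estimate_glottal(
    voiced: VoicedSignal,
    lp_order: int = 12,
    frame_len: int = 256,
    hop: int = 128,
    leak: float = 0.99,
    de_emphasis: float = 0.9375,
) -> GlottalWaveform:
    """Two-pass LP inverse filtering of a pre-emphasized voiced signal.

    The front end's pre-emphasis (coefficient ``de_emphasis``; 0 disables)
    is first undone by its exact inverse 1/(1 - a z^-1), since an extra
    differentiation in the input shifts the recovered source one derivative
    away from the glottal flow. Deterministic; all-zero frames pass through
    as zeros (with a warning). Output length equals input length.
    """
    x = voiced.samples
    if de_emphasis:
        x = lfilter([1.0], [1.0, -de_emphasis], x)
    n = len(x)
    if n == 0:
        raise ValueError("voiced signal is empty")
    if lp_order >= frame_len:
        raise ValueError("lp_order must be < frame_len")
    if n < frame_len:
        frame_len = n
        hop = max(1, n // 2)

    starts = list(range(0, n - frame_len + 1, hop))
    if starts[-1] + frame_len < n:  # cover the tail
        starts.append(n - frame_len)
    window = np.hamming(frame_len)
    out = np.zeros(n)
    wsum = np.zeros(n)
    n_bad = 0
    for s in starts:
        frame = x[s : s + frame_len]
        a_tilt = lpc(frame * window, min(2, frame_len - 1))
        if a_tilt is None:
            n_bad += 1
            continue
        detilted = lfilter(a_tilt, [1.0], frame)
        a_tract = lpc(detilted * window, min(lp_order, frame_len - 1))
        if a_tract is None:
            n_bad += 1
            continue
        resid = lfilter(a_tract, [1.0], frame)
        flow = lfilter([1.0], [1.0, -leak], resid)
        out[s : s + frame_len] += flow * window
        wsum[s : s + frame_len] += window
    if n_bad:
        warnings.warn(f"{n_bad} degenerate frame(s) passed through as zeros")
    nz = wsum > 1e-12
    out[nz] /= wsum[nz]
    return GlottalWaveform(out, lp_order)
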