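"""Daubechies wavelet filters, stationary wavelet transform and wavelet packets.

Minimal orthogonal-wavelet machinery: the analysis filters are built by
spectral factorization of the Daubechies polynomial, the SWT is the
undecimated (a trous) transform with periodic wrapping, and the wavelet
packet transform is the fully decimated binary tree with periodization so
that node lengths halve exactly at every level.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np

__all__ = ["daubechies_filters", "swt", "wpt_nodes"]


@lru_cache(maxsize=None)
def daubechies_filters(n_vanishing: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi) analysis filters for dbN, length ``2 * n_vanishing``.

    Constructed by rooting the Daubechies polynomial
    ``P(y) = sum_k C(N-1+k, k) y^k`` and keeping the minimum-phase half of
    the zeros, i.e. the standard extremal-phase db family.
    """
    n = int(n_vanishing)
    if n < 1:
        raise ValueError("n_vanishing must be >= 1")
    poly = np.array([comb(n - 1 + k, k) for k in range(n)], dtype=float)
    yroots = np.roots(poly[::-1]) if n > 1 else np.array([])
    h = np.array([1.0], dtype=complex)
    for _ in range(n):  # (1 + z)^N factor: the N vanishing moments
        h = np.convolve(h, [0.5, 0.5])
    for y in yroots:
        zpair = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        h = np.convolve(h, [1.0, -zpair[np.argmin(np.abs(zpair))]])
    lo = np.real(h)
    lo *= np.sqrt(2.0) / lo.sum()
    hi = lo[::-1].copy()
    hi[1::2] *= -1.0
    lo.setflags(write=False)
    hi.setflags(write=False)
    return lo, hi


def _periodic_conv(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Circular convolution of x with filt, same length as x.

    Folds the linear convolution back period by period:
    ``c[n] = sum_j l[n + j*len(x)]``.
    """
    nx = len(x)
    full = np.convolve(x, filt)
    out = np.zeros(nx)
    for start in range(0, len(full), nx):
        seg = full[start : start + nx]
        out[: len(seg)] += seg
    return out


def swt(x: np.ndarray, levels: int, n_vanishing: int = 10) -> list[np.ndarray]:
    """Undecimated wavelet decomposition.

    Returns ``[cA_L, cD_L, cD_{L-1}, ..., cD_1]`` — each the same length as
    ``x``, whose length must be a multiple of ``2**levels``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("swt expects a non-empty 1-D signal")
    if len(x) % (1 << levels):
        raise ValueError(f"signal length {len(x)} not a multiple of 2^{levels}")
    lo, hi = daubechies_filters(n_vanishing)
    approx = x
    details: list[np.ndarray] = []
    for j in range(levels):
        if j == 0:
            lo_j, hi_j = lo, hi
        else:  # a trous: insert 2^j - 1 zeros between taps
            lo_j = np.zeros((len(lo) - 1) * (1 << j) + 1)
            hi_j = np.zeros_like(lo_j)
            lo_j[:: 1 << j] = lo
            hi_j[:: 1 << j] = hi
        details.append(_periodic_conv(approx, hi_j))
        approx = _periodic_conv(approx, lo_j)
    return [approx] + details[::-1]


def _analysis_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """One periodized filter-and-decimate step; output length ceil(len/2)."""
    n = len(x)
    if n % 2:
        x = np.concatenate([x, x[-1:]])  # odd length: repeat edge sample
    return _periodic_conv(x, filt)[1::2]


def wpt_nodes(x: np.ndarray, levels: int, n_vanishing: int = 10) -> list[np.ndarray]:
    """Wavelet packet coefficients for every node of levels 1..levels.

    Natural (Paley) order within each level: the returned list is
    ``[(1,0), (1,1), (2,0), ..., (levels, 2**levels - 1)]`` —
    ``2 + 4 + ... + 2**levels`` nodes in total (30 for 4 levels).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("wpt expects a 1-D signal with at least 2 samples")
    lo, hi = daubechies_filters(n_vanishing)
    out: list[np.ndarray] = []
    level = [x]
    for _ in range(levels):
        nxt: list[np.ndarray] = []
        for node in level:
            nxt.append(_analysis_step(node, lo))
            nxt.append(_analysis_step(node, hi))
        out.extend(nxt)
        level = nxt
    return out
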