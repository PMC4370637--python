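"""The 614-dimensional acoustic/glottal feature vector.

Seven families are extracted from each of the two streams (voiced speech and
its estimated glottal waveform), 307 values per stream:

========  ====  =============================================================
family    size  summary
========  ====  =============================================================
mfcc        24  Mel-frequency cepstra, frame-averaged
lpcc        18  LP-derived cepstra (LPC order 12, recursion extended to 18)
gtfb        24  log mean energies of a 24-channel ERB-spaced gammatone bank
plp         13  perceptual linear prediction cepstra (Bark/equal-loudness/
                cube-root front end, all-pole order 12)
ttf         24  6 timbral texture series x 4 summary statistics
swt        144  the same 6 x 4 on each of 6 stationary-wavelet subbands (db10)
rwpf        60  relative wavelet-packet energy + entropy over the 30 nodes of
                a 4-level db10 packet tree, frame-averaged
========  ====  =============================================================

All framing is 32 ms (256 samples at 8 kHz) with 50% overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import gammatone as gammatone_design
from scipy.signal import lfilter

from ._wavelets import swt, wpt_nodes
from .glottal import GlottalWaveform, lpc
from .preprocess import TARGET_RATE, VoicedSignal

log = logging.getLogger(__name__)

FRAME_LEN = 256
HOP = 128
LOG_FLOOR = 1e-10

FAMILY_SIZES = {"mfcc": 24, "lpcc": 18, "gtfb": 24, "plp": 13, "ttf": 24, "swt": 144, "rwpf": 60}
STREAM_SIZE = 307  # sum of the family sizes
TOTAL_SIZE = 614

_TTF_SERIES = ("centroid", "flux", "rolloff", "entropy", "energy", "zcr")
_TTF_STATS = ("std", "maxstd", "maxmed", "varmean")
_SWT_BANDS = ("ca5", "cd5", "cd4", "cd3", "cd2", "cd1")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature front end (defaults follow the published recipe)."""

    frame_len: int = FRAME_LEN
    hop: int = HOP
    n_mel_filters: int = 26
    lpc_order: int = 12
    sample_std: bool = True  # ddof=1 in the timbral statistics
    rwpf_energy: str = "as-printed"  # or "energy": log10(sum|C|^2 / L)


# ---------------------------------------------------------------------------
# framing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSequence:
    frames: np.ndarray  # (n_frames, frame_len)
    frame_len: int
    hop: int
    window: str


def frame_signal(
    signal: np.ndarray, frame_len: int = FRAME_LEN, hop: int = HOP, window: str = "hamming"
) -> FrameSequence:
    """Slice into overlapping frames and apply the named taper."""
    x = np.asarray(signal, dtype=float)
    if len(x) < frame_len:
        raise ValueError("signal shorter than one frame")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    if window == "hamming":
        frames = frames * np.hamming(frame_len)
    elif window not in ("rect", "rectangular", "boxcar"):
        raise ValueError(f"unknown window {window!r}")
    return FrameSequence(frames, frame_len, hop, window)


# ---------------------------------------------------------------------------
# cepstral families
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, rate: int) -> np.ndarray:
    """Triangular filters on a mel grid over [0, rate/2]; (n_filters, nfft//2+1)."""
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(rate / 2), n_filters + 2))
    bins = np.fft.rfftfreq(nfft, d=1.0 / rate)
    bank = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        bank[i] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mfcc24(voiced: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Frame-averaged MFCCs: power spectrum -> mel bank -> log -> DCT-II, 24 coeffs."""
    cfg = cfg or FeatureConfig()
    frames = frame_signal(voiced, cfg.frame_len, cfg.hop, "hamming").frames
    power = np.abs(rfft(frames, axis=1)) ** 2
    bank = _mel_filterbank(cfg.n_mel_filters, cfg.frame_len, TARGET_RATE)
    logmel = np.log(np.maximum(power @ bank.T, LOG_FLOOR))
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, :24]
    return coeffs.mean(axis=0)


def _lpc_to_cepstrum(a_poly: np.ndarray, n_ceps: int) -> np.ndarray:
    """Cepstra of the all-pole model 1/A(z); a_poly = [1, a_1..a_p].

    Standard recursion with predictor coefficients b_k = -a_k:
    c_n = b_n + sum_{k=1}^{n-1} (k/n) c_k b_{n-k}.
    """
    p = len(a_poly) - 1
    b = np.zeros(n_ceps + 1)
    b[1 : p + 1] = -a_poly[1:]
    c = np.zeros(n_ceps + 1)
    for n in range(1, n_ceps + 1):
        c[n] = b[n] + sum(k / n * c[k] * b[n - k] for k in range(1, n))
    return c[1:]


def lpcc18(voiced: np.ndarray, lpc_order: int = 12, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Frame-averaged LP cepstra: Levinson-Durbin order-12 LPC, recursion to 18."""
    cfg = cfg or FeatureConfig()
    frames = frame_signal(voiced, cfg.frame_len, cfg.hop, "hamming").frames
    acc, n_ok = np.zeros(18), 0
    for frame in frames:
        a = lpc(frame, lpc_order)
        if a is None:
            continue
        acc += _lpc_to_cepstrum(a, 18)
        n_ok += 1
    if n_ok == 0:
        warnings.warn("lpcc18: every frame degenerate; returning zeros")
        return np.zeros(18)
    return acc / n_ok


def erb_space(low: float, high: float, n: int) -> np.ndarray:
    """n center frequencies equally spaced on the ERB-rate scale, ascending."""
    ear_q, min_bw = 9.26449, 24.7
    k = ear_q * min_bw
    fcs = -k + np.exp(np.arange(1, n + 1) * (np.log(low + k) - np.log(high + k)) / n) * (high + k)
    return fcs[::-1].copy()


def gtfb24(voiced: np.ndarray, n_channels: int = 24) -> np.ndarray:
    """Log mean energy per channel of a 4th-order gammatone filterbank.

    ERB-spaced centers over [50, 3999] Hz (the top edge backed off one bin
    from Nyquist, which the IIR design excludes).
    """
    x = np.asarray(voiced, dtype=float)
    out = np.empty(n_channels)
    for i, fc in enumerate(erb_space(50.0, 3999.0, n_channels)):
        b, a = gammatone_design(fc, "iir", fs=TARGET_RATE)
        y = lfilter(b, a, x)
        out[i] = np.log10(np.mean(y**2) + LOG_FLOOR)
    return out


def _bark(f):
    return 6.0 * np.arcsinh(np.asarray(f) / 600.0)


def _equal_loudness(f):
    f2 = np.asarray(f, dtype=float) ** 2
    return ((f2 + 56.8e6) * f2**2) / ((f2 + 6.3e6) ** 2 * (f2 + 0.38e9))


def plp13(voiced: np.ndarray, model_order: int = 12, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Perceptual linear prediction cepstra (13 values, frame-averaged).

    Per frame: power spectrum -> triangular critical-band integration on the
    Bark scale (1-Bark spacing) -> equal-loudness preemphasis -> cube-root
    intensity-loudness compression -> autocorrelation via inverse DFT ->
    order-12 all-pole fit -> cepstra c0..c12 (c0 = log model error).
    """
    cfg = cfg or FeatureConfig()
    frames = frame_signal(voiced, cfg.frame_len, cfg.hop, "hamming").frames
    power = np.abs(rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(cfg.frame_len, d=1.0 / TARGET_RATE)
    zmax = _bark(TARGET_RATE / 2)
    centers = np.arange(1.0, zmax)  # 1-Bark spacing, interior centers
    z = _bark(freqs)
    bank = np.clip(1.0 - np.abs(z[None, :] - centers[:, None]), 0.0, None)
    loud = _equal_loudness(600.0 * np.sinh(centers / 6.0))
    aud = (np.maximum(power @ bank.T, LOG_FLOOR) * loud) ** (1.0 / 3.0)
    # symmetrize (Hermansky's duplicated endpoints) and invert to autocorrelation
    spec = np.concatenate([aud[:, :1], aud, aud[:, -1:]], axis=1)
    full = np.concatenate([spec, spec[:, -2:0:-1]], axis=1)
    r = np.fft.ifft(full, axis=1).real[:, : model_order + 1]
    acc, n_ok = np.zeros(13), 0
    for rf in r:
        if rf[0] <= 0:
            continue
        a, err = _levinson_from_r(rf, model_order)
        if a is None:
            continue
        ceps = np.empty(13)
        ceps[0] = np.log(max(err, LOG_FLOOR))
        ceps[1:] = _lpc_to_cepstrum(a, 12)
        acc += ceps
        n_ok += 1
    if n_ok == 0:
        warnings.warn("plp13: every frame degenerate; returning zeros")
        return np.zeros(13)
    return acc / n_ok


def _levinson_from_r(r: np.ndarray, order: int):
    """Levinson-Durbin on a given autocorrelation; returns (A-poly, error)."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[1:i][::-1]
        k = -acc / err
        a[1 : i + 1] = a[1 : i + 1] + k * a[i - 1 :: -1][:i]
        err *= 1.0 - k * k
        if err <= 0.0 or not np.isfinite(err):
            return None, 0.0
    return a, err


# ---------------------------------------------------------------------------
# timbral texture features
# ---------------------------------------------------------------------------


def timbral_sequence(frames: FrameSequence) -> dict[str, np.ndarray]:
    """Six per-frame timbral series.

    centroid and rolloff in Hz, flux as the L2 change of successive unit-norm
    magnitude spectra (length n_frames - 1), energy entropy in bits over 8
    sub-blocks, short-time energy as mean square, zero-crossing rate per
    sample. Needs >= 2 frames (flux is a difference series).
    """
    x = frames.frames
    if x.shape[0] < 2:
        raise ValueError("timbral_sequence needs at least 2 frames")
    rate = TARGET_RATE
    mag = np.abs(rfft(x, axis=1))
    freqs = np.fft.rfftfreq(frames.frame_len, d=1.0 / rate)
    msum = mag.sum(axis=1)
    centroid = np.where(msum > 0, (mag * freqs).sum(axis=1) / np.maximum(msum, 1e-300), 0.0)

    norms = np.linalg.norm(mag, axis=1, keepdims=True)
    unit = np.where(norms > 0, mag / np.maximum(norms, 1e-300), 0.0)
    flux = np.linalg.norm(np.diff(unit, axis=0), axis=1)

    psd = mag**2
    cum = np.cumsum(psd, axis=1)
    total = cum[:, -1]
    thresh = 0.9 * total[:, None]
    roll_idx = np.argmax(cum >= thresh, axis=1)
    rolloff = np.where(total > 0, freqs[roll_idx], 0.0)

    n_sub = 8
    sub = x[:, : (frames.frame_len // n_sub) * n_sub].reshape(x.shape[0], n_sub, -1)
    sub_e = np.sum(sub**2, axis=2)
    tot_e = sub_e.sum(axis=1, keepdims=True)
    p = np.where(tot_e > 0, sub_e / np.maximum(tot_e, 1e-300), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)

    energy = np.mean(x**2, axis=1)
    zcr = np.mean(np.abs(np.diff(np.sign(x), axis=1)) > 0, axis=1)
    return {
        "centroid": centroid,
        "flux": flux,
        "rolloff": rolloff,
        "entropy": entropy,
        "energy": energy,
        "zcr": zcr,
    }


def ttf_stats(series: np.ndarray, sample_std: bool = True) -> np.ndarray:
    """(sigma, max/sigma, max/median, sigma^2/mu^2); zero denominators give 0."""
    s = np.asarray(series, dtype=float)
    if len(s) < 2:
        raise ValueError("ttf_stats needs a series of length >= 2")
    sigma = float(np.std(s, ddof=1 if sample_std else 0))
    mx, med, mu = float(np.max(s)), float(np.median(s)), float(np.mean(s))
    return np.array(
        [
            sigma,
            mx / sigma if sigma != 0 else 0.0,
            mx / med if med != 0 else 0.0,
            sigma**2 / mu**2 if mu != 0 else 0.0,
        ]
    )


def ttf24(voiced: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """6 timbral series x 4 statistics on rectangular 32 ms / 50% frames."""
    cfg = cfg or FeatureConfig()
    frames = frame_signal(voiced, cfg.frame_len, cfg.hop, "rect")
    series = timbral_sequence(frames)
    return np.concatenate([ttf_stats(series[name], cfg.sample_std) for name in _TTF_SERIES])


def swt_ttf144(voiced: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Timbral statistics on the 6 subbands of a 5-level db10 SWT.

    The input is symmetrically padded to a multiple of 32, decomposed, and
    each coefficient sequence (cA5, cD5..cD1) is truncated back to the input
    length and summarized exactly like the time-domain timbral family.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(voiced, dtype=float)
    n = len(x)
    if n < cfg.frame_len + cfg.hop:
        raise ValueError("signal too short for SWT timbral analysis")
    block = 32
    pad = (-n) % block
    if pad:
        x = np.pad(x, (0, pad), mode="symmetric")
    bands = [c[:n] for c in swt(x, levels=5, n_vanishing=10)]
    out = []
    for band in bands:
        frames = frame_signal(band, cfg.frame_len, cfg.hop, "rect")
        series = timbral_sequence(frames)
        out.extend(ttf_stats(series[name], cfg.sample_std) for name in _TTF_SERIES)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# relative wavelet packet energy / entropy
# ---------------------------------------------------------------------------


def rwpf_frame(frame: np.ndarray, cfg: FeatureConfig | None = None):
    """Relative wavelet-packet energy and entropy of one frame, or None.

    Over the 30 nodes (j,k) of the 4-level db10 packet tree:
    ``EGY_{j,k} = log10(sum|C| / L^2)`` (as-printed normalization; the
    log-energy alternative ``log10(sum|C|^2 / L)`` sits behind
    ``cfg.rwpf_energy``) and ``EPY_{j,k} = -sum |C|^2 log10 |C|^2`` with
    0*log0 := 0. Each is divided by its total over nodes, so both vectors
    sum to one. Returns None for frames where a total degenerates.
    """
    cfg = cfg or FeatureConfig()
    nodes = wpt_nodes(frame, levels=4, n_vanishing=10)
    egy = np.empty(len(nodes))
    epy = np.empty(len(nodes))
    for i, c in enumerate(nodes):
        absc = np.abs(c)
        length = len(c)
        s1 = absc.sum()
        if s1 <= 0:
            return None
        if cfg.rwpf_energy == "as-printed":
            egy[i] = np.log10(s1 / length**2)
        elif cfg.rwpf_energy == "energy":
            egy[i] = np.log10(np.sum(absc**2) / length)
        else:
            raise ValueError(f"unknown rwpf_energy mode {cfg.rwpf_energy!r}")
        c2 = absc**2
        nz = c2 > 0
        epy[i] = -np.sum(c2[nz] * np.log10(c2[nz]))
    egy_tot, epy_tot = egy.sum(), epy.sum()
    if abs(egy_tot) < 1e-12 or abs(epy_tot) < 1e-12:
        return None
    return egy / egy_tot, epy / epy_tot


def rwpf60(voiced: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Frame-averaged relative packet energies (30) then entropies (30)."""
    cfg = cfg or FeatureConfig()
    frames = frame_signal(voiced, cfg.frame_len, cfg.hop, "rect").frames
    acc_e, acc_p, n_ok = np.zeros(30), np.zeros(30), 0
    for frame in frames:
        res = rwpf_frame(frame, cfg)
        if res is None:
            continue
        acc_e += res[0]
        acc_p += res[1]
        n_ok += 1
    if n_ok == 0:
        warnings.warn("rwpf60: every frame degenerate; returning zeros")
        return np.zeros(60)
    return np.concatenate([acc_e, acc_p]) / n_ok


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _stream_names(stream: str) -> list[str]:
    names = [f"{stream}.mfcc.{i:02d}" for i in range(1, 25)]
    names += [f"{stream}.lpcc.{i:02d}" for i in range(1, 19)]
    names += [f"{stream}.gtfb.{i:02d}" for i in range(1, 25)]
    names += [f"{stream}.plp.{i:02d}" for i in range(1, 14)]
    names += [f"{stream}.ttf.{s}.{st}" for s in _TTF_SERIES for st in _TTF_STATS]
    names += [f"{stream}.swt.{b}.{s}.{st}" for b in _SWT_BANDS for s in _TTF_SERIES for st in _TTF_STATS]
    names += [f"{stream}.rwpf.energy.{i:02d}" for i in range(1, 31)]
    names += [f"{stream}.rwpf.entropy.{i:02d}" for i in range(1, 31)]
    return names


def feature_names() -> list[str]:
    """The 614 stable feature identifiers, speech stream then glottal stream."""
    return _stream_names("speech") + _stream_names("glottal")


def family_of(name: str) -> str:
    """Family component of a qualified feature name; the name itself if unqualified."""
    parts = name.split(".")
    return parts[1] if len(parts) > 1 else name


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")


def extract_stream(samples: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """All seven families, in order, for one stream: 307 values."""
    cfg = cfg or FeatureConfig()
    parts = [
        mfcc24(samples, cfg),
        lpcc18(samples, cfg.lpc_order, cfg),
        gtfb24(samples),
        plp13(samples, cfg.lpc_order, cfg),
        ttf24(samples, cfg),
        swt_ttf144(samples, cfg),
        rwpf60(samples, cfg),
    ]
    return np.concatenate(parts)


def extract_all(
    speech: VoicedSignal, glottal: GlottalWaveform, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """The full 614-value vector: speech stream then glottal stream."""
    if len(speech.samples) == 0 or len(glottal.samples) == 0:
        raise ValueError("both streams must be non-empty")
    values = np.concatenate(
        [extract_stream(speech.samples, cfg), extract_stream(glottal.samples, cfg)]
    )
    return FeatureVector(values, tuple(feature_names()))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Sample x feature matrix plus emotion label and speaker id per row."""

    features: pd.DataFrame
    labels: pd.Series
    speakers: pd.Series
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.labels) != n or len(self.speakers) != n:
            raise ValueError("labels/speakers must match the number of rows")
        if self.sex is not None and len(self.sex) != n:
            raise ValueError("sex must match the number of rows")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        self.features = self.features.reset_index(drop=True)
        self.labels = pd.Series(np.asarray(self.labels), name="label")
        self.speakers = pd.Series(np.asarray(self.speakers), name="speaker")
        if self.sex is not None:
            self.sex = pd.Series(np.asarray(self.sex), name="sex")

    # -- basic views -------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_classes(self) -> int:
        return int(pd.unique(self.labels).size)

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.features.iloc[idx],
            self.labels.iloc[idx],
            self.speakers.iloc[idx],
            None if self.sex is None else self.sex.iloc[idx],
        )

    def select_columns(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.features.loc[:, np.asarray(mask, dtype=bool)],
            self.labels,
            self.speakers,
            self.sex,
        )

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = self.features.copy()
        df["label"] = self.labels.to_numpy()
        df["speaker"] = self.speakers.to_numpy()
        if self.sex is not None:
            df["sex"] = self.sex.to_numpy()
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        speaker_col: str = "speaker",
        sex_col: str | None = "sex",
    ) -> "FeatureTable":
        meta = [label_col, speaker_col] + ([sex_col] if sex_col and sex_col in df else [])
        feats = df.drop(columns=meta)
        return cls(
            feats,
            df[label_col],
            df[speaker_col],
            df[sex_col] if sex_col and sex_col in df else None,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def extract_utterance(
    signal, cfg: FeatureConfig | None = None, lp_order: int = 12, energy_frac: float = 0.1
) -> FeatureVector:
    """Audio -> voiced -> pre-emphasis -> glottal -> 614 features."""
    from .glottal import estimate_glottal
    from .preprocess import preprocess_audio

    voiced = preprocess_audio(signal, threshold_frac=energy_frac)
    flow = estimate_glottal(voiced, lp_order=lp_order)
    return extract_all(voiced, flow, cfg)


def extract_table(
    manifest: pd.DataFrame, cfg: FeatureConfig | None = None, root: str | Path | None = None
) -> FeatureTable:
    """Batch-extract a manifest (columns: path, label, speaker[, sex])."""
    from .preprocess import read_wav

    rows = []
    for _, rec in manifest.iterrows():
        path = Path(root) / rec["path"] if root else Path(rec["path"])
        rows.append(extract_utterance(read_wav(path), cfg).values)
    feats = pd.DataFrame(np.vstack(rows), columns=feature_names())
    sex = manifest["sex"] if "sex" in manifest else None
    return FeatureTable(feats, manifest["label"], manifest["speaker"], sex)
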