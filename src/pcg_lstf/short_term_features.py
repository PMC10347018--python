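"""Per-fragment (short-term) features: 14 statistics + 13 MFCCs.

The 14 time/statistics/energy/frequency features use population
conventions throughout (divide by N, not N-1): population standard
deviation, population skewness and non-excess kurtosis, mean absolute
deviation, and quartiles by the (n+1)/4 rank rule with linear
interpolation.  Shannon entropy is computed on the normalized
absolute-amplitude distribution p_i = |x_i| / sum|x|, spectral entropy on
the normalized one-sided power spectrum; both use natural logarithms and
are scale-invariant.  The three spectral-peak features are the argmax
frequency of the one-sided FFT magnitude (Hz), that magnitude, and the
ratio of the peak bin's power to the total power.

MFCCs: 25 ms Hamming frames with a 10 ms hop, a 512-point periodogram
power spectrum |FFT|^2/NFFT, 26 triangular mel filters spanning 0..fs/2 on
the HTK mel scale m = 2595 log10(1 + f/700), natural-log filter energies
(floored at machine epsilon), an orthonormal DCT-II, and the first 13
coefficients (the 0th-order coefficient included as mfcc_1).  The
fragment-level value of each coefficient is its mean over frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq

from .errors import ParameterError, PCGWarning
from .preprocessing import Fragment

STAT_NAMES = (
    "mean",
    "median",
    "std",
    "mad",
    "q1",
    "q3",
    "iqr",
    "skewness",
    "kurtosis",
    "shannon_entropy",
    "spectral_entropy",
    "max_freq_hz",
    "max_spectrum",
    "max_freq_energy_ratio",
)
MFCC_NAMES = tuple(f"mfcc_{i}" for i in range(1, 14))
SHORT_TERM_NAMES = STAT_NAMES + MFCC_NAMES


@dataclass
class ShortTermFeatures:
    values: np.ndarray
    names: tuple = SHORT_TERM_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if self.values.size != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} values, got {self.values.size}"
            )


def _quartile(x_sorted: np.ndarray, quarter: int) -> float:
    """(n+1)*quarter/4-th order statistic with linear interpolation."""
    n = x_sorted.size
    pos = quarter * (n + 1) / 4.0  # 1-indexed rank
    pos = min(max(pos, 1.0), float(n))
    lo = int(np.floor(pos)) - 1
    hi = int(np.ceil(pos)) - 1
    w = pos - np.floor(pos)
    return float((1 - w) * x_sorted[lo] + w * x_sorted[hi])


def _entropy(weights: np.ndarray) -> float:
    """Shannon entropy (nats) of non-negative weights, normalized to sum 1."""
    total = weights.sum()
    if total <= 0:
        return 0.0
    p = weights / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def stat_features(frag: Fragment | np.ndarray,
                  fs: float | None = None) -> np.ndarray:
    """The 14 statistical/energy/frequency features of a fragment."""
    if isinstance(frag, Fragment):
        x, fs = frag.samples, frag.fs
    else:
        x = np.asarray(frag, dtype=np.float64)
        if fs is None:
            raise ParameterError("fs required when passing a bare array")
    n = x.size
    if n < 4:
        raise ParameterError(f"fragment too short for statistics: {n} samples")

    m = float(x.mean())
    med = float(np.median(x))
    s = float(x.std())  # population (ddof=0)
    mad = float(np.abs(x - m).mean())
    xs = np.sort(x)
    q1 = _quartile(xs, 1)
    q3 = _quartile(xs, 3)
    iqr = q3 - q1
    if s == 0:
        warnings.warn(
            "constant fragment: skewness/kurtosis undefined, returning 0",
            PCGWarning,
            stacklevel=2,
        )
        skew = kurt = 0.0
    else:
        z = (x - m) / s
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    ent = _entropy(np.abs(x))

    spec = np.abs(rfft(x))
    power = spec**2
    spec_ent = _entropy(power)
    freqs = rfftfreq(n, d=1.0 / fs)
    k = int(np.argmax(spec))
    max_freq_hz = float(freqs[k])
    max_spectrum = float(spec[k])
    total_power = float(power.sum())
    ratio = float(power[k] / total_power) if total_power > 0 else 0.0

    return np.array(
        [m, med, s, mad, q1, q3, iqr, skew, kurt, ent, spec_ent,
         max_freq_hz, max_spectrum, ratio]
    )


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular mel filters (HTK scale) spanning 0..fs/2.

    Returns an (n_filters, nfft//2 + 1) weight matrix; filter edges snap to
    FFT bins via floor((nfft+1) * f / fs).
    """
    mel_max = 2595.0 * np.log10(1.0 + (fs / 2.0) / 700.0)
    mels = np.linspace(0.0, mel_max, n_filters + 2)
    hz = 700.0 * (10.0 ** (mels / 2595.0) - 1.0)
    bins = np.floor((nfft + 1) * hz / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        left, center, right = bins[j], bins[j + 1], bins[j + 2]
        for k in range(left, center):
            if center > left:
                fb[j, k] = (k - left) / (center - left)
        for k in range(center, right):
            if right > center:
                fb[j, k] = (right - k) / (right - center)
    return fb


def mfcc_features(
    frag: Fragment | np.ndarray,
    fs: float | None = None,
    n_filters: int = 26,
    n_coeffs: int = 13,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
    nfft: int = 512,
) -> np.ndarray:
    """Mean-over-frames mel-frequency cepstral coefficients of a fragment."""
    if isinstance(frag, Fragment):
        x, fs = frag.samples, frag.fs
    else:
        x = np.asarray(frag, dtype=np.float64)
        if fs is None:
            raise ParameterError("fs required when passing a bare array")
    frame = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    if x.size < frame:
        raise ParameterError(
            f"fragment shorter than one {frame_ms} ms frame"
        )
    if np.all(x == 0):
        warnings.warn(
            "all-zero fragment: MFCCs computed on the log floor",
            PCGWarning,
            stacklevel=2,
        )
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(frame)
    power = np.abs(rfft(frames, n=nfft, axis=1)) ** 2 / nfft
    fb = mel_filterbank(n_filters, nfft, fs)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, np.finfo(np.float64).eps))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    return coeffs.mean(axis=0)


def short_term_vector(frag: Fragment, **mfcc_kwargs) -> ShortTermFeatures:
    """The ordered 27-vector [14 statistics | 13 MFCCs] of one fragment."""
    return ShortTermFeatures(
        np.concatenate([stat_features(frag), mfcc_features(frag, **mfcc_kwargs)])
    )
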