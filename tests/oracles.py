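"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a direct, loop-based transcription of the
published formulas, deliberately sharing no code with the package: the
quartile rank rule, population moments, entropies, the interval
statistics, and a naive MFCC chain with an explicitly summed DCT.
"""

from __future__ import annotations

import math

import numpy as np


def brute_quartile(x, quarter: int) -> float:
    """(n+1)*quarter/4-th order statistic, linear interpolation, 1-indexed."""
    xs = sorted(x)
    n = len(xs)
    pos = quarter * (n + 1) / 4.0
    pos = min(max(pos, 1.0), float(n))
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo - 1] * (1 - frac) + xs[hi - 1] * frac


def brute_stats(x, fs) -> dict[str, float]:
    """The 14 statistical features evaluated directly from their formulas."""
    x = [float(v) for v in x]
    n = len(x)
    m = sum(x) / n
    med = float(np.median(x))
    s = math.sqrt(sum((v - m) ** 2 for v in x) / n)
    mad = sum(abs(v - m) for v in x) / n
    q1 = brute_quartile(x, 1)
    q3 = brute_quartile(x, 3)
    if s > 0:
        skew = sum(((v - m) / s) ** 3 for v in x) / n
        kurt = sum(((v - m) / s) ** 4 for v in x) / n
    else:
        skew = kurt = 0.0
    tot = sum(abs(v) for v in x)
    ent = 0.0
    if tot > 0:
        for v in x:
            p = abs(v) / tot
            if p > 0:
                ent -= p * math.log(p)
    spec = np.abs(np.fft.rfft(x))
    power = spec**2
    ptot = power.sum()
    spec_ent = 0.0
    if ptot > 0:
        for p in power / ptot:
            if p > 0:
                spec_ent -= p * math.log(p)
    k = int(np.argmax(spec))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return {
        "mean": m,
        "median": med,
        "std": s,
        "mad": mad,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "skewness": skew,
        "kurtosis": kurt,
        "shannon_entropy": ent,
        "spectral_entropy": spec_ent,
        "max_freq_hz": float(freqs[k]),
        "max_spectrum": float(spec[k]),
        "max_freq_energy_ratio": float(power[k] / ptot) if ptot > 0 else 0.0,
    }


def naive_mel_filterbank(n_filters, nfft, fs):
    """Triangular mel filters built point-by-point from the HTK formulas."""

    def to_mel(hz):
        return 2595.0 * math.log10(1.0 + hz / 700.0)

    def to_hz(mel):
        return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)

    edges_mel = [to_mel(0.0) + i * (to_mel(fs / 2.0) - to_mel(0.0)) /
                 (n_filters + 1) for i in range(n_filters + 2)]
    bins = [math.floor((nfft + 1) * to_hz(m) / fs) for m in edges_mel]
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        for k in range(bins[j], bins[j + 1]):
            fb[j, k] = (k - bins[j]) / (bins[j + 1] - bins[j])
        for k in range(bins[j + 1], bins[j + 2]):
            fb[j, k] = (bins[j + 2] - k) / (bins[j + 2] - bins[j + 1])
    return fb


def naive_mfcc(x, fs, n_filters=26, n_coeffs=13, frame_ms=25.0,
               hop_ms=10.0, nfft=512):
    """Frame-averaged MFCCs with an explicitly summed orthonormal DCT-II."""
    x = np.asarray(x, dtype=float)
    frame = int(round(frame_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    win = np.array(
        [0.54 - 0.46 * math.cos(2 * math.pi * i / (frame - 1))
         for i in range(frame)]
    )
    fb = naive_mel_filterbank(n_filters, nfft, fs)
    eps = np.finfo(float).eps
    out = []
    start = 0
    while start + frame <= x.size:
        seg = x[start : start + frame] * win
        power = np.abs(np.fft.rfft(seg, nfft)) ** 2 / nfft
        loge = [math.log(max(float(fb[j] @ power), eps))
                for j in range(n_filters)]
        coeffs = []
        for k in range(n_coeffs):
            c = sum(loge[m] * math.cos(math.pi * k * (2 * m + 1) /
                                       (2 * n_filters))
                    for m in range(n_filters))
            scale = math.sqrt(1.0 / n_filters) if k == 0 else math.sqrt(
                2.0 / n_filters)
            coeffs.append(scale * c)
        out.append(coeffs)
        start += hop
    return np.mean(np.array(out), axis=0)


def brute_interval_stats(s1, s2):
    """T12/T21/SD12/SD21 evaluated literally (alternating S1,S2 lists)."""
    n = len(s1)
    sys_iv = [abs(s1[i] - s2[i]) for i in range(n)]
    dia_iv = [abs(s2[i] - s1[i + 1]) for i in range(n - 1)]
    t12 = sum(sys_iv) / n
    t21 = sum(dia_iv) / (n - 1)
    sd12 = math.sqrt(sum((v - t12) ** 2 for v in sys_iv) / n)
    sd21 = math.sqrt(sum((v - t21) ** 2 for v in dia_iv) / (n - 1))
    return t12, t21, sd12, sd21
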