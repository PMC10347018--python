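"""Synthetic phonocardiogram generator with ground-truth annotations.

A recording is a pulse train of Gaussian-windowed sinusoids: one S1
(default 60 Hz center, 60 ms width, unit amplitude) at each cycle start
and one S2 (90 Hz, 40 ms, amplitude 0.7) a systolic interval later, with
per-event Gaussian timing jitter.  An "abnormal" recording additionally
carries a systolic murmur — 150-400 Hz band-passed noise confined to the
systolic intervals — at a configurable RMS relative to the S1 peak.
Clinical murmurs wax and wane with respiration and stethoscope position,
so the murmur is active only over a contiguous fraction of the recording
(``murmur_duty``; 1.0 = every cycle): a five-second fragment of an
abnormal recording may therefore contain no murmur at all, while the
whole recording still does — the information asymmetry between the two
timescales that motivates long-term features.  White noise is added at a
stated SNR (relative to the clean signal power).  The generator returns
the exact (jittered) S1/S2 centers as a ground-truth segmentation, which
makes every upstream stage testable without real data.

The default dataset conditions emulate the variety of a screening
corpus: 20 s recordings, heart rate U(60, 110) bpm, systolic fraction
U(0.34, 0.40) of the cycle, jitter U(5, 10) ms, SNR U(15, 25) dB, and,
for the abnormal class, murmur relative RMS U(0.15, 0.35) active over a
contiguous U(0.35, 0.65) fraction of the recording.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError
from .io_audio import Manifest, Recording, write_manifest, write_wav
from .preprocessing import Segmentation

#: Physiological cardiac-cycle bounds in ms (40-150 bpm).
CYCLE_BOUNDS_MS = (400.0, 1500.0)


@dataclass(frozen=True)
class PulseSpec:
    """Morphology of one heart-sound pulse."""

    freq_hz: float
    width_ms: float
    amplitude: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording."""

    duration_s: float = 20.0
    fs: float = 2000.0
    heart_rate_bpm: float = 75.0
    systole_ms: float = 300.0
    s1: PulseSpec = PulseSpec(60.0, 60.0, 1.0)
    s2: PulseSpec = PulseSpec(90.0, 40.0, 0.7)
    murmur_rel_amp: float = 0.0  # murmur RMS relative to S1 peak; 0 = off
    murmur_duty: float = 1.0  # contiguous fraction of cycles with murmur
    jitter_ms: float = 8.0
    snr_db: float | None = 25.0  # None disables additive noise
    seed: int = 0

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm

    def validate(self) -> None:
        if self.fs < 2000:
            raise ParameterError("fs must be >= 2000 Hz")
        lo, hi = CYCLE_BOUNDS_MS
        if not lo <= self.cycle_ms <= hi:
            raise ParameterError(
                f"cycle {self.cycle_ms:.0f} ms outside the physiological "
                f"range [{lo:.0f}, {hi:.0f}] ms"
            )
        if not 0 < self.systole_ms < self.cycle_ms:
            raise ParameterError("require 0 < systole_ms < cycle_ms")
        if self.murmur_rel_amp < 0 or self.jitter_ms < 0:
            raise ParameterError("murmur_rel_amp and jitter_ms must be >= 0")
        if not 0 < self.murmur_duty <= 1:
            raise ParameterError("murmur_duty must lie in (0, 1]")


def _pulse(t_ms: np.ndarray, center_ms: float, spec: PulseSpec) -> np.ndarray:
    sigma = spec.width_ms / 6.0  # pulse spans ~ +/- 3 sigma
    dt = t_ms - center_ms
    return (
        spec.amplitude
        * np.exp(-0.5 * (dt / sigma) ** 2)
        * np.sin(2 * np.pi * spec.freq_hz * dt / 1000.0)
    )


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, Segmentation]:
    """Synthesize one recording plus its ground-truth S1/S2 segmentation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t_ms = np.arange(n) * 1000.0 / spec.fs
    total_ms = spec.duration_s * 1000.0

    n_cycles = int(np.floor(total_ms / spec.cycle_ms))
    base = np.arange(n_cycles) * spec.cycle_ms
    jit = spec.jitter_ms
    # jitter clipped to 1/4 cycle so events never reorder
    clip = spec.cycle_ms / 4.0
    s1_times = base + np.clip(rng.normal(0, jit, n_cycles), -clip, clip)
    s2_times = (
        base
        + spec.systole_ms
        + np.clip(rng.normal(0, jit, n_cycles), -clip, clip)
    )
    s1_times = np.clip(s1_times, 0, None)

    clean = np.zeros(n)
    for tc in s1_times:
        clean += _pulse(t_ms, tc, spec.s1)
    for tc in s2_times:
        clean += _pulse(t_ms, tc, spec.s2)

    if spec.murmur_rel_amp > 0:
        sos = butter(4, [150.0, 400.0], btype="band", fs=spec.fs,
                     output="sos")
        band = sosfiltfilt(sos, rng.standard_normal(n))
        n_active = max(1, int(np.ceil(spec.murmur_duty * n_cycles)))
        start = int(rng.integers(0, n_cycles - n_active + 1))
        active = slice(start, start + n_active)
        gate = np.zeros(n)
        for t1, t2 in zip(s1_times[active], s2_times[active]):
            a = t1 + spec.s1.width_ms / 2.0
            b = t2 - spec.s2.width_ms / 2.0
            if b <= a:
                continue
            seg = (t_ms >= a) & (t_ms <= b)
            # half-cosine taper confines the murmur to systole smoothly
            gate[seg] = np.sin(np.pi * (t_ms[seg] - a) / (b - a))
        murmur = band * gate
        rms = np.sqrt(np.mean(murmur[gate > 0] ** 2)) if np.any(gate > 0) else 0
        if rms > 0:
            murmur *= spec.murmur_rel_amp * spec.s1.amplitude / rms
        clean = clean + murmur

    x = clean
    if spec.snr_db is not None:
        p_sig = float(np.mean(clean**2))
        p_noise = p_sig / (10.0 ** (spec.snr_db / 10.0))
        x = clean + rng.standard_normal(n) * np.sqrt(p_noise)

    label = "abnormal" if spec.murmur_rel_amp > 0 else "normal"
    rec = Recording(
        id=f"synth_{spec.seed}", samples=x, fs=spec.fs, label=label
    )
    gt = Segmentation(
        s1_times_ms=s1_times,
        s2_times_ms=s2_times,
        n_candidates=2 * n_cycles,
        n_retained=2 * n_cycles,
        mean_amp_candidates=(spec.s1.amplitude + spec.s2.amplitude) / 2.0,
        mean_amp_retained=(spec.s1.amplitude + spec.s2.amplitude) / 2.0,
    )
    return rec, gt


#: Per-recording parameter ranges used by :func:`generate_dataset`.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate_bpm": (60.0, 110.0),
    "systole_frac": (0.34, 0.40),
    "jitter_ms": (5.0, 10.0),
    "snr_db": (15.0, 25.0),
    "murmur_rel_amp": (0.15, 0.35),
    "murmur_duty": (0.35, 0.65),
}


def draw_spec(
    rng: np.random.Generator,
    abnormal: bool,
    seed: int,
    duration_s: float = 20.0,
    ranges: dict | None = None,
) -> SyntheticSpec:
    """Draw one recording's parameters uniformly from the stated ranges."""
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    hr = rng.uniform(*r["heart_rate_bpm"])
    cycle = 60000.0 / hr
    return SyntheticSpec(
        duration_s=duration_s,
        heart_rate_bpm=hr,
        systole_ms=rng.uniform(*r["systole_frac"]) * cycle,
        jitter_ms=rng.uniform(*r["jitter_ms"]),
        snr_db=rng.uniform(*r["snr_db"]),
        murmur_rel_amp=rng.uniform(*r["murmur_rel_amp"]) if abnormal else 0.0,
        murmur_duty=rng.uniform(*r["murmur_duty"]) if abnormal else 1.0,
        seed=seed,
    )


def simulate_dataset(
    n_normal: int,
    n_abnormal: int,
    seed: int = 0,
    duration_s: float = 20.0,
    ranges: dict | None = None,
) -> list[tuple[Recording, Segmentation]]:
    """In-memory dataset: alternating labeled recordings with ground truth."""
    if n_normal < 1 or n_abnormal < 1:
        raise ParameterError("need at least one recording per class")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        sub_seed = int((seed * 100_003 + i) % (2**31 - 1))
        spec = draw_spec(rng, abnormal, sub_seed, duration_s, ranges)
        rec, gt = generate_recording(spec)
        rec = replace(
            rec, id=f"{'abn' if abnormal else 'nrm'}_{i:04d}"
        )
        out.append((rec, gt))
    return out


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    out_dir: str,
    seed: int = 0,
    duration_s: float = 20.0,
    ranges: dict | None = None,
) -> Manifest:
    """Write a WAV dataset + manifest CSV + ground-truth JSON sidecars."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for rec, gt in simulate_dataset(n_normal, n_abnormal, seed, duration_s,
                                    ranges):
        peak = np.max(np.abs(rec.samples))
        scaled = replace(rec, samples=rec.samples / peak * 0.9)
        fname = rec.id + ".wav"
        write_wav(scaled, os.path.join(out_dir, fname), dtype="int16")
        with open(os.path.join(out_dir, rec.id + ".truth.json"), "w") as fh:
            json.dump(
                {
                    "s1_ms": list(map(float, gt.s1_times_ms)),
                    "s2_ms": list(map(float, gt.s2_times_ms)),
                    "label": rec.label,
                },
                fh,
            )
        entries.append((fname, rec.label))
    manifest = Manifest(entries=entries, root=out_dir)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
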