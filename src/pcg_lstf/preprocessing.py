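"""Segmentation of the fundamental heart sounds and fragmentation.

The pre-processing chain is: zero-phase low-pass filtering (noise and lung
sounds live above the fundamental-heart-sound band), a normalized average
Shannon-energy envelope, candidate peak detection at 30 % of the envelope
maximum, an extra-peak-rejection pass that enforces physiological timing
constraints (no two events closer than 50 ms; a cardiac cycle between 400
and 1500 ms, i.e. 40-150 bpm), S1/S2 labeling under the prior that systole
is shorter than diastole, and finally division of the recording into
contiguous five-second fragments for short-term feature extraction.

Rejection rules, applied until stable:

(a) two neighboring peaks closer than 50 ms cannot both be heart sounds:
    the smaller-amplitude one is dropped;
(b) three peaks inside a single 400 ms span exceed what one cardiac cycle
    can contain (one S1 and one S2): the smallest of the three is dropped;
(c) a gap longer than 1500 ms means a heart sound was missed below the
    threshold: the threshold is lowered locally (×0.8 per iteration, floor
    at 5 % of the envelope maximum) over that gap only and detection is
    re-run there.  Rule (c) needs the envelope; when no envelope is given
    long gaps are left as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import (
    InsufficientPeaksError,
    NoPeaksError,
    ParameterError,
    PCGWarning,
    SegmentationFailureError,
)
from .io_audio import Recording


@dataclass
class Envelope:
    """A non-negative amplitude envelope sampled at its own (lower) rate."""

    values: np.ndarray
    rate_hz: float
    t0_ms: float = 0.0  # time of the first envelope sample (frame center)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.values.size) * 1000.0 / self.rate_hz


@dataclass
class PeakList:
    """Envelope peaks: ascending times (ms), amplitudes, and the threshold."""

    times_ms: np.ndarray
    amplitudes: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64).reshape(-1)
        self.amplitudes = np.asarray(
            self.amplitudes, dtype=np.float64
        ).reshape(-1)
        if self.times_ms.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times_ms.size > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def __len__(self) -> int:
        return int(self.times_ms.size)


@dataclass
class Segmentation:
    """S1/S2 event times plus candidate/retained peak bookkeeping."""

    s1_times_ms: np.ndarray
    s2_times_ms: np.ndarray
    n_candidates: int
    n_retained: int
    mean_amp_candidates: float
    mean_amp_retained: float

    def __post_init__(self) -> None:
        self.s1_times_ms = np.asarray(self.s1_times_ms, dtype=np.float64)
        self.s2_times_ms = np.asarray(self.s2_times_ms, dtype=np.float64)

    def events(self) -> list[tuple[float, str]]:
        """All events as (time_ms, label) sorted by time."""
        ev = [(t, "S1") for t in self.s1_times_ms]
        ev += [(t, "S2") for t in self.s2_times_ms]
        return sorted(ev)


@dataclass
class Fragment:
    """A fixed-length window of a recording; the unit being classified."""

    recording_id: str
    index: int
    samples: np.ndarray
    fs: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.index < 0:
            raise ValueError("fragment index must be >= 0")


def lowpass_filter(rec: Recording, cutoff: float = 400.0,
                   order: int = 4) -> Recording:
    """Zero-phase Butterworth low-pass; peak times are not shifted."""
    nyq = rec.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff must lie in (0, {nyq}) Hz for fs={rec.fs}, got {cutoff}"
        )
    sos = butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    from dataclasses import replace

    return replace(rec, samples=sosfiltfilt(sos, rec.samples))


def compute_envelope(rec: Recording, frame_ms: float = 20.0,
                     hop_ms: float = 10.0) -> Envelope:
    """Normalized average Shannon-energy envelope.

    The signal is scaled to unit maximum absolute amplitude, then each
    ``frame_ms`` window (hop ``hop_ms``) contributes the average Shannon
    energy -mean(x^2 log x^2).  Shannon energy emphasises medium-intensity
    samples, which makes the weaker S2 comparable to S1 — the standard
    choice for phonocardiogram envelope extraction.
    """
    if not frame_ms >= hop_ms > 0:
        raise ParameterError("require frame_ms >= hop_ms > 0")
    x = rec.samples
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    frame = max(1, int(round(frame_ms * rec.fs / 1000.0)))
    hop = max(1, int(round(hop_ms * rec.fs / 1000.0)))
    n_frames = max(0, 1 + (x.size - frame) // hop)
    if n_frames == 0:
        return Envelope(np.zeros(0), rate_hz=1000.0 / hop_ms,
                        t0_ms=frame_ms / 2.0)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    sq = frames * frames
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(sq > 0, -sq * np.log(sq), 0.0)
    return Envelope(e.mean(axis=1), rate_hz=rec.fs / hop,
                    t0_ms=frame_ms / 2.0)


def _as_envelope(env) -> Envelope:
    if isinstance(env, Envelope):
        return env
    # bare arrays are interpreted on a 1 ms grid
    return Envelope(np.asarray(env, dtype=np.float64), rate_hz=1000.0)


def detect_candidate_peaks(env, threshold_frac: float = 0.3) -> PeakList:
    """All local envelope maxima at or above ``threshold_frac`` of the max."""
    env = _as_envelope(env)
    if env.values.size == 0:
        raise NoPeaksError("empty envelope")
    vmax = float(env.values.max())
    if vmax <= 0:
        raise NoPeaksError("flat zero envelope: no peaks above threshold")
    thr = threshold_frac * vmax
    idx, _ = find_peaks(env.values, height=thr, plateau_size=1)
    if idx.size == 0:
        raise NoPeaksError("no local maxima at or above threshold")
    step = 1000.0 / env.rate_hz
    return PeakList(times_ms=env.t0_ms + idx * step,
                    amplitudes=env.values[idx], threshold=thr)


def _apply_min_gap(times: list, amps: list, min_gap_ms: float) -> bool:
    """Rule (a): drop the smaller of any pair closer than min_gap_ms."""
    changed = False
    i = 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] < min_gap_ms:
            j = i + 1 if amps[i + 1] <= amps[i] else i
            del times[j], amps[j]
            changed = True
            i = max(i - 1, 0)
        else:
            i += 1
    return changed


def _apply_cycle_dedup(times: list, amps: list, min_cycle_ms: float) -> bool:
    """Rule (b): >2 peaks inside one min_cycle_ms span -> drop the smallest."""
    changed = False
    i = 0
    while i < len(times) - 2:
        if times[i + 2] - times[i] < min_cycle_ms:
            trio = [i, i + 1, i + 2]
            j = min(trio, key=lambda k: (amps[k], -k))
            del times[j], amps[j]
            changed = True
            i = max(i - 2, 0)
        else:
            i += 1
    return changed


def reject_extra_peaks(
    peaks: PeakList,
    min_gap_ms: float = 50.0,
    min_cycle_ms: float = 400.0,
    max_cycle_ms: float = 1500.0,
    envelope: Envelope | None = None,
    refine_factor: float = 0.8,
    floor_frac: float = 0.05,
) -> PeakList:
    """Remove spurious envelope peaks so only S1/S2 remain.

    See the module docstring for the three rules.  The returned peak list
    is stable: applying this function to its own output changes nothing,
    and no two retained peaks are closer than ``min_gap_ms``.
    """
    times = list(peaks.times_ms)
    amps = list(peaks.amplitudes)

    def stabilize() -> None:
        while _apply_min_gap(times, amps, min_gap_ms) or _apply_cycle_dedup(
            times, amps, min_cycle_ms
        ):
            pass

    stabilize()

    if envelope is not None:
        env = _as_envelope(envelope)
        step = 1000.0 / env.rate_hz
        floor = floor_frac * float(env.values.max())
        guard = 0
        while guard < 1000:
            guard += 1
            gaps = [
                i
                for i in range(len(times) - 1)
                if times[i + 1] - times[i] > max_cycle_ms
            ]
            if not gaps:
                break
            i = gaps[0]
            t_lo, t_hi = times[i], times[i + 1]
            local = peaks.threshold
            progressed = False
            while True:
                local *= refine_factor
                if local < floor:
                    raise SegmentationFailureError(
                        f"gap {t_hi - t_lo:.0f} ms at [{t_lo:.0f}, "
                        f"{t_hi:.0f}] ms not resolvable above the "
                        "threshold floor",
                        gap_ms=(t_lo, t_hi),
                    )
                idx, _ = find_peaks(env.values, height=local, plateau_size=1)
                t_new = env.t0_ms + idx * step
                inside = (t_new > t_lo + min_gap_ms) & (
                    t_new < t_hi - min_gap_ms
                )
                fresh = [
                    (t, env.values[k])
                    for t, k in zip(t_new[inside], idx[inside])
                    if not np.any(np.isclose(times, t))
                ]
                if fresh:
                    for t, a in fresh:
                        pos = int(np.searchsorted(times, t))
                        times.insert(pos, t)
                        amps.insert(pos, float(a))
                    stabilize()
                    # progress iff the offending gap actually shrank
                    k = int(np.searchsorted(times, t_lo))
                    if (
                        k < len(times) - 1
                        and times[k + 1] - times[k] < t_hi - t_lo
                    ):
                        progressed = True
                        break
            if not progressed:  # pragma: no cover - loop always breaks/raises
                break

    return PeakList(np.array(times), np.array(amps), peaks.threshold)


def label_s1_s2(peaks: PeakList, candidates: PeakList | None = None
                ) -> Segmentation:
    """Assign alternating S1/S2 labels to a retained peak train.

    Of the two possible label parities, the one whose S1->S2 intervals have
    the smaller mean is chosen (physiological prior: systole is shorter
    than diastole).  A tie picks the first peak as S1 and warns.
    """
    t = peaks.times_ms
    a = peaks.amplitudes
    if t.size < 4:
        raise InsufficientPeaksError(
            f"need >= 4 retained peaks to label S1/S2, got {t.size}"
        )
    iv = np.diff(t)
    mean_even = float(iv[0::2].mean())
    mean_odd = float(iv[1::2].mean())
    if np.isclose(mean_even, mean_odd):
        warnings.warn(
            "systolic/diastolic interval means tie; assuming the first "
            "peak is S1",
            PCGWarning,
            stacklevel=2,
        )
        parity = 0
    else:
        # even intervals are t[0]->t[1], t[2]->t[3], ...: if they are the
        # shorter ones they are systoles and even-position peaks are S1.
        parity = 0 if mean_even < mean_odd else 1
    s1 = t[parity::2]
    s2 = t[1 - parity :: 2]
    cand = candidates if candidates is not None else peaks
    return Segmentation(
        s1_times_ms=s1,
        s2_times_ms=s2,
        n_candidates=len(cand),
        n_retained=len(peaks),
        mean_amp_candidates=float(np.mean(cand.amplitudes)),
        mean_amp_retained=float(np.mean(a)),
    )


def fragment(rec: Recording, window_s: float = 5.0) -> list[Fragment]:
    """Cut a recording into contiguous non-overlapping windows from t=0.

    The trailing remainder shorter than ``window_s`` is discarded; each
    fragment inherits the recording's label.
    """
    win = int(round(window_s * rec.fs))
    n = rec.samples.size // win
    if n == 0:
        warnings.warn(
            f"recording {rec.id!r} ({rec.duration_s:.2f} s) is shorter than "
            f"the {window_s} s window; no fragments produced",
            PCGWarning,
            stacklevel=2,
        )
        return []
    return [
        Fragment(
            recording_id=rec.id,
            index=i,
            samples=rec.samples[i * win : (i + 1) * win],
            fs=rec.fs,
            label=rec.label,
        )
        for i in range(n)
    ]


def segment_recording(
    rec: Recording,
    cutoff: float = 400.0,
    order: int = 4,
    frame_ms: float = 20.0,
    hop_ms: float = 10.0,
    threshold_frac: float = 0.3,
    min_gap_ms: float = 50.0,
    min_cycle_ms: float = 400.0,
    max_cycle_ms: float = 1500.0,
    refine_factor: float = 0.8,
    floor_frac: float = 0.05,
) -> tuple[Segmentation, Recording]:
    """Full segmentation chain; returns (segmentation, filtered recording)."""
    filtered = lowpass_filter(rec, cutoff=cutoff, order=order)
    env = compute_envelope(filtered, frame_ms=frame_ms, hop_ms=hop_ms)
    cand = detect_candidate_peaks(env, threshold_frac=threshold_frac)
    kept = reject_extra_peaks(
        cand,
        min_gap_ms=min_gap_ms,
        min_cycle_ms=min_cycle_ms,
        max_cycle_ms=max_cycle_ms,
        envelope=env,
        refine_factor=refine_factor,
        floor_frac=floor_frac,
    )
    return label_s1_s2(kept, candidates=cand), filtered


def write_segmentation(seg: Segmentation, recording_id: str,
                       path: str) -> None:
    """Export events as a `recording_id\\ttime_ms\\tlabel` TSV."""
    with open(path, "w") as fh:
        fh.write("recording_id\ttime_ms\tlabel\n")
        for t, lab in seg.events():
            fh.write(f"{recording_id}\t{t:.3f}\t{lab}\n")
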