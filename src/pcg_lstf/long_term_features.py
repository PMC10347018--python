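"""Per-recording (long-term) features from the S1/S2 segmentation.

Six features summarize the whole recording: the mean and population
standard deviation of the systolic (S1->S2) and diastolic (S2->next S1)
intervals, in milliseconds, and two extra-peak-rejection ratios — the
fraction of candidate peaks retained and the ratio of the retained peaks'
mean envelope amplitude to that of all candidates.  The interval means
divide by the number of intervals of each kind (systoles N, diastoles
N-1 for a recording that starts on S1 and ends on S2), matching the
population convention used throughout the package.

These six values are later broadcast to every five-second fragment of the
recording, so each fragment's feature vector carries information about
the signal it came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientCyclesError, ParameterError
from .io_audio import Recording
from .preprocessing import Segmentation

LONG_TERM_NAMES = (
    "t12_mean_ms",
    "t21_mean_ms",
    "sd12_ms",
    "sd21_ms",
    "retained_peak_ratio",
    "retained_amp_ratio",
)


@dataclass
class LongTermFeatures:
    values: np.ndarray
    names: tuple = LONG_TERM_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if self.values.size != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} values, got {self.values.size}"
            )


def _intervals(seg: Segmentation) -> tuple[np.ndarray, np.ndarray]:
    """Systolic and diastolic interval arrays (ms) from alternating events."""
    ev = seg.events()
    systoles, diastoles = [], []
    for (t0, l0), (t1, l1) in zip(ev, ev[1:]):
        if l0 == "S1" and l1 == "S2":
            systoles.append(abs(t1 - t0))
        elif l0 == "S2" and l1 == "S1":
            diastoles.append(abs(t1 - t0))
    return np.asarray(systoles), np.asarray(diastoles)


def interval_features(seg: Segmentation) -> np.ndarray:
    """[T12, T21, SD12, SD21]: systolic/diastolic means and SDs in ms."""
    sys_iv, dia_iv = _intervals(seg)
    if sys_iv.size < 2 or dia_iv.size < 1:
        raise InsufficientCyclesError(
            f"need >= 2 systolic and >= 1 diastolic intervals, got "
            f"{sys_iv.size}/{dia_iv.size}"
        )
    return np.array(
        [
            sys_iv.mean(),
            dia_iv.mean(),
            sys_iv.std(),  # population SD over the N systoles
            dia_iv.std(),  # population SD over the N-1 diastoles
        ]
    )


def rejection_features(seg: Segmentation) -> np.ndarray:
    """[retained/total peak count, retained/total mean amplitude]."""
    if seg.n_candidates < 1:
        raise ParameterError("segmentation records zero candidate peaks")
    if seg.mean_amp_candidates <= 0:
        raise ParameterError("mean candidate amplitude must be positive")
    return np.array(
        [
            seg.n_retained / seg.n_candidates,
            seg.mean_amp_retained / seg.mean_amp_candidates,
        ]
    )


def long_term_vector(rec: Recording | None, seg: Segmentation
                     ) -> LongTermFeatures:
    """The ordered 6-vector of one recording's long-term features.

    ``rec`` is accepted for interface symmetry with the short-term side;
    the features depend only on the segmentation.
    """
    return LongTermFeatures(
        np.concatenate([interval_features(seg), rejection_features(seg)])
    )
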