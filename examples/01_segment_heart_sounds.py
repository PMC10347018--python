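"""Segment the fundamental heart sounds of a synthetic recording.

Generates one 20 s phonocardiogram at 75 bpm, runs the envelope-threshold
segmentation with extra-peak rejection, and compares the detected S1/S2
times with the generator's ground truth.
"""

import numpy as np

from pcg_lstf import SyntheticSpec, generate_recording, segment_recording

spec = SyntheticSpec(duration_s=20.0, heart_rate_bpm=75.0, systole_ms=300.0,
                     jitter_ms=5.0, snr_db=25.0, seed=7)
rec, truth = generate_recording(spec)
seg, _ = segment_recording(rec)

print(f"recording: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz, "
      f"label {rec.label}")
print(f"true events: {truth.s1_times_ms.size} S1 + "
      f"{truth.s2_times_ms.size} S2")
print(f"detected:    {seg.s1_times_ms.size} S1 + {seg.s2_times_ms.size} S2 "
      f"({seg.n_retained}/{seg.n_candidates} envelope peaks retained)")

err = [np.min(np.abs(seg.s1_times_ms - t)) for t in truth.s1_times_ms]
print(f"median |S1 timing error|: {np.median(err):.1f} ms")
print("Each detected S1 should sit within a few ms of a true S1: the")
print("Shannon-energy envelope peaks at the pulse centers and the")
print("rejection rules remove everything that violates cardiac timing.")
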