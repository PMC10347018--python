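"""Extract short-term, long-term and merged features from one recording.

Five-second fragments each yield 27 short-term features (14 statistics +
13 MFCCs); the whole recording yields 6 long-term interval/rejection
features, which are appended to every fragment to form the 33-dimensional
long short-term vector.
"""

from pcg_lstf import (
    SyntheticSpec,
    fragment,
    generate_recording,
    long_term_vector,
    merge_features,
    segment_recording,
    short_term_vector,
)

rec, _ = generate_recording(
    SyntheticSpec(duration_s=20.0, heart_rate_bpm=80.0, systole_ms=290.0,
                  seed=3)
)
seg, filtered = segment_recording(rec)
ltf = long_term_vector(rec, seg)

print("long-term features (whole recording):")
for name, value in zip(ltf.names, ltf.values):
    print(f"  {name:>22s} = {value:8.3f}")

frags = fragment(filtered, window_s=5.0)
stf = short_term_vector(frags[0])
merged, names = merge_features(stf, ltf)
print(f"\nfragment 0 of {len(frags)}: {stf.values.size} short-term features")
print(f"merged vector: {merged.size} values; last 6 are the recording-level")
print("features, identical for every fragment of this recording — this is")
print("how each fragment carries information about the signal it came from.")
print("first five short-term values:",
      ", ".join(f"{n}={v:.3g}" for n, v in zip(names[:5], merged[:5])))
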