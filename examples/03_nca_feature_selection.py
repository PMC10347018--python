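"""Rank the 33 features by neighborhood component analysis weight.

Builds a small synthetic murmur dataset, extracts the merged feature
table, and prints the NCA weight ranking.  On data like this the
long-term features tend to rank highest — the recording-level interval
and rejection statistics separate murmur recordings even when individual
fragments are ambiguous.
"""

from pcg_lstf import make_feature_table, nca_weights, simulate_dataset
from pcg_lstf.pipeline import PipelineConfig, featurize_recording

rows = []
for rec, _ in simulate_dataset(20, 20, seed=5, duration_s=20.0):
    rows.extend(featurize_recording(rec, PipelineConfig()))
table = make_feature_table(rows, feature_set_tag="LSTF")
print(f"feature table: {len(table)} fragments x "
      f"{len(table.feature_names)} features")

result = nca_weights(table, seed=0)
ranked = sorted(result.weights.items(), key=lambda kv: -kv[1])
print("\ntop 10 features by NCA weight:")
for name, weight in ranked[:10]:
    kind = "long-term " if name in table.feature_names[27:] else "short-term"
    print(f"  {weight:8.4f}  {kind}  {name}")
print(f"\nmean-weight threshold keeps {len(result.selected)} features;")
print("top_k_short(16) instead keeps the 16 best short-term features, the")
print("canonical post-reduction cardinality used for the SSTF/SLSTF sets.")
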