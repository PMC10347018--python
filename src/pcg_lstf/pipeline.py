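"""End-to-end orchestration: ingest -> segment -> featurize -> select -> train.

``run_pipeline`` executes the four main stages on a manifest of WAV/WFDB
recordings: (1) read, resample to 2000 Hz and low-pass filter; (2) segment
the fundamental heart sounds and extract the 6 long-term features; (3) cut
five-second fragments and extract the 27 short-term features, merging them
into the 33-column long short-term table; (4) rank features with NCA and
evaluate the classifier presets on all five feature sets.  Recordings
whose segmentation fails are excluded (with reasons logged and counted)
rather than aborting the run — noisy records are a fact of real corpora.

Intermediate artifacts (feature table CSV, selection JSON, report JSON,
per-recording segmentation TSVs) are persisted in the output directory;
a rerun reuses the cached feature table, making the pipeline resumable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io_audio, preprocessing
from .classification import BEST_VARIANTS, EvalReport, ablation
from .errors import PCGError, PipelineError
from .feature_pooling import (
    FeatureTable,
    SelectionResult,
    make_feature_table,
    nca_weights,
)
from .io_audio import Manifest, read_feature_table, write_feature_table
from .long_term_features import LONG_TERM_NAMES, long_term_vector
from .short_term_features import SHORT_TERM_NAMES, short_term_vector

log = logging.getLogger("pcg_lstf")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable to JSON."""

    # io
    target_fs: float = 2000.0
    normalize_amplitude: bool = False
    # preprocessing
    lowpass_cutoff_hz: float = 400.0
    lowpass_order: int = 4
    envelope_frame_ms: float = 20.0
    envelope_hop_ms: float = 10.0
    threshold_frac: float = 0.3
    min_gap_ms: float = 50.0
    min_cycle_ms: float = 400.0
    max_cycle_ms: float = 1500.0
    refine_factor: float = 0.8
    floor_frac: float = 0.05
    window_s: float = 5.0
    # short-term features
    mfcc_frame_ms: float = 25.0
    mfcc_hop_ms: float = 10.0
    n_filters: int = 26
    n_coeffs: int = 13
    nfft: int = 512
    # selection
    nca_regularization: float | None = None
    nca_max_rows: int = 500
    #: number of short-term features kept for SSTF/SLSTF (None = mean-weight
    #: threshold); 16 is the canonical post-reduction cardinality.
    select_k: int | None = 16
    # classification
    presets: tuple = BEST_VARIANTS
    train_frac: float = 0.7
    split_mode: str = "fragment"
    seeds: tuple = (0,)
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("presets", "seeds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    report: EvalReport
    table33: FeatureTable
    selection: SelectionResult
    n_recordings: int
    excluded: list[tuple[str, str]]  # (recording id, reason)


def featurize_recording(rec, config: PipelineConfig) -> list[dict]:
    """Rows (meta + 33 features + label) for one recording's fragments."""
    rec = io_audio.resample(rec, config.target_fs)
    if config.normalize_amplitude:
        rec = rec.normalized()
    seg, filtered = preprocessing.segment_recording(
        rec,
        cutoff=config.lowpass_cutoff_hz,
        order=config.lowpass_order,
        frame_ms=config.envelope_frame_ms,
        hop_ms=config.envelope_hop_ms,
        threshold_frac=config.threshold_frac,
        min_gap_ms=config.min_gap_ms,
        min_cycle_ms=config.min_cycle_ms,
        max_cycle_ms=config.max_cycle_ms,
        refine_factor=config.refine_factor,
        floor_frac=config.floor_frac,
    )
    ltf = long_term_vector(rec, seg)
    rows = []
    for frag in preprocessing.fragment(filtered, window_s=config.window_s):
        stf = short_term_vector(
            frag,
            n_filters=config.n_filters,
            n_coeffs=config.n_coeffs,
            frame_ms=config.mfcc_frame_ms,
            hop_ms=config.mfcc_hop_ms,
            nfft=config.nfft,
        )
        row = {"recording_id": frag.recording_id,
               "fragment_index": frag.index}
        row.update(zip(SHORT_TERM_NAMES, stf.values))
        row.update(zip(LONG_TERM_NAMES, ltf.values))
        row["label"] = frag.label
        rows.append(row)
    return rows


def featurize_manifest(
    manifest: Manifest, config: PipelineConfig
) -> tuple[FeatureTable, list[tuple[str, str]]]:
    """Feature table for every readable, segmentable manifest recording."""
    rows, excluded = [], []
    for path, label in manifest.resolved():
        rec_id = os.path.splitext(os.path.basename(path))[0]
        t0 = time.perf_counter()
        try:
            rec = io_audio.read_recording(path, label=label)
            new_rows = featurize_recording(rec, config)
            if not new_rows:
                raise PCGError("recording shorter than one window")
            rows.extend(new_rows)
        except (PCGError, FileNotFoundError, OSError) as exc:
            log.warning("excluding %s: %s", rec_id, exc)
            excluded.append((rec_id, str(exc)))
            continue
        log.info("featurized %s in %.2fs (%d fragments)", rec_id,
                 time.perf_counter() - t0, len(new_rows))
    if not rows:
        raise PipelineError("all recordings failed segmentation")
    return make_feature_table(rows, feature_set_tag="LSTF"), excluded


def run_pipeline(
    manifest: Manifest,
    config: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Execute the full pipeline; artifacts cached under ``out_dir``."""
    config = config or PipelineConfig()
    if len(manifest) == 0:
        raise PipelineError("manifest is empty")
    features_path = selection_path = report_path = None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        config.to_json(os.path.join(out_dir, "config.json"))
        features_path = os.path.join(out_dir, "features.csv")
        selection_path = os.path.join(out_dir, "selection.json")
        report_path = os.path.join(out_dir, "report.json")

    excluded: list[tuple[str, str]] = []
    if features_path and os.path.exists(features_path):
        log.info("reusing cached feature table %s", features_path)
        table33 = read_feature_table(features_path, feature_set_tag="LSTF")
    else:
        table33, excluded = featurize_manifest(manifest, config)
        if features_path:
            write_feature_table(table33, features_path)

    if selection_path and os.path.exists(selection_path):
        selection = SelectionResult.from_json(selection_path)
    else:
        selection = nca_weights(
            table33,
            regularization=config.nca_regularization,
            seed=config.seed,
            max_rows=config.nca_max_rows,
        )
        if config.select_k is not None:
            selection = selection.top_k_short(config.select_k)
        if selection_path:
            selection.to_json(selection_path)

    report = ablation(
        table33,
        selection,
        presets=list(config.presets),
        seeds=tuple(config.seeds),
        train_frac=config.train_frac,
        mode=config.split_mode,
    )
    report.split["excluded"] = [list(e) for e in excluded]
    if report_path:
        report.to_json(report_path)
    n_rec = int(table33.data["recording_id"].nunique())
    log.info("pipeline done: %d recordings, %d fragments, %d excluded",
             n_rec, len(table33), len(excluded))
    return PipelineResult(report, table33, selection, n_rec, excluded)
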