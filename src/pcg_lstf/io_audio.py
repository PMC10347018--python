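"""Recording and feature-table input/output.

Heart-sound recordings are read from RIFF PCM WAV files or WFDB
``.hea``/``.dat`` pairs (format 16, as distributed by PhysioNet/CinC 2016)
into a :class:`Recording`.  The dataset convention is a common sampling
rate of 2000 Hz; :func:`resample` enforces it with polyphase filtering so
that downsampling is anti-aliased and event times are preserved.

Amplitudes are kept in their native units: the 30 % peak threshold used by
segmentation is relative to each recording's own envelope maximum, so no
global normalization is required (an optional max-abs normalization flag is
available for callers that want scale-free feature values).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import (
    DegenerateInputError,
    FormatError,
    ManifestError,
    ParameterError,
    PCGWarning,
)

#: Labels a recording may carry.
VALID_LABELS = ("normal", "abnormal", "unknown")

#: The dataset's common sampling rate in Hz.
TARGET_FS = 2000.0


@dataclass
class Recording:
    """A labeled, uniformly sampled heart-sound waveform.

    Parameters
    ----------
    id : str
        Identifier, typically the file stem.
    samples : ndarray
        Amplitudes in arbitrary units; converted to float64.
    fs : float
        Sampling rate in Hz; must be positive.
    label : {"normal", "abnormal", "unknown"}
    source_path : str
        Provenance of the samples, empty for in-memory recordings.
    """

    id: str
    samples: np.ndarray
    fs: float
    label: str = "unknown"
    source_path: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise DegenerateInputError(f"recording {self.id!r} has no samples")
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {VALID_LABELS}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def normalized(self) -> "Recording":
        """Return a copy scaled to unit maximum absolute amplitude."""
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return replace(self, samples=self.samples.copy())
        return replace(self, samples=self.samples / peak)


@dataclass
class Manifest:
    """A list of (path, label) pairs rooted at a directory."""

    entries: list[tuple[str, str]]
    root: str = "."

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestError(f"duplicate manifest paths: {dupes}")
        for p, lab in self.entries:
            if lab not in VALID_LABELS:
                raise ManifestError(
                    f"label {lab!r} for {p!r} not in {VALID_LABELS}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def resolved(self) -> list[tuple[str, str]]:
        """Entries with paths joined onto the manifest root."""
        return [(os.path.join(self.root, p), lab) for p, lab in self.entries]


def _read_wav(path: str) -> tuple[float, np.ndarray]:
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted ValueError subtypes
        raise FormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(
            f"{path!r} has {data.shape[1]} channels; taking the first",
            PCGWarning,
            stacklevel=3,
        )
        data = data[:, 0]
    # integer PCM -> float in [-1, 1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return float(fs), data


def _read_wfdb(path: str) -> tuple[float, np.ndarray]:
    """Minimal WFDB reader: .hea header + format-16 .dat, first signal."""
    hea = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"WFDB header {hea!r} not found")
    with open(hea) as fh:
        lines = [
            ln.strip()
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise FormatError(f"WFDB header {hea!r} is empty")
    head = lines[0].split()
    try:
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed WFDB record line in {hea!r}") from exc
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise FormatError(f"{hea!r} declares {n_sig} signals but lists fewer")
    sig = lines[1].split()  # first signal's specification
    dat_name, fmt = sig[0], sig[1]
    if int(fmt.split("+")[0].split(":")[0]) != 16:
        raise FormatError(
            f"{hea!r}: only WFDB format 16 is supported, got {fmt!r}"
        )
    gain, baseline = 200.0, 0.0
    if len(sig) > 2:
        g = sig[2].split("/")[0]
        if "(" in g:
            g, base = g.split("(")
            baseline = float(base.rstrip(")"))
        if float(g) != 0:
            gain = float(g)
    dat = os.path.join(os.path.dirname(hea), dat_name)
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        warnings.warn(
            f"{hea!r} has {n_sig} signals; taking the first", PCGWarning,
            stacklevel=3,
        )
        raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samp:
        raw = raw[:n_samp]
    return fs, (raw.astype(np.float64) - baseline) / gain


def read_recording(path: str, label: str = "unknown") -> Recording:
    """Read a WAV or WFDB recording from disk.

    ``path`` may be a ``.wav`` file, a ``.hea`` header, or a WFDB record
    name (extensionless, with ``.hea`` alongside).
    """
    if not os.path.exists(path) and os.path.exists(path + ".hea"):
        path = path + ".hea"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".wav":
        fs, data = _read_wav(path)
    elif ext in (".hea", ""):
        fs, data = _read_wfdb(path)
    else:
        raise FormatError(f"unsupported recording format: {path!r}")
    if data.size == 0:
        raise DegenerateInputError(f"recording {path!r} contains no samples")
    rec_id = os.path.splitext(os.path.basename(path))[0]
    return Recording(id=rec_id, samples=data, fs=fs, label=label,
                     source_path=path)


def write_wav(rec: Recording, path: str, dtype: str = "int16") -> None:
    """Write a recording as RIFF PCM WAV.

    With ``dtype="int16"`` amplitudes are assumed to lie in [-1, 1] and are
    quantized; ``dtype="float32"`` stores them losslessly (to float32).
    """
    if dtype == "int16":
        x = np.clip(rec.samples, -1.0, 1.0)
        wavfile.write(path, int(round(rec.fs)),
                      np.round(x * 32767.0).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, int(round(rec.fs)),
                      rec.samples.astype(np.float32))
    else:
        raise ParameterError(f"unsupported WAV dtype {dtype!r}")


def resample(rec: Recording, target_fs: float = TARGET_FS) -> Recording:
    """Resample to ``target_fs`` with an anti-aliased polyphase filter.

    Returns the recording unchanged (same samples) when the rate already
    matches.  Duration is preserved to within one output sample.
    """
    if target_fs <= 0:
        raise ParameterError(f"target_fs must be positive, got {target_fs}")
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return replace(rec, samples=out, fs=float(target_fs))


def load_manifest(path: str) -> Manifest:
    """Load a ``path,label`` CSV manifest; the root is the CSV's directory."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"manifest {path!r} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries = [(str(p), str(lab)) for p, lab in zip(df["path"], df["label"])]
    return Manifest(entries=entries, root=os.path.dirname(os.path.abspath(path)))


def write_manifest(manifest: Manifest, path: str) -> None:
    pd.DataFrame(manifest.entries, columns=["path", "label"]).to_csv(
        path, index=False
    )


def write_feature_table(table, path: str) -> None:
    """Serialize a FeatureTable to CSV at full double precision."""
    df = table.data
    if df.columns.duplicated().any():
        raise ValueError("feature table has duplicate column names")
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str, feature_set_tag: str | None = None):
    """Read a FeatureTable CSV written by :func:`write_feature_table`."""
    from .feature_pooling import FeatureTable  # local import: layering

    df = pd.read_csv(path, float_precision="round_trip")
    kw = {} if feature_set_tag is None else {"feature_set_tag": feature_set_tag}
    return FeatureTable(df, **kw)
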