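"""Feature pooling: the merged long short-term representation and NCA.

Each five-second fragment is described by 27 short-term features; the 6
long-term features of its parent recording are appended to give the
33-dimensional long short-term feature vector (LSTF).  Five feature sets
are derived from it:

=====  ==========================================================
STF    the 27 short-term features
LTF    the 6 long-term features
LSTF   all 33
SSTF   short-term features surviving NCA selection
SLSTF  SSTF plus all 6 long-term features (long-term always kept)
=====  ==========================================================

Feature informativeness is scored by neighborhood component analysis
(NCA) feature weighting: per-feature weights w_r scale an L1 distance
d(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|, and the expected leave-one-out
accuracy of a soft nearest neighbor classifier,

    F(w) = (1/n) sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda sum_r w_r^2,
    p_ij = exp(-d(x_i, x_j)) / sum_{k != i} exp(-d(x_i, x_k)),

is maximized by L-BFGS from the all-equal initialization w = 1.  Features
are z-scored inside the optimizer; the reported weight of feature r is
w_r^2, so irrelevant features shrink toward zero under the L2 penalty
(default lambda = 1/n).  Features whose weight exceeds a threshold
(default: the mean weight) are selected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ParameterError, PCGWarning
from .long_term_features import LONG_TERM_NAMES, LongTermFeatures
from .short_term_features import SHORT_TERM_NAMES, ShortTermFeatures

META_COLUMNS = ("recording_id", "fragment_index")
LABEL_COLUMN = "label"
FEATURE_SET_TAGS = ("STF", "LTF", "LSTF", "SSTF", "SLSTF")
#: "CUSTOM" marks tables outside the five canonical sets (no width check).
_ALLOWED_TAGS = FEATURE_SET_TAGS + ("CUSTOM",)
_FIXED_WIDTH = {"STF": 27, "LTF": 6, "LSTF": 33}


@dataclass
class FeatureTable:
    """Per-fragment rows of named features with labels and provenance.

    Wraps a DataFrame whose columns are ``recording_id``,
    ``fragment_index``, the feature columns, and ``label``.
    """

    data: pd.DataFrame
    feature_set_tag: str = "CUSTOM"

    def __post_init__(self) -> None:
        if self.feature_set_tag not in _ALLOWED_TAGS:
            raise ParameterError(
                f"unknown feature set tag {self.feature_set_tag!r}; "
                f"expected one of {_ALLOWED_TAGS}"
            )
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate column names in feature table")
        for c in META_COLUMNS + (LABEL_COLUMN,):
            if c not in cols:
                raise ValueError(f"feature table missing column {c!r}")
        expected = _FIXED_WIDTH.get(self.feature_set_tag)
        if expected is not None and len(self.feature_names) != expected:
            raise ValueError(
                f"{self.feature_set_tag} table must have {expected} feature "
                f"columns, got {len(self.feature_names)}"
            )

    @property
    def feature_names(self) -> list[str]:
        skip = set(META_COLUMNS) | {LABEL_COLUMN}
        return [c for c in self.data.columns if c not in skip]

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.data[LABEL_COLUMN].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset_rows(self, idx) -> "FeatureTable":
        return replace(self, data=self.data.iloc[idx].reset_index(drop=True))


def make_feature_table(rows: list[dict], feature_set_tag: str = "CUSTOM"
                       ) -> FeatureTable:
    """Build a FeatureTable from per-fragment dicts (meta + features + label)."""
    df = pd.DataFrame(rows)
    ordered = [c for c in META_COLUMNS if c in df.columns]
    feats = [c for c in df.columns
             if c not in META_COLUMNS and c != LABEL_COLUMN]
    df = df[ordered + feats + [LABEL_COLUMN]]
    return FeatureTable(df, feature_set_tag=feature_set_tag)


def merge_features(stf: ShortTermFeatures, ltf: LongTermFeatures
                   ) -> tuple[np.ndarray, tuple]:
    """Concatenate [27 short-term | 6 long-term] preserving names."""
    if stf.values.size != len(SHORT_TERM_NAMES):
        raise ValueError("short-term vector has wrong length")
    if ltf.values.size != len(LONG_TERM_NAMES):
        raise ValueError("long-term vector has wrong length")
    return (
        np.concatenate([stf.values, ltf.values]),
        SHORT_TERM_NAMES + LONG_TERM_NAMES,
    )


def split_merged(values: np.ndarray) -> tuple[ShortTermFeatures,
                                              LongTermFeatures]:
    """Inverse of :func:`merge_features`."""
    values = np.asarray(values).reshape(-1)
    if values.size != 33:
        raise ValueError("merged vector must have length 33")
    return (ShortTermFeatures(values[:27]), LongTermFeatures(values[27:]))


@dataclass
class SelectionResult:
    """NCA feature weights, the selection threshold, and the survivors."""

    weights: dict[str, float]
    threshold: float
    selected: list[str]
    seed: int

    def __post_init__(self) -> None:
        want = [f for f, w in self.weights.items() if w > self.threshold]
        if set(want) != set(self.selected):
            raise ValueError("selected set inconsistent with threshold")

    def top_k(self, k: int) -> "SelectionResult":
        """Re-threshold so exactly the k highest-weight features survive."""
        order = sorted(self.weights, key=self.weights.get, reverse=True)
        if not 0 < k <= len(order):
            raise ParameterError(f"k must be in [1, {len(order)}], got {k}")
        kept = order[:k]
        w_in = self.weights[kept[-1]]
        w_out = self.weights[order[k]] if k < len(order) else 0.0
        thr = 0.5 * (w_in + w_out)
        return SelectionResult(dict(self.weights), thr, kept, self.seed)

    def top_k_short(self, k: int = 16) -> "SelectionResult":
        """Re-threshold so exactly k short-term features survive.

        The threshold is placed between the k-th and (k+1)-th highest
        short-term weights; long-term features above it also remain
        selected (they are kept in SLSTF by construction anyway).
        """
        short = [f for f in self.weights if f in SHORT_TERM_NAMES]
        if not 0 < k <= len(short):
            raise ParameterError(f"k must be in [1, {len(short)}], got {k}")
        order = sorted(short, key=self.weights.get, reverse=True)
        w_in = self.weights[order[k - 1]]
        w_out = self.weights[order[k]] if k < len(order) else 0.0
        thr = 0.5 * (w_in + w_out)
        kept = [f for f, w in self.weights.items() if w > thr]
        return SelectionResult(dict(self.weights), thr, kept, self.seed)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights,
                    "threshold": self.threshold,
                    "selected": self.selected,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["weights"], d["threshold"], d["selected"], d["seed"])


def _nca_objective(w, Z, same, lam):
    """(negative objective, negative gradient) of the NCA weighting problem."""
    n, d = Z.shape
    dist = np.zeros((n, n))
    for r in range(d):
        dist += w[r] ** 2 * np.abs(Z[:, r, None] - Z[None, :, r])
    np.fill_diagonal(dist, np.inf)
    # row-wise softmax of -dist (guarded against all-inf rows)
    shift = np.min(dist, axis=1, keepdims=True)
    K = np.exp(-(dist - shift))
    np.fill_diagonal(K, 0.0)
    denom = K.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    P = K / denom
    p_i = (P * same).sum(axis=1)
    f = p_i.mean() - lam * np.dot(w, w)
    grad = np.empty(d)
    PM = P * same
    for r in range(d):
        Dr = np.abs(Z[:, r, None] - Z[None, :, r])
        term = p_i * (P * Dr).sum(axis=1) - (PM * Dr).sum(axis=1)
        grad[r] = 2.0 * w[r] * term.mean() - 2.0 * lam * w[r]
    return -f, -grad


def nca_weights(
    table: FeatureTable,
    regularization: float | None = None,
    seed: int = 0,
    max_rows: int = 500,
    max_iter: int = 100,
    threshold: float | None = None,
) -> SelectionResult:
    """Per-feature NCA weights and the selected feature set.

    Features are z-scored internally.  Tables with more than ``max_rows``
    rows are subsampled (seeded, class-stratified) before optimization;
    the weights are otherwise deterministic given the data.  The reported
    weight of feature r is w_r^2 >= 0.  ``threshold`` defaults to the mean
    weight.
    """
    y = table.y
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ParameterError("NCA needs at least two classes in the table")
    X = table.X
    n = X.shape[0]
    if n > max_rows:
        rng = np.random.default_rng(seed)
        keep = []
        for c in range(classes.size):
            rows = np.flatnonzero(y_idx == c)
            take = max(2, int(round(max_rows * rows.size / n)))
            keep.append(rng.choice(rows, size=min(take, rows.size),
                                   replace=False))
        keep = np.sort(np.concatenate(keep))
        X, y_idx = X[keep], y_idx[keep]
        n = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    same = (y_idx[:, None] == y_idx[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)
    lam = 1.0 / n if regularization is None else float(regularization)

    d = Z.shape[1]
    res = minimize(
        _nca_objective,
        x0=np.ones(d),
        args=(Z, same, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        warnings.warn(
            f"NCA optimizer stopped early: {res.message}", PCGWarning,
            stacklevel=2,
        )
    elif res.status == 1:
        warnings.warn(
            "NCA optimizer hit the iteration cap; using the last iterate",
            PCGWarning,
            stacklevel=2,
        )
    w2 = res.x**2
    names = table.feature_names
    weights = {f: float(v) for f, v in zip(names, w2)}
    thr = float(np.mean(w2)) if threshold is None else float(threshold)
    selected = [f for f in names if weights[f] > thr]
    return SelectionResult(weights=weights, threshold=thr, selected=selected,
                           seed=seed)


def build_feature_set(
    table33: FeatureTable,
    tag: str,
    selection: SelectionResult | None = None,
) -> FeatureTable:
    """Project a 33-column LSTF table onto one of the five feature sets."""
    if tag not in FEATURE_SET_TAGS:
        raise ParameterError(f"unknown feature set tag {tag!r}")
    names = table33.feature_names
    if len(names) != 33:
        raise ValueError("expected a 33-feature LSTF table")
    short = [f for f in names if f in SHORT_TERM_NAMES]
    long = [f for f in names if f in LONG_TERM_NAMES]
    if tag == "STF":
        keep = short
    elif tag == "LTF":
        keep = long
    elif tag == "LSTF":
        keep = names
    else:
        if selection is None:
            raise ParameterError(f"{tag} requires a SelectionResult")
        chosen_short = [f for f in short if f in set(selection.selected)]
        if tag == "SSTF" and not chosen_short:
            raise ParameterError(
                "no short-term features survive selection; re-threshold "
                "with SelectionResult.top_k_short()"
            )
        keep = chosen_short if tag == "SSTF" else chosen_short + long
    cols = list(META_COLUMNS) + keep + [LABEL_COLUMN]
    return FeatureTable(table33.data[cols].copy(), feature_set_tag=tag)
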