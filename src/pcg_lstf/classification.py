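"""Classifier presets, the 70/30 evaluation protocol, and the ablation.

Twenty-two classical classifier variants across five families (decision
trees, naive Bayes, support vector machines, k-nearest neighbors,
ensembles) are exposed under the preset names of the MATLAB Machine
Learning Toolbox, mapped onto scikit-learn estimators with the documented
toolbox hyperparameters (e.g. a "fine" tree allows 100 splits, "fine" KNN
uses k=1, the "fine Gaussian" SVM uses an RBF kernel scale of sqrt(P)/4
for P features, subspace ensembles use 30 learners on ceil(P/2)-feature
subspaces).  Two presets absent from scikit-learn — kernel naive Bayes and
RUSBoosted trees — are implemented here as small estimators.

Evaluation follows the fragment-level protocol: a stratified 70/30
train/validation split (``mode="fragment"``; ``mode="recording"`` keeps
all fragments of a recording on one side and is the leakage-safe
alternative), features z-scored with statistics fit on the training split
only, and accuracy / sensitivity / specificity / F1 on the validation
split with "abnormal" as the positive class.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from scipy.stats import gaussian_kde

from .errors import ParameterError, PCGWarning
from .feature_pooling import FeatureTable, SelectionResult, build_feature_set

POSITIVE_LABEL = "abnormal"

FAMILIES = ("decision_tree", "naive_bayes", "svm", "knn", "ensemble")

#: The per-family best variants reported by the comparison protocol.
BEST_VARIANTS = (
    "fine_tree",
    "gaussian_nb",
    "fine_gaussian_svm",
    "weighted_knn",
    "subspace_knn",
)


def _inv_sq_dist(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Mirrors the toolbox "Kernel Naive Bayes" preset: class-conditional
    densities are products of univariate KDEs (Silverman bandwidth).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.priors_ = np.bincount(y_idx) / y_idx.size
        self.kdes_ = []
        for c in range(self.classes_.size):
            rows = X[y_idx == c]
            feats = []
            for r in range(X.shape[1]):
                col = rows[:, r]
                if np.ptp(col) == 0 or col.size < 2:
                    feats.append(("normal", col.mean(),
                                  max(col.std(), 1e-9)))
                else:
                    feats.append(("kde", gaussian_kde(col), None))
            self.kdes_.append(feats)
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, dtype=np.float64)
        ll = np.zeros((X.shape[0], self.classes_.size))
        for c, feats in enumerate(self.kdes_):
            ll[:, c] = np.log(self.priors_[c])
            for r, spec in enumerate(feats):
                if spec[0] == "kde":
                    dens = spec[1](X[:, r])
                else:
                    _, mu, sd = spec
                    dens = np.exp(-0.5 * ((X[:, r] - mu) / sd) ** 2) / (
                        sd * math.sqrt(2 * math.pi)
                    )
                ll[:, c] += np.log(np.maximum(dens, 1e-300))
        return ll

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost.M1 on random-undersampled training sets.

    Each boosting round draws a class-balanced subsample (the majority
    class undersampled to the minority size, weighted by the current boost
    distribution), fits a shallow tree, and applies the usual AdaBoost
    weight update on the full training set.
    """

    def __init__(self, n_estimators: int = 30, max_leaf_nodes: int = 21,
                 learning_rate: float = 0.1, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_leaf_nodes = max_leaf_nodes
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        n = y_idx.size
        w = np.full(n, 1.0 / n)
        n_min = np.bincount(y_idx).min()
        self.estimators_, self.alphas_ = [], []
        for m in range(self.n_estimators):
            sample = []
            for c in range(self.classes_.size):
                rows = np.flatnonzero(y_idx == c)
                p = w[rows] / w[rows].sum()
                sample.append(
                    rng.choice(rows, size=min(n_min, rows.size),
                               replace=True, p=p)
                )
            sample = np.concatenate(sample)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[sample], y_idx[sample])
            pred = tree.predict(X)
            err = float(w[pred != y_idx].sum())
            if err >= 0.5:
                if not self.estimators_:  # keep at least one learner
                    self.estimators_.append(tree)
                    self.alphas_.append(1.0)
                break
            err = max(err, 1e-12)
            alpha = self.learning_rate * 0.5 * math.log((1 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * np.where(pred != y_idx, 1.0, -1.0))
            w /= w.sum()
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            votes[np.arange(X.shape[0]), tree.predict(X)] += alpha
        return self.classes_[np.argmax(votes, axis=1)]


@dataclass(frozen=True)
class ClassifierPreset:
    """A named classifier variant with its toolbox-style hyperparameters."""

    family: str
    variant: str
    hyperparameters: dict

    def build(self, n_features: int, seed: int = 0):
        """Instantiate the scikit-learn (or in-package) estimator."""
        return _BUILDERS[self.variant](self.hyperparameters, n_features, seed)


def _knn(k, n_features, seed, **kw):
    return KNeighborsClassifier(n_neighbors=k, **kw)


_BUILDERS = {
    "fine_tree": lambda h, p, s: DecisionTreeClassifier(
        max_leaf_nodes=h["max_splits"] + 1, random_state=s),
    "medium_tree": lambda h, p, s: DecisionTreeClassifier(
        max_leaf_nodes=h["max_splits"] + 1, random_state=s),
    "coarse_tree": lambda h, p, s: DecisionTreeClassifier(
        max_leaf_nodes=h["max_splits"] + 1, random_state=s),
    "gaussian_nb": lambda h, p, s: GaussianNB(),
    "kernel_nb": lambda h, p, s: KernelNaiveBayes(),
    "linear_svm": lambda h, p, s: SVC(kernel="linear", C=h["C"],
                                      random_state=s),
    "quadratic_svm": lambda h, p, s: SVC(kernel="poly", degree=2, coef0=1,
                                         gamma="scale", C=h["C"],
                                         random_state=s),
    "cubic_svm": lambda h, p, s: SVC(kernel="poly", degree=3, coef0=1,
                                     gamma="scale", C=h["C"],
                                     random_state=s),
    "fine_gaussian_svm": lambda h, p, s: SVC(
        kernel="rbf", C=h["C"], gamma=1.0 / (math.sqrt(p) / 4) ** 2,
        random_state=s),
    "medium_gaussian_svm": lambda h, p, s: SVC(
        kernel="rbf", C=h["C"], gamma=1.0 / math.sqrt(p) ** 2,
        random_state=s),
    "coarse_gaussian_svm": lambda h, p, s: SVC(
        kernel="rbf", C=h["C"], gamma=1.0 / (4 * math.sqrt(p)) ** 2,
        random_state=s),
    "fine_knn": lambda h, p, s: _knn(1, p, s),
    "medium_knn": lambda h, p, s: _knn(10, p, s),
    "coarse_knn": lambda h, p, s: _knn(100, p, s),
    "cosine_knn": lambda h, p, s: _knn(10, p, s, metric="cosine"),
    "cubic_knn": lambda h, p, s: _knn(10, p, s, metric="minkowski",
                                      p=3),
    "weighted_knn": lambda h, p, s: _knn(10, p, s, weights=_inv_sq_dist),
    "boosted_tree": lambda h, p, s: AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=21),
        n_estimators=h["n_learners"], learning_rate=0.1, random_state=s),
    "bagged_tree": lambda h, p, s: RandomForestClassifier(
        n_estimators=h["n_learners"], random_state=s),
    "subspace_discriminant": lambda h, p, s: BaggingClassifier(
        estimator=LinearDiscriminantAnalysis(),
        n_estimators=h["n_learners"], bootstrap=False,
        max_features=max(1, math.ceil(p / 2)), random_state=s),
    "subspace_knn": lambda h, p, s: BaggingClassifier(
        estimator=KNeighborsClassifier(n_neighbors=1),
        n_estimators=h["n_learners"], bootstrap=False,
        max_features=max(1, math.ceil(p / 2)), random_state=s),
    "rusboosted_tree": lambda h, p, s: RUSBoostClassifier(
        n_estimators=h["n_learners"], random_state=s),
}

#: All 22 toolbox variants, keyed by variant name.
PRESETS: dict[str, ClassifierPreset] = {
    # decision trees
    "fine_tree": ClassifierPreset("decision_tree", "fine_tree",
                                  {"max_splits": 100}),
    "medium_tree": ClassifierPreset("decision_tree", "medium_tree",
                                    {"max_splits": 20}),
    "coarse_tree": ClassifierPreset("decision_tree", "coarse_tree",
                                    {"max_splits": 4}),
    # naive Bayes
    "gaussian_nb": ClassifierPreset("naive_bayes", "gaussian_nb", {}),
    "kernel_nb": ClassifierPreset("naive_bayes", "kernel_nb", {}),
    # SVMs
    "linear_svm": ClassifierPreset("svm", "linear_svm", {"C": 1.0}),
    "quadratic_svm": ClassifierPreset("svm", "quadratic_svm", {"C": 1.0}),
    "cubic_svm": ClassifierPreset("svm", "cubic_svm", {"C": 1.0}),
    "fine_gaussian_svm": ClassifierPreset("svm", "fine_gaussian_svm",
                                          {"C": 1.0}),
    "medium_gaussian_svm": ClassifierPreset("svm", "medium_gaussian_svm",
                                            {"C": 1.0}),
    "coarse_gaussian_svm": ClassifierPreset("svm", "coarse_gaussian_svm",
                                            {"C": 1.0}),
    # KNNs
    "fine_knn": ClassifierPreset("knn", "fine_knn", {"k": 1}),
    "medium_knn": ClassifierPreset("knn", "medium_knn", {"k": 10}),
    "coarse_knn": ClassifierPreset("knn", "coarse_knn", {"k": 100}),
    "cosine_knn": ClassifierPreset("knn", "cosine_knn", {"k": 10}),
    "cubic_knn": ClassifierPreset("knn", "cubic_knn", {"k": 10}),
    "weighted_knn": ClassifierPreset("knn", "weighted_knn",
                                     {"k": 10, "weights": "squaredinverse"}),
    # ensembles
    "boosted_tree": ClassifierPreset("ensemble", "boosted_tree",
                                     {"n_learners": 30}),
    "bagged_tree": ClassifierPreset("ensemble", "bagged_tree",
                                    {"n_learners": 30}),
    "subspace_discriminant": ClassifierPreset(
        "ensemble", "subspace_discriminant", {"n_learners": 30}),
    "subspace_knn": ClassifierPreset("ensemble", "subspace_knn",
                                     {"n_learners": 30}),
    "rusboosted_tree": ClassifierPreset("ensemble", "rusboosted_tree",
                                        {"n_learners": 30}),
}


@dataclass
class EvalReport:
    """Per (preset, feature set) validation metrics plus the split spec."""

    frame: pd.DataFrame  # columns: preset, family, feature_set, metrics...
    split: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "schema": "pcg-lstf-report/1",
                    "split": self.split,
                    "rows": self.frame.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "EvalReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(pd.DataFrame(d["rows"]), d.get("split", {}))


def split_table(
    table: FeatureTable,
    train_frac: float = 0.7,
    mode: str = "fragment",
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/validation split of a feature table.

    ``mode="fragment"`` splits rows independently; ``mode="recording"``
    keeps every fragment of a recording on the same side.
    """
    if mode not in ("fragment", "recording"):
        raise ParameterError(f"unknown split mode {mode!r}")
    y = table.y
    rng = np.random.default_rng(seed)
    if mode == "fragment":
        train_idx = []
        for c in np.unique(y):
            rows = np.flatnonzero(y == c)
            if rows.size < 2:
                raise ParameterError(
                    f"class {c!r} has fewer than 2 rows; cannot split"
                )
            perm = rng.permutation(rows)
            n_tr = int(round(train_frac * rows.size))
            n_tr = min(max(n_tr, 1), rows.size - 1)
            train_idx.append(perm[:n_tr])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        recs = table.data["recording_id"].to_numpy()
        uniq = pd.unique(recs)
        rec_label = {r: y[recs == r][0] for r in uniq}
        train_recs = []
        for c in np.unique(y):
            rs = [r for r in uniq if rec_label[r] == c]
            if len(rs) < 2:
                raise ParameterError(
                    f"class {c!r} has fewer than 2 recordings; cannot split"
                )
            perm = rng.permutation(len(rs))
            n_tr = min(max(int(round(train_frac * len(rs))), 1), len(rs) - 1)
            train_recs += [rs[i] for i in perm[:n_tr]]
        train_idx = np.flatnonzero(np.isin(recs, train_recs))
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    train, val = table.subset_rows(np.flatnonzero(mask)), table.subset_rows(
        np.flatnonzero(~mask)
    )
    for side, name in ((train, "train"), (val, "validation")):
        if np.unique(side.y).size < np.unique(y).size:
            raise ParameterError(
                f"a class is absent from the {name} side; use more data"
            )
    return train, val


def _metrics(y_true, y_pred) -> dict[str, float]:
    pos = POSITIVE_LABEL
    tp = float(np.sum((y_pred == pos) & (y_true == pos)))
    tn = float(np.sum((y_pred != pos) & (y_true != pos)))
    fp = float(np.sum((y_pred == pos) & (y_true != pos)))
    fn = float(np.sum((y_pred != pos) & (y_true == pos)))
    acc = (tp + tn) / max(tp + tn + fp + fn, 1.0)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "f1": f1}


def train_eval(
    train: FeatureTable,
    validation: FeatureTable,
    presets: list[str | ClassifierPreset],
    seed: int = 0,
    scale: bool = True,
) -> EvalReport:
    """Fit each preset on the training table, score on validation."""
    if not presets:
        raise ParameterError("presets must be non-empty")
    if train.feature_names != validation.feature_names:
        raise ParameterError("train/validation column mismatch")
    X_tr, y_tr = train.X, train.y
    X_va, y_va = validation.X, validation.y
    keep = np.ptp(X_tr, axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(train.feature_names, keep) if not k]
        warnings.warn(
            f"dropping constant training columns: {dropped}", PCGWarning,
            stacklevel=2,
        )
        X_tr, X_va = X_tr[:, keep], X_va[:, keep]
    scaler = None
    if scale:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_va = scaler.transform(X_tr), scaler.transform(X_va)
    rows = []
    for item in presets:
        preset = PRESETS[item] if isinstance(item, str) else item
        clf = preset.build(n_features=X_tr.shape[1], seed=seed)
        if isinstance(clf, KNeighborsClassifier):
            clf.set_params(n_neighbors=min(clf.n_neighbors, X_tr.shape[0]))
        clf.fit(X_tr, y_tr)
        row = {
            "preset": preset.variant,
            "family": preset.family,
            "feature_set": train.feature_set_tag,
        }
        row.update(_metrics(y_va, np.asarray(clf.predict(X_va))))
        rows.append(row)
    report = EvalReport(pd.DataFrame(rows), split={"seed": seed})
    report.scaler_ = scaler  # exposed so leakage can be audited
    return report


def ablation(
    table33: FeatureTable,
    selection: SelectionResult,
    presets: list[str] = BEST_VARIANTS,
    seeds: tuple[int, ...] = (0,),
    train_frac: float = 0.7,
    mode: str = "fragment",
) -> EvalReport:
    """Evaluate the presets on all five feature sets (mean +/- sd over seeds)."""
    all_rows = []
    from .feature_pooling import FEATURE_SET_TAGS

    for tag in FEATURE_SET_TAGS:
        sub = build_feature_set(table33, tag, selection=selection)
        for seed in seeds:
            tr, va = split_table(sub, train_frac=train_frac, mode=mode,
                                 seed=seed)
            rep = train_eval(tr, va, presets, seed=seed)
            rep.frame["seed"] = seed
            all_rows.append(rep.frame)
    raw = pd.concat(all_rows, ignore_index=True)
    metrics = ["accuracy", "sensitivity", "specificity", "f1"]
    agg = raw.groupby(["preset", "family", "feature_set"], as_index=False)[
        metrics
    ].agg(["mean", "std"])
    agg.columns = [
        c[0] if c[1] in ("", None) else f"{c[0]}_{c[1]}" for c in agg.columns
    ]
    agg = agg.fillna(0.0)
    report = EvalReport(
        agg,
        split={"train_frac": train_frac, "mode": mode, "seeds": list(seeds)},
    )
    report.raw_ = raw
    return report
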