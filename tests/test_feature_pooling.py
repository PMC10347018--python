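import numpy as np
import pytest

from pcg_lstf.errors import ParameterError
from pcg_lstf.feature_pooling import (
    FeatureTable,
    SelectionResult,
    build_feature_set,
    make_feature_table,
    merge_features,
    nca_weights,
    split_merged,
)
from pcg_lstf.long_term_features import LONG_TERM_NAMES, LongTermFeatures
from pcg_lstf.short_term_features import SHORT_TERM_NAMES, ShortTermFeatures


def toy_table(X, y, feature_names=None, rec_ids=None):
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    rows = []
    for i in range(X.shape[0]):
        d = {"recording_id": rec_ids[i] if rec_ids else f"r{i}",
             "fragment_index": 0, "label": y[i]}
        d.update(zip(names, X[i]))
        rows.append(d)
    return make_feature_table(rows)


def lstf_table(n_rows, rng, n_recordings=None):
    """A 33-column table with random features and alternating labels."""
    names = list(SHORT_TERM_NAMES + LONG_TERM_NAMES)
    X = rng.normal(size=(n_rows, 33))
    y = ["normal" if i % 2 == 0 else "abnormal" for i in range(n_rows)]
    t = toy_table(X, y, feature_names=names)
    return FeatureTable(t.data, feature_set_tag="LSTF")


class TestMergeSplit:
    def test_merge_gives_33_in_order(self, rng):
        stf = ShortTermFeatures(rng.normal(size=27))
        ltf = LongTermFeatures(np.arange(6, dtype=float))
        merged, names = merge_features(stf, ltf)
        assert merged.size == 33
        assert names == SHORT_TERM_NAMES + LONG_TERM_NAMES
        assert np.array_equal(merged[27:], ltf.values)

    def test_merge_then_split_recovers_both(self, rng):
        stf = ShortTermFeatures(rng.normal(size=27))
        ltf = LongTermFeatures(rng.normal(size=6) ** 2 + 0.1)
        merged, _ = merge_features(stf, ltf)
        s2, l2 = split_merged(merged)
        assert np.array_equal(s2.values, stf.values)
        assert np.array_equal(l2.values, ltf.values)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_merged(np.zeros(30))


class TestNCAWeights:
    def _planted(self, rng, n=500, d=10, flip=0.0):
        y = np.array(["normal", "abnormal"])[rng.integers(0, 2, size=n)]
        X = rng.normal(size=(n, d))
        signal = np.where(y == "abnormal", 1.0, -1.0)
        X[:, 3] = signal + 0.1 * rng.normal(size=n)
        return toy_table(X, list(y))

    def test_planted_feature_gets_maximum_weight(self, rng):
        table = self._planted(rng)
        res = nca_weights(table, seed=0)
        assert max(res.weights, key=res.weights.get) == "f3"
        assert "f3" in res.selected

    def test_noise_features_weighted_low(self, rng):
        table = self._planted(rng)
        res = nca_weights(table, seed=0)
        wmax = res.weights["f3"]
        for f, w in res.weights.items():
            if f != "f3":
                assert w < 0.1 * wmax

    def test_duplicated_feature_shares_weight(self, rng):
        table = self._planted(rng)
        df = table.data.copy()
        df["f3_dup"] = df["f3"]
        res = nca_weights(FeatureTable(df), seed=0)
        w1, w2 = res.weights["f3"], res.weights["f3_dup"]
        assert abs(w1 - w2) <= 0.1 * max(w1, w2)

    def test_deterministic_and_permutation_invariant(self, rng):
        table = self._planted(rng, n=200)
        res1 = nca_weights(table, seed=0)
        res2 = nca_weights(table, seed=0)
        assert res1.weights == res2.weights
        perm = rng.permutation(len(table))
        res3 = nca_weights(table.subset_rows(perm), seed=0)
        for f in res1.weights:
            assert res3.weights[f] == pytest.approx(res1.weights[f],
                                                    abs=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        table = toy_table(X, ["normal"] * 20)
        with pytest.raises(ParameterError):
            nca_weights(table)

    def test_long_term_signal_ranks_long_term_features_top(self, rng):
        """When class signal lives in the 6 long-term columns, they rank
        in the top 10 by NCA weight."""
        n = 400
        names = list(SHORT_TERM_NAMES + LONG_TERM_NAMES)
        y = np.array(["normal", "abnormal"])[rng.integers(0, 2, size=n)]
        X = rng.normal(size=(n, 33))
        shift = np.where(y == "abnormal", 1.5, -1.5)
        for j in range(27, 33):
            X[:, j] = shift + 0.3 * rng.normal(size=n)
        table = toy_table(X, list(y), feature_names=names)
        res = nca_weights(table, seed=0)
        ranked = sorted(res.weights, key=res.weights.get, reverse=True)
        top10 = set(ranked[:10])
        assert set(LONG_TERM_NAMES) <= top10


class TestSelectionResult:
    def _result(self):
        weights = {f"f{i}": float(10 - i) for i in range(10)}
        return SelectionResult(weights, threshold=5.5,
                               selected=[f"f{i}" for i in range(5)], seed=0)

    def test_threshold_consistency_enforced(self):
        with pytest.raises(ValueError):
            SelectionResult({"a": 1.0, "b": 2.0}, threshold=0.5,
                            selected=["b"], seed=0)

    def test_top_k(self):
        res = self._result().top_k(3)
        assert res.selected == ["f0", "f1", "f2"]

    def test_json_round_trip(self, tmp_path):
        res = self._result()
        path = str(tmp_path / "sel.json")
        res.to_json(path)
        back = SelectionResult.from_json(path)
        assert back.weights == res.weights
        assert back.selected == res.selected

    def test_top_k_short_keeps_exactly_k_short_term(self, rng):
        names = list(SHORT_TERM_NAMES + LONG_TERM_NAMES)
        weights = {f: float(rng.uniform(0, 1)) for f in names}
        thr = float(np.mean(list(weights.values())))
        res = SelectionResult(
            weights, thr, [f for f, w in weights.items() if w > thr], seed=0
        )
        res16 = res.top_k_short(16)
        n_short = sum(f in SHORT_TERM_NAMES for f in res16.selected)
        assert n_short == 16


class TestBuildFeatureSet:
    def test_canonical_widths(self, rng):
        table = lstf_table(8, rng)
        assert len(build_feature_set(table, "STF").feature_names) == 27
        assert len(build_feature_set(table, "LTF").feature_names) == 6
        assert len(build_feature_set(table, "LSTF").feature_names) == 33

    def test_ltf_is_the_trailing_block(self, rng):
        table = lstf_table(8, rng)
        sub = build_feature_set(table, "LTF")
        assert tuple(sub.feature_names) == LONG_TERM_NAMES

    def test_slstf_width_is_k_plus_6(self, rng):
        table = lstf_table(8, rng)
        weights = {f: float(i) for i, f in enumerate(table.feature_names)}
        sel = SelectionResult(weights, -1.0, list(weights), seed=0)
        sel = sel.top_k_short(16)
        sstf = build_feature_set(table, "SSTF", selection=sel)
        slstf = build_feature_set(table, "SLSTF", selection=sel)
        assert len(sstf.feature_names) == 16
        assert len(slstf.feature_names) == 22
        assert set(LONG_TERM_NAMES) <= set(slstf.feature_names)

    def test_selection_required_for_selected_sets(self, rng):
        table = lstf_table(8, rng)
        with pytest.raises(ParameterError):
            build_feature_set(table, "SSTF")

    def test_broadcast_long_term_shared_within_recording(self, rng):
        """All fragments of a recording carry identical trailing 6 values."""
        names = list(SHORT_TERM_NAMES + LONG_TERM_NAMES)
        rows = []
        ltf_vals = rng.normal(size=6)
        for i in range(3):
            d = {"recording_id": "recA", "fragment_index": i,
                 "label": "normal"}
            d.update(zip(names[:27], rng.normal(size=27)))
            d.update(zip(names[27:], ltf_vals))
            rows.append(d)
        table = FeatureTable(make_feature_table(rows).data,
                             feature_set_tag="LSTF")
        sub = build_feature_set(table, "LTF")
        assert np.allclose(sub.X, sub.X[0])
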