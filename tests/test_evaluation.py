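"""Split-sample mechanics, AUC/TSS oracles, ensemble weighting."""

import numpy as np
import pandas as pd
import pytest

import viperarisk as v
from viperarisk.errors import EnsembleError, EvaluationError
from viperarisk.evaluation import EnsembleSuitability
from tests.test_predictors import table_from_array


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_tss(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best, best_thr = -np.inf, None
    for thr in sorted(set(scores)):
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        stat = sens + spec - 1
        if stat > best + 1e-12:
            best, best_thr = stat, thr
    return best, best_thr


class TestSplitSample:
    def test_eight_plus_eight(self):
        table = table_from_array(np.zeros((16, 1)), ["a"],
                                 [1] * 8 + [0] * 8)
        train, test = v.split_sample(table, 0.75, seed=0)
        assert (train.data["label"] == 1).sum() == 6
        assert (train.data["label"] == 0).sum() == 6
        assert len(test.data) == 4

    def test_partition(self):
        rng = np.random.default_rng(0)
        table = table_from_array(rng.standard_normal((40, 2)), ["a", "b"],
                                 [1] * 15 + [0] * 25)
        table.data["a"] = np.arange(40.0)  # unique key per row
        train, test = v.split_sample(table, 0.75, seed=1)
        got = sorted(train.data["a"]) + sorted(test.data["a"])
        assert sorted(got) == sorted(table.data["a"])
        assert set(train.data["a"]).isdisjoint(test.data["a"])

    def test_seeded_determinism(self):
        table = table_from_array(np.arange(30.0)[:, None], ["a"],
                                 [1] * 10 + [0] * 20)
        a = v.split_sample(table, seed=5)[0].data
        b = v.split_sample(table, seed=5)[0].data
        assert a.equals(b)

    def test_tiny_class_rejected(self):
        table = table_from_array(np.zeros((3, 1)), ["a"], [1, 0, 0])
        with pytest.raises(EvaluationError):
            v.split_sample(table)


class TestAuc:
    def test_perfect_separation(self):
        assert v.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert v.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_worked_four_point_example(self):
        # pairs: (.8>.6) w, (.8>.3) w, (.55<.6) l, (.55>.3) w -> 3/4
        assert v.auc([0.8, 0.6, 0.55, 0.3], [1, 0, 1, 0]) == 0.75

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert v.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        base = v.auc(scores, labels)
        assert v.auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert v.auc(np.argsort(np.argsort(scores)), labels) == pytest.approx(
            base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            v.auc([0.1, 0.2], [1, 1])


class TestTss:
    def test_perfect_separation(self):
        t, thr = v.tss([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert t == 1.0 and thr == pytest.approx(0.8)

    def test_uninformative_scores(self):
        t, _ = v.tss([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert t == 0.0

    def test_six_point_worked_set(self):
        scores = [0.9, 0.7, 0.65, 0.5, 0.45, 0.2]
        labels = [1, 1, 0, 1, 0, 0]
        t, thr = v.tss(scores, labels)
        bt, bthr = brute_force_tss(scores, labels)
        assert t == pytest.approx(bt, abs=1e-12)
        assert thr == pytest.approx(bthr)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scan_oracle_and_threshold_reproduces(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=25), 2)
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        t, thr = v.tss(scores, labels)
        bt, _ = brute_force_tss(scores, labels)
        assert t == pytest.approx(bt, abs=1e-12)
        pred = np.asarray(scores) >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        assert sens + spec - 1 == pytest.approx(t, abs=1e-12)


@pytest.fixture(scope="module")
def records(small_table):
    algorithms = {"GLM": v.GlmSuitability(),
                  "SRE": v.SreSuitability(),
                  "GBM": v.GbmSuitability(n_trees=100, learning_rate=0.05)}
    return v.evaluate_replicates(small_table.subset(
        v.select_predictors(small_table)[0]), algorithms,
        n_replicates=4, seed=3)


class TestEvaluateReplicates:
    def test_record_count_and_ranges(self, records):
        assert len(records) == 12  # 3 algorithms x 4 replicates
        assert records["auc"].between(0, 1).all()
        assert records["tss"].between(-1, 1).all()

    def test_replicates_share_splits(self, records):
        # same split per replicate: identical replicate ids across algorithms
        assert set(records.groupby("algorithm")["replicate"].apply(tuple)) == {
            (1, 2, 3, 4)}


class TestEnsemble:
    def test_auc_proportional_weights(self):
        recs = pd.DataFrame({"algorithm": ["A", "A", "B", "B"],
                             "replicate": [1, 2, 1, 2],
                             "auc": [0.95, 0.85, 0.65, 0.55],
                             "tss": [0.8] * 4, "tss_threshold": [0.5] * 4})

        class Stub:
            def __init__(self, value):
                self.value = value
                self.predictor_names_ = ["a"]

            def fit(self, X, y, sample_weight=None):
                return self

            def predict(self, X):
                return np.full(len(X), self.value)

            def get_params(self, deep=True):
                return {"value": self.value}

            def set_params(self, **kw):
                return self

        table = table_from_array(np.zeros((8, 1)), ["a"], [1] * 4 + [0] * 4)
        ens = v.build_ensemble(table, {"A": Stub(1.0), "B": Stub(0.0)}, recs)
        np.testing.assert_allclose(ens.weights, [0.6, 0.4])
        assert ens.predict(table.X)[0] == pytest.approx(0.6)

    def test_equal_aucs_equal_weights(self):
        ens = EnsembleSuitability(
            members=[v.SreSuitability(), v.SreSuitability()], weights=[0.7, 0.7])
        np.testing.assert_allclose(ens.weights, [0.5, 0.5])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(EnsembleError):
            EnsembleSuitability(members=[v.SreSuitability()], weights=[0.0])

    def test_ensemble_map_is_convex_combination(self, small_stack, small_table):
        sub = small_table.subset(v.select_predictors(small_table)[0])
        algorithms = {"GLM": v.GlmSuitability(), "SRE": v.SreSuitability()}
        recs = v.evaluate_replicates(sub, algorithms, n_replicates=2, seed=1)
        ens = v.build_ensemble(sub, algorithms, recs)
        stack = small_stack.subset(sub.predictor_names)
        smap = v.predict_ensemble(ens, stack)
        members = [v.predict_model(m, stack).values for m in ens.members]
        lo, hi = np.minimum(*members), np.maximum(*members)
        assert (smap.values >= lo - 1e-9).all()
        assert (smap.values <= hi + 1e-9).all()

    def test_single_member_identity(self, small_stack, small_table):
        sub = small_table.subset(v.select_predictors(small_table)[0])
        model = v.SreSuitability().fit(sub.X, sub.y)
        ens = EnsembleSuitability(members=[model], weights=[1.0])
        stack = small_stack.subset(sub.predictor_names)
        np.testing.assert_array_equal(v.predict_ensemble(ens, stack).values,
                                      v.predict_model(model, stack).values)


class TestEvaluateConsensus:
    def test_both_modes_return_valid_metrics(self, small_table, records):
        sub = small_table.subset(v.select_predictors(small_table)[0])
        algorithms = {"GLM": v.GlmSuitability(), "SRE": v.SreSuitability(),
                      "GBM": v.GbmSuitability(n_trees=100, learning_rate=0.05)}
        for mode in ("holdout", "resubstitution"):
            out = v.evaluate_consensus(sub, algorithms, records, mode=mode,
                                       seed=2)
            assert 0 <= out["auc"] <= 1
            assert -1 <= out["tss"] <= 1

    def test_unknown_mode_rejected(self, small_table, records):
        with pytest.raises(EvaluationError):
            v.evaluate_consensus(small_table, {}, records, mode="magic")
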