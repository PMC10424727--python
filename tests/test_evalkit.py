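import numpy as np
import pytest

from ecgtracks import evalkit
from ecgtracks.io import EcgRecord, LabelScheme

SCHEME4 = LabelScheme.synthetic(("a", "b", "c", "d"))


def brute_force_counts(truth, predicted, classes):
    """Independent oracle: enumerate every record into TP/FP/TN/FN."""
    out = {}
    for c in classes:
        tp = fp = tn = fn = 0
        for t, p in zip(truth, predicted):
            t = t if isinstance(t, (set, frozenset)) else {t}
            p = p if isinstance(p, (set, frozenset)) else {p}
            if c in t and c in p:
                tp += 1
            elif c in t:
                fn += 1
            elif c in p:
                fp += 1
            else:
                tn += 1
        out[c] = (tp, fp, tn, fn)
    return out


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = [{"a"}, {"b"}, {"c"}, {"d"}] * 5
        rep = evalkit.compute_metrics(truth, truth, SCHEME4)
        for m in rep.per_class.values():
            assert m["f1"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_formula_case_half(self):
        # class 'a': TP=1, FP=1, FN=1 -> precision=recall=F1=0.5
        truth = [{"a"}, {"a"}, {"b"}, {"b"}]
        pred = [{"a"}, {"b"}, {"a"}, {"b"}]
        rep = evalkit.compute_metrics(truth, pred, SCHEME4)
        m = rep.per_class["a"]
        assert m["precision"] == m["sensitivity"] == m["f1"] == 0.5

    def test_absent_never_predicted_class_scores_one(self):
        truth = [{"a"}, {"b"}]
        rep = evalkit.compute_metrics(truth, truth, SCHEME4)
        assert rep.per_class["c"]["f1"] == 1.0
        assert rep.per_class["c"]["sensitivity"] == 1.0

    @pytest.mark.parametrize("mode", ["multiclass", "multilabel"])
    def test_matches_bruteforce_oracle(self, mode, rng):
        classes = ["a", "b", "c", "d"]
        n = 200
        for trial in range(5):
            if mode == "multiclass":
                truth = [{classes[i]} for i in rng.integers(0, 4, n)]
                pred = [{classes[i]} for i in rng.integers(0, 4, n)]
            else:
                truth = [set(np.array(classes)[rng.random(4) < 0.4]) or {"a"}
                         for _ in range(n)]
                pred = [set(np.array(classes)[rng.random(4) < 0.4]) or {"b"}
                        for _ in range(n)]
            rep = evalkit.compute_metrics(truth, pred, SCHEME4)
            oracle = brute_force_counts(truth, pred, classes)
            for c in classes:
                cc = rep.counts[c]
                assert (cc.tp, cc.fp, cc.tn, cc.fn) == oracle[c]
                tp, fp, tn, fn = oracle[c]
                if tp + fp and tp + fn:
                    p, r = tp / (tp + fp), tp / (tp + fn)
                    f1 = 2 * p * r / (p + r) if p + r else 0.0
                    assert rep.per_class[c]["f1"] == pytest.approx(f1)

    def test_macro_invariant_to_relabeling(self, rng):
        classes = ["a", "b", "c", "d"]
        truth = [{classes[i]} for i in rng.integers(0, 4, 100)]
        pred = [{classes[i]} for i in rng.integers(0, 4, 100)]
        rep1 = evalkit.compute_metrics(truth, pred, SCHEME4)
        perm = {"a": "c", "b": "d", "c": "a", "d": "b"}
        t2 = [{perm[next(iter(t))]} for t in truth]
        p2 = [{perm[next(iter(p))]} for p in pred]
        rep2 = evalkit.compute_metrics(t2, p2, SCHEME4)
        assert rep1.averaged["f1"] == pytest.approx(rep2.averaged["f1"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evalkit.compute_metrics([{"a"}], [{"a"}, {"b"}], SCHEME4)

    def test_micro_average(self):
        truth = [{"a"}, {"a"}, {"b"}, {"c"}]
        pred = [{"a"}, {"b"}, {"b"}, {"c"}]
        rep = evalkit.compute_metrics(truth, pred, SCHEME4, average="micro")
        # pooled: TP=3, FP=1, FN=1 over one-vs-rest counts
        assert rep.averaged["precision"] == pytest.approx(3 / 4)


class TestCrossvalidate:
    def test_folds_partition_records(self):
        labels = [["a", "b", "c", "d"][i % 4] for i in range(40)]
        folds = evalkit.stratified_folds(labels, 5, seed=0)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(40))
        assert all(len(f) == 8 for f in folds)

    def test_fold_sizes_1000(self):
        labels = ["a"] * 1000
        folds = evalkit.stratified_folds(labels, 5, seed=1)
        assert [len(f) for f in folds] == [200] * 5

    def test_constant_classifier_zero_sd(self):
        """A majority-class classifier on evenly stratified folds has zero
        fold-to-fold variance in the majority class's specificity."""
        records = list(range(100))
        labels = ["a"] * 60 + ["b"] * 40
        scheme = LabelScheme.synthetic(("a", "b"))

        def fit_predict(tr, trl, te):
            return [{"a"}] * len(te)

        rep = evalkit.crossvalidate(records, labels, fit_predict, scheme,
                                    k=5, seed=0)
        assert rep.cv_sd["specificity"] == pytest.approx(0.0)
        assert rep.cv_sd["sensitivity"] == pytest.approx(0.0)

    def test_missing_class_warns(self):
        records = list(range(10))
        labels = ["a"] * 9 + ["b"]
        scheme = LabelScheme.synthetic(("a", "b"))
        with pytest.warns(UserWarning, match="absent"):
            evalkit.crossvalidate(records, labels,
                                  lambda tr, trl, te: [{"a"}] * len(te),
                                  scheme, k=5, seed=0)


class TestPerSource:
    def _rec(self, rid, source, seconds=10.0):
        return EcgRecord(record_id=rid, signal=np.zeros((1, int(300 * seconds))),
                         fs=300.0, lead_names=["I"], labels={"a"},
                         source=source)

    def test_identical_sources_identical_f1(self):
        scheme = LabelScheme.synthetic(("a", "b"))
        recs = [self._rec(f"x{i}", "S1") for i in range(4)]
        recs += [self._rec(f"y{i}", "S2") for i in range(4)]
        truth = [{"a"}] * 8
        pred = [{"a"}, {"a"}, {"b"}, {"a"}] * 2
        table = evalkit.per_source_report(recs, truth, pred, scheme)
        assert table["S1"]["f1"] == table["S2"]["f1"]

    def test_all_correct_source_scores_one(self):
        scheme = LabelScheme.synthetic(("a", "b"))
        recs = [self._rec("x0", "S1")]
        table = evalkit.per_source_report(recs, [{"a"}], [{"a"}], scheme)
        assert table["S1"]["f1"] == 1.0

    def test_mean_length_column(self):
        scheme = LabelScheme.synthetic(("a", "b"))
        recs = [self._rec("x0", "S1", 10.0), self._rec("x1", "S1", 30.0)]
        table = evalkit.per_source_report(recs, [{"a"}] * 2, [{"a"}] * 2,
                                          scheme)
        assert table["S1"]["mean_length_s"] == pytest.approx(20.0)


class TestProfile:
    def _records(self, n):
        return [EcgRecord(record_id=f"r{i}", signal=np.zeros((1, 600)),
                          fs=300.0, lead_names=["I"], labels={"a"})
                for i in range(n)]

    def test_times_are_means(self):
        import time

        def proc(rec):
            time.sleep(0.002)
            return rec

        rep = evalkit.profile(proc, lambda x: 0, self._records(4))
        assert rep.time_processing_ms >= 2.0
        assert rep.time_total_ms == pytest.approx(
            rep.time_processing_ms + rep.time_predicting_ms)

    def test_zero_carbon_intensity(self):
        rep = evalkit.profile(lambda r: r, lambda x: 0, self._records(2),
                              carbon_intensity_g_per_wh=0.0)
        assert rep.co2_g == 0.0
        assert rep.estimated is True

    def test_energy_grows_with_set_size(self):
        def proc(rec):
            np.linalg.qr(np.random.default_rng(0).standard_normal((120, 120)))
            return rec

        small = evalkit.profile(proc, lambda x: 0, self._records(3))
        large = evalkit.profile(proc, lambda x: 0, self._records(12))
        assert large.energy_wh > small.energy_wh

    def test_empty_records(self):
        with pytest.raises(ValueError):
            evalkit.profile(lambda r: r, lambda x: 0, [])
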