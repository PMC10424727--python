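import numpy as np
import pandas as pd
import pytest

from ecgtracks import synth, tsboost
from ecgtracks.features import EXCLUDED_FAMILIES, extract_feature_vector
from ecgtracks.io import EcgRecord


def _rec(x, rid="r0", labels=frozenset({"sinus"})):
    return EcgRecord(record_id=rid, signal=np.atleast_2d(x), fs=300.0,
                     lead_names=["I"], labels=set(labels))


@pytest.fixture(scope="module")
def feature_dataset():
    """Small 4-class feature table with labels."""
    mix = {k: 30 for k in ("sinus", "af", "tachy", "brady")}
    pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=31,
                                   duration_s=10.0)
    recs = [r for r, _ in pairs]
    labels = [sorted(r.labels)[0] for r in recs]
    table = tsboost.extract_features(recs)
    return table, labels


class TestExtractFeatures:
    def test_no_excluded_family_in_columns(self, feature_dataset):
        table, _ = feature_dataset
        for col in table.columns:
            for fam in EXCLUDED_FAMILIES:
                assert fam not in col

    def test_identical_records_identical_rows(self, rng):
        x = rng.standard_normal(600)
        t = tsboost.extract_features([_rec(x, "a"), _rec(x, "b")])
        assert np.array_equal(t.loc["a"].to_numpy(), t.loc["b"].to_numpy(),
                              equal_nan=True)

    def test_reversal_invariant_features(self, rng):
        x = rng.standard_normal(500)
        t = tsboost.extract_features([_rec(x, "fwd"), _rec(x[::-1], "rev")])
        for col in ("variance", "mean", "maximum", "minimum", "abs_energy",
                    "standard_deviation", "quantile__q_0.3"):
            assert t.loc["fwd", col] == pytest.approx(t.loc["rev", col])

    def test_constant_signal_does_not_raise(self):
        t = tsboost.extract_features([_rec(np.full(500, 1.5))])
        assert t.shape[0] == 1  # degenerate values allowed, imputation handles

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tsboost.extract_features([])


class TestImputeAndFilter:
    def test_missing_becomes_minus_999(self):
        t = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.1, 0.2, 0.3]})
        out, _ = tsboost.impute_and_filter(t)
        assert out.loc[1, "a"] == -999.0

    def test_constant_column_dropped(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.1, 0.2, 0.3]})
        out, retained = tsboost.impute_and_filter(t)
        assert retained == ["b"] and list(out.columns) == ["b"]

    def test_infinite_threshold_errors(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [0.1, 0.2]})
        with pytest.raises(ValueError, match="every column"):
            tsboost.impute_and_filter(t, var_threshold=np.inf)

    def test_variance_computed_on_training_rows_only(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [0.1, 0.2, 0.3]},
                         index=["r0", "r1", "r2"])
        _, retained = tsboost.impute_and_filter(t, train_index=["r0", "r1"])
        assert retained == ["b"]  # 'a' is constant on the training rows

    def test_retained_list_reapplied_verbatim(self, feature_dataset):
        table, _ = feature_dataset
        tr = table.iloc[:80]
        _, retained = tsboost.impute_and_filter(tr)
        # replacing the held-out rows must not change the column selection
        out_a, _ = tsboost.impute_and_filter(table.iloc[80:], retained=retained)
        out_b, _ = tsboost.impute_and_filter(
            table.iloc[80:] * 3.14, retained=retained)
        assert list(out_a.columns) == list(out_b.columns) == retained


class TestTuneAndFit:
    def test_single_trial_boundary(self, feature_dataset):
        table, labels = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        res = tsboost.tune_and_fit(tab, labels, n_trials=1, seed=0)
        assert len(res.trials) == 1
        assert res.model is not None

    def test_sampled_params_within_bounds(self, feature_dataset):
        table, labels = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        res = tsboost.tune_and_fit(tab, labels, n_trials=10, seed=1)
        space = tsboost.SearchSpace.default(tab.shape[1])
        assert len(res.trials) == 10
        for trial in res.trials:
            for name, (lo, hi, _) in space.dims.items():
                assert lo <= trial["params"][name] <= hi

    def test_seed_determinism(self, feature_dataset):
        table, labels = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        a = tsboost.tune_and_fit(tab, labels, n_trials=6, seed=4)
        b = tsboost.tune_and_fit(tab, labels, n_trials=6, seed=4)
        assert a.best_params == b.best_params
        assert [t["score"] for t in a.trials] == [t["score"] for t in b.trials]

    def test_single_class_rejected(self, feature_dataset):
        table, _ = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        with pytest.raises(ValueError, match="2 classes"):
            tsboost.tune_and_fit(tab, ["sinus"] * len(tab), n_trials=1)

    def test_min_features_honored(self, feature_dataset):
        table, labels = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        res = tsboost.tune_and_fit(tab, labels, n_trials=3, seed=2)
        m = int(res.best_params["min_features_to_select"])
        assert len(res.selected_features) == min(m, tab.shape[1])


class TestFeatureImportance:
    def test_group_scores_sum_to_one(self, feature_dataset):
        table, labels = feature_dataset
        tab, _ = tsboost.impute_and_filter(table)
        res = tsboost.tune_and_fit(tab, labels, n_trials=2, seed=3)
        imp = tsboost.feature_importance(res)
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp["importance"].diff().dropna() <= 1e-12).all()  # descending

    def test_grouping_arithmetic(self):
        """Two features of one group with split counts 2 and 1 out of 10
        total yield a group score of 0.3."""
        class FakeBooster:
            def get_score(self, importance_type="weight"):
                return {"fft_coefficient__a": 2.0, "fft_coefficient__b": 1.0,
                        "quantile__q": 7.0}

        class FakeModel:
            def get_booster(self):
                return FakeBooster()

        res = tsboost.BoostResult(
            model=FakeModel(), classes=["x", "y"],
            selected_features=["fft_coefficient__a", "fft_coefficient__b",
                               "quantile__q"],
            best_params={}, best_score=1.0)
        imp = tsboost.feature_importance(res)
        assert imp.loc["fft_coefficient", "importance"] == pytest.approx(0.3)
        assert imp.loc["fft_coefficient", "n_features"] == 2
        assert imp.index[0] == "quantile"

    def test_peak_related_groups_rank_high_for_af(self):
        """AF vs sinus discrimination should lean on beat/spectral structure
        rather than slow baseline trends."""
        mix = {"sinus": 40, "af": 40}
        pairs = synth.simulate_dataset(mix, dialect="cinc2017", seed=33,
                                       duration_s=10.0)
        recs = [r for r, _ in pairs]
        labels = [sorted(r.labels)[0] for r in recs]
        tab, _ = tsboost.impute_and_filter(tsboost.extract_features(recs))
        res = tsboost.tune_and_fit(tab, labels, n_trials=4, seed=33)
        top5 = set(tsboost.feature_importance(res).index[:5])
        peaky = {"fft_coefficient", "ratio_beyond_r_sigma", "autocorrelation",
                 "spkt_welch_density", "number_peaks", "agg_autocorrelation",
                 "cwt_coefficients", "energy_ratio_by_chunks", "c3",
                 "cid_ce", "mean_abs_change", "abs_energy",
                 "root_mean_square", "standard_deviation", "variance"}
        assert top5 & peaky, f"no beat-structure group in top 5: {top5}"
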