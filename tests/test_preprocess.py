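import numpy as np
import pandas as pd
import pytest

from icufair import preprocess, synthetic
from icufair.preprocess import StayRecord


def _stay(sid="s1", age=50.0, order=1, dur=48.0):
    return StayRecord(sid, f"p_{sid}", age, order, dur)


class TestSelectCohort:
    def test_age_below_threshold_excluded(self):
        assert preprocess.select_cohort([_stay(age=14.9)]) == []
        assert len(preprocess.select_cohort([_stay(age=15.0)])) == 1

    def test_duration_bounds_inclusive(self):
        assert preprocess.select_cohort([_stay(dur=11.0)]) == []
        assert len(preprocess.select_cohort([_stay(dur=12.0)])) == 1
        assert preprocess.select_cohort([_stay(dur=241.0)]) == []

    def test_only_first_stay_kept(self):
        assert preprocess.select_cohort([_stay(order=2)]) == []

    def test_order_preserved(self):
        stays = [_stay("s2"), _stay("s1")]
        assert [s.stay_id for s in preprocess.select_cohort(stays)] == ["s2", "s1"]


class TestCleanEvents:
    def test_numeric_duplicates_averaged(self, toy_events, tiny_spec):
        out = preprocess.clean_events(toy_events, tiny_spec)
        v = out.loc[(out.stay_id == "s1") & (out.feature_id == "temp_000") & (out.time_hours == 0.2), "value"]
        assert v.item() == 5.0

    def test_range_token_becomes_midpoint(self, toy_events, tiny_spec):
        out = preprocess.clean_events(toy_events, tiny_spec)
        v = out.loc[(out.stay_id == "s1") & (out.time_hours == 0.7), "value"]
        assert v.item() == 3.0

    def test_categorical_duplicates_take_first(self):
        spec = preprocess.FeatureSpec([preprocess.FeatureDef("cat", "temporal", kind="categorical")])
        events = pd.DataFrame(
            {"stay_id": ["s", "s"], "feature_id": ["cat", "cat"], "time_hours": [0.0, 0.0], "value": ["A", "B"]}
        )
        out = preprocess.clean_events(events, spec)
        assert out["value"].item() == "A"

    def test_unknown_feature_raises(self, toy_events):
        spec = preprocess.default_spec({"temporal": 1, "demographic": 0, "admission": 0, "comorbidity": 0})
        with pytest.raises(preprocess.SpecError):
            preprocess.clean_events(toy_events, spec)

    def test_unit_conversion_applied(self):
        spec = preprocess.FeatureSpec(
            [preprocess.FeatureDef("temp_000", "temporal", unit_factors={"mg": 0.001})]
        )
        events = pd.DataFrame(
            {"stay_id": ["s"], "feature_id": ["temp_000"], "time_hours": [0.0], "value": [500], "unit": ["mg"]}
        )
        assert preprocess.clean_events(events, spec)["value"].item() == 0.5

    def test_idempotent(self, toy_events, tiny_spec):
        once = preprocess.clean_events(toy_events, tiny_spec)
        twice = preprocess.clean_events(once, tiny_spec)
        pd.testing.assert_frame_equal(once, twice)


class TestFilterStays:
    def _events(self, times, sid="s1", fid="temp_000"):
        return pd.DataFrame(
            {"stay_id": sid, "feature_id": fid, "time_hours": list(times), "value": 1.0}
        )

    def test_short_coverage_excluded(self):
        ev = self._events([0.0, 23.0])
        assert preprocess.filter_stays(ev, [_stay()]) == []

    def test_exact_24h_included(self):
        ev = self._events([0.0, 24.0])
        assert len(preprocess.filter_stays(ev, [_stay()])) == 1

    def test_over_240h_excluded(self):
        ev = self._events([0.0, 241.0])
        assert preprocess.filter_stays(ev, [_stay()]) == []

    def test_anchor_ignores_events_before_lookback(self):
        # events at -7h and -5h: the anchor is -5h (first record within 6h
        # before admission), so the span to +18h is 23h -- too short.  Were
        # the -7h event anchoring, the span would be 25h and the stay kept.
        ev = self._events([-7.0, -5.0, 18.0])
        assert preprocess.filter_stays(ev, [_stay()]) == []

    def test_anchor_is_first_event_in_window(self):
        ev = self._events([-7.0, -5.0, 19.5])
        # anchor -5h, span 24.5h -> kept at the default 24h minimum coverage
        assert len(preprocess.filter_stays(ev, [_stay()])) == 1


class TestBuildMatrix:
    def test_hourly_binning_averages(self, tiny_spec):
        ev = pd.DataFrame(
            {
                "stay_id": ["s1"] * 2,
                "feature_id": ["temp_000"] * 2,
                "time_hours": [0.2, 0.7],
                "value": [4.0, 6.0],
            }
        )
        m = preprocess.build_matrix(ev, ["s1"], tiny_spec, t_hours=24)
        assert m.values[0, 0, 0] == 5.0
        assert np.isnan(m.values[0, 1:, 0]).all()

    def test_events_beyond_window_dropped(self, tiny_spec):
        ev = pd.DataFrame(
            {
                "stay_id": ["s1"] * 2,
                "feature_id": ["temp_000"] * 2,
                "time_hours": [0.0, 24.5],
                "value": [1.0, 99.0],
            }
        )
        m = preprocess.build_matrix(ev, ["s1"], tiny_spec, t_hours=24)
        assert not (m.values == 99.0).any()

    def test_default_spec_shape(self):
        spec = preprocess.default_spec()
        ev = pd.DataFrame(
            {"stay_id": ["s1"], "feature_id": ["temp_000"], "time_hours": [0.0], "value": [1.0]}
        )
        m = preprocess.build_matrix(ev, ["s1"], spec, t_hours=24)
        assert m.shape == (1, 24, 164)

    def test_static_features_broadcast(self):
        spec = preprocess.default_spec({"temporal": 1, "demographic": 1, "admission": 0, "comorbidity": 0})
        ev = pd.DataFrame(
            {
                "stay_id": ["s1", "s1"],
                "feature_id": ["temp_000", "age"],
                "time_hours": [0.0, 0.0],
                "value": [1.0, 63.0],
            }
        )
        m = preprocess.build_matrix(ev, ["s1"], spec, t_hours=24)
        assert (m.values[0, :, 1] == 63.0).all()

    def test_conservation_against_brute_force(self):
        # every non-missing cell equals the mean of the input events in its bin
        rng = np.random.default_rng(0)
        n_ev = 300
        ev = pd.DataFrame(
            {
                "stay_id": rng.choice(["s1", "s2"], n_ev),
                "feature_id": rng.choice(["temp_000", "temp_001"], n_ev),
                "time_hours": rng.uniform(-2, 26, n_ev),
                "value": rng.normal(size=n_ev),
            }
        )
        spec = preprocess.default_spec(
            {"temporal": 2, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=()
        )
        m = preprocess.build_matrix(ev, ["s1", "s2"], spec, t_hours=24)
        anchors = m.anchors
        for si, sid in enumerate(["s1", "s2"]):
            for fi, fid in enumerate(["temp_000", "temp_001"]):
                sub = ev[(ev.stay_id == sid) & (ev.feature_id == fid)]
                for h in range(24):
                    lo = anchors[sid] + h
                    vals = sub[(sub.time_hours >= lo) & (sub.time_hours < lo + 1)]["value"]
                    cell = m.values[si, h, fi]
                    if len(vals):
                        assert np.isclose(cell, vals.mean())
                    else:
                        assert np.isnan(cell)


class TestImpute:
    def _matrix(self, series, train_mean=2.5):
        spec = preprocess.default_spec(
            {"temporal": 1, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=()
        )
        values = np.array(series, dtype=float)[None, :, None]
        m = preprocess.FeatureMatrix(values, ["s1"], spec, {"s1": 0.0})
        return preprocess.impute(m, np.array([train_mean]))

    def test_forward_backward_fill(self):
        out = self._matrix([np.nan, 5.0, np.nan])
        assert out.values[0, :, 0].tolist() == [5.0, 5.0, 5.0]

    def test_all_missing_uses_train_mean(self):
        out = self._matrix([np.nan] * 24)
        assert (out.values == 2.5).all()

    def test_no_missing_is_identity_and_idempotent(self):
        series = [1.0, 2.0, 3.0]
        out = self._matrix(series)
        assert out.values[0, :, 0].tolist() == series
        again = preprocess.impute(out, np.array([2.5]))
        assert np.array_equal(again.values, out.values)

    def test_missing_train_means_raises(self):
        spec = preprocess.default_spec(
            {"temporal": 2, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=()
        )
        m = preprocess.FeatureMatrix(np.zeros((1, 3, 2)), ["s1"], spec, {"s1": 0.0})
        with pytest.raises(preprocess.SpecError):
            preprocess.impute(m, np.zeros(1))


class TestSummarizeTabular:
    def test_min_max_mean_columns(self):
        spec = preprocess.default_spec(
            {"temporal": 1, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=()
        )
        values = np.arange(1.0, 25.0)[None, :, None]
        m = preprocess.FeatureMatrix(values, ["s1"], spec, {"s1": 0.0})
        tab = preprocess.summarize_tabular(m)
        assert tab.columns == [("temp_000", "min"), ("temp_000", "max"), ("temp_000", "mean")]
        assert tab.values[0].tolist() == [1.0, 24.0, 12.5]

    def test_sum_flag_adds_column(self):
        spec = preprocess.default_spec(
            {"temporal": 1, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=("temp_000",)
        )
        values = np.zeros((1, 24, 1))
        values[0, :3, 0] = [1.0, 2.0, 3.0]
        m = preprocess.FeatureMatrix(values, ["s1"], spec, {"s1": 0.0})
        tab = preprocess.summarize_tabular(m)
        assert tab.values[0, tab.column_index("temp_000", "sum")] == 6.0

    def test_default_spec_gives_409_columns(self):
        spec = preprocess.default_spec()
        m = preprocess.FeatureMatrix(np.zeros((2, 24, 164)), ["s1", "s2"], spec, {})
        tab = preprocess.summarize_tabular(m)
        assert tab.values.shape == (2, 409)


class TestPipelineRoundTrip:
    def test_latent_array_recovered_without_missingness(self):
        cfg = synthetic.SimConfig(
            n_stays=20,
            feature_counts={"temporal": 3, "demographic": 2, "admission": 1, "comorbidity": 1},
            planted_features=[synthetic.PlantedFeature("temp_000", 2.0)],
            missing_rate=0.0,
            seed=2,
        )
        c = synthetic.generate_cohort(cfg)
        spec = preprocess.default_spec(
            {"temporal": 3, "demographic": 2, "admission": 1, "comorbidity": 1}, sum_features=()
        )
        clean = preprocess.clean_events(c.events, spec)
        m = preprocess.build_matrix(clean, list(c.labels.index), spec, t_hours=cfg.t_hours)
        im = preprocess.impute(m, preprocess.train_feature_means(m, range(20)))
        assert np.allclose(im.values, c.latent)

    def test_paper_shaped_pipeline_shapes(self, paper_shaped_pipeline):
        matrix, tabular = paper_shaped_pipeline
        assert matrix.shape == (5, 24, 164)
        assert tabular.values.shape == (5, 409)


@pytest.fixture(scope="module")
def paper_shaped_pipeline():
    cfg = synthetic.SimConfig(n_stays=5, missing_rate=0.05, seed=13)
    c = synthetic.generate_cohort(cfg)
    spec = preprocess.default_spec()
    clean = preprocess.clean_events(c.events, spec)
    m = preprocess.build_matrix(clean, list(c.labels.index), spec, t_hours=24)
    im = preprocess.impute(m, preprocess.train_feature_means(m, range(5)))
    return im, preprocess.summarize_tabular(im)
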