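"""Window features, the combined index, and the streaming classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afdetect import (
    ClassifierParams,
    RhythmClass,
    RRSeries,
    WARMUP_LABEL,
    classify_beat,
    classify_stream,
    heterogeneity_index,
    randomness_index,
    variability_index,
)
from afdetect.core import (
    CLASS_COLORS,
    InvalidSeriesError,
    InvalidWindowError,
    stream_features,
)
from afdetect.estimators import HeterogeneityBeatClassifier

rr_windows = st.lists(
    st.floats(min_value=240.0, max_value=3000.0), min_size=8, max_size=64
)


class TestRRSeries:
    def test_timestamps_are_cumulative_and_increasing(self):
        s = RRSeries([800.0, 700.0, 900.0])
        assert np.allclose(s.t_ms, [800.0, 1500.0, 2400.0])
        assert np.all(np.diff(s.t_ms) > 0)

    @pytest.mark.parametrize("bad", [[], [0.0], [-5.0, 800.0], [800.0, np.nan]])
    def test_invalid_series_rejected(self, bad):
        with pytest.raises(InvalidSeriesError):
            RRSeries(bad)

    def test_out_of_bounds_intervals_flagged_but_kept(self):
        s = RRSeries([800.0, 100.0, 3500.0, 900.0])
        assert list(s.flagged) == [False, True, True, False]
        assert len(s) == 4
        assert len(s.dropped()) == 2


class TestVariabilityIndex:
    def test_constant_window_is_zero(self):
        assert variability_index([800.0] * 32) == 0.0

    def test_hand_computed_example(self):
        # RMSSD = sqrt((0 + 800^2)/2) = 565.685, mean = 1066.667
        assert variability_index([800.0, 800.0, 1600.0]) == pytest.approx(
            0.53033, abs=1e-5
        )

    @given(rr_windows, st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, w, k):
        w = np.asarray(w)
        assert variability_index(k * w) == pytest.approx(
            variability_index(w), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [[800.0], [800.0, -1.0, 900.0]])
    def test_invalid_windows_rejected(self, bad):
        with pytest.raises(InvalidWindowError):
            variability_index(bad)


class TestRandomnessIndex:
    def test_deterministic_patterns_score_zero(self):
        assert randomness_index([800.0] * 32) == 0.0
        assert randomness_index([600.0, 900.0] * 16) == 0.0

    def test_iid_uniform_symbols_approach_one(self):
        # symbol steps of +-100/0 ms around a 2000 ms base are i.i.d. uniform
        # over the three symbols; plug-in entropy rate should approach 1
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(1000):
            steps = (rng.integers(0, 3, 512) - 1) * 100.0
            rr = np.concatenate([[0.0], np.cumsum(steps)])
            rr = rr - rr.min() + 2000.0
            vals.append(randomness_index(rr[:513]))
        assert abs(float(np.mean(vals)) - 1.0) < 0.05

    def test_short_window_rejected(self):
        with pytest.raises(InvalidWindowError):
            randomness_index([800.0] * 7)

    @given(rr_windows)
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, w):
        assert 0.0 <= randomness_index(w) <= 1.0


class TestHeterogeneityIndex:
    def test_lower_bound(self, params):
        assert heterogeneity_index(0.0, 0.0, params).index == 0.0

    def test_upper_limit(self, params):
        f = heterogeneity_index(1e12, 1.0, params)
        assert f.index == pytest.approx(1.0, abs=1e-9)

    def test_weighted_combination_arithmetic(self, params):
        # v = 0.4 requires v_raw = v_scale * v / (1 - v) = 0.1 * 2/3
        v_raw = params.v_scale * 0.4 / 0.6
        f = heterogeneity_index(v_raw, 0.8, params)
        assert f.v == pytest.approx(0.4)
        assert f.index == pytest.approx(0.6)

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_components(self, a, b, r1, r2):
        params = ClassifierParams()
        lo = heterogeneity_index(min(a, b), min(r1, r2), params)
        hi = heterogeneity_index(max(a, b), max(r1, r2), params)
        assert hi.index >= lo.index
        assert 0.0 <= lo.index <= 1.0 and 0.0 <= hi.index <= 1.0


class TestClassifyBeat:
    def test_af_boundary_is_inclusive(self, params):
        assert classify_beat(params.theta_af, params) is RhythmClass.PROBABLE_AF

    def test_zero_index_is_normal(self, params):
        assert classify_beat(0.0, params) is RhythmClass.NORMAL

    def test_middle_band_including_lower_tie(self, params):
        assert (
            classify_beat(params.theta_sr, params)
            is RhythmClass.UNCLASSIFIED_NON_AF
        )
        mid = (params.theta_sr + params.theta_af) / 2
        assert classify_beat(mid, params) is RhythmClass.UNCLASSIFIED_NON_AF

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_label_order(self, i1, i2):
        params = ClassifierParams()
        order = {
            RhythmClass.NORMAL: 0,
            RhythmClass.UNCLASSIFIED_NON_AF: 1,
            RhythmClass.PROBABLE_AF: 2,
        }
        lo, hi = sorted((i1, i2))
        assert order[classify_beat(hi, params)] >= order[classify_beat(lo, params)]

    def test_class_color_mapping(self):
        assert CLASS_COLORS[RhythmClass.PROBABLE_AF] == "red"
        assert CLASS_COLORS[RhythmClass.NORMAL] == "blue"
        assert CLASS_COLORS[RhythmClass.UNCLASSIFIED_NON_AF] == "yellow"


class TestClassifyStream:
    def test_warmup_only_for_short_series(self, params):
        labeled = classify_stream([800.0] * (params.window_n - 1), params)
        assert len(labeled) == params.window_n - 1
        assert all(b.label == WARMUP_LABEL for b in labeled)

    def test_warmup_prefix_then_labels(self, params):
        n = params.window_n + 10
        labeled = classify_stream([800.0] * n, params)
        assert len(labeled) == n
        warm = [b for b in labeled if b.label == WARMUP_LABEL]
        assert len(warm) == params.window_n - 1
        assert all(b.index_value is None for b in warm)
        for b in labeled[params.window_n - 1 :]:
            assert b.label == RhythmClass.NORMAL.value
            assert b.index_value == 0.0

    def test_deterministic(self, params):
        rng = np.random.default_rng(11)
        rr = rng.uniform(400, 1200, 200)
        a = classify_stream(rr, params)
        b = classify_stream(rr, params)
        assert a == b

    def test_empty_series_rejected(self, params):
        with pytest.raises(InvalidSeriesError):
            classify_stream([], params)

    def test_causal_prefix_consistency(self, params):
        # labels over a prefix equal the prefix of labels over the full series
        rng = np.random.default_rng(5)
        rr = rng.uniform(400, 1200, 120)
        full = classify_stream(rr, params)
        prefix = classify_stream(rr[:80], params)
        assert full[:80] == prefix

    def test_streaming_features_match_bruteforce_windows(self, params):
        rng = np.random.default_rng(42)
        rr = rng.uniform(300, 1800, 1000 + params.window_n - 1)
        v_raw, v, rn, idx = stream_features(rr, params)
        m = params.window_n
        for i in range(m - 1, rr.size):
            w = rr[i - m + 1 : i + 1]
            exp_v = variability_index(w)
            exp_rn = randomness_index(w, params.delta_ms)
            f = heterogeneity_index(exp_v, exp_rn, params)
            assert v_raw[i] == pytest.approx(exp_v, rel=1e-12)
            assert rn[i] == pytest.approx(exp_rn, rel=1e-12, abs=1e-12)
            assert idx[i] == pytest.approx(f.index, rel=1e-12, abs=1e-12)

    def test_scale_invariance_with_scaled_delta(self, params):
        rng = np.random.default_rng(3)
        rr = rng.uniform(400, 1200, 300)
        base = [b.label for b in classify_stream(rr, params)]
        k = 1.7
        scaled_params = ClassifierParams(
            delta_ms=params.delta_ms * k,
        )
        scaled = [b.label for b in classify_stream(k * rr, scaled_params)]
        assert base == scaled

    def test_alternating_series_never_probable_af(self, params):
        # randomness is exactly 0, so index <= w_v < theta_af
        rr = np.array([440.0, 880.0] * 200)
        labels = {b.label for b in classify_stream(rr, params)} - {WARMUP_LABEL}
        assert RhythmClass.PROBABLE_AF.value not in labels


class TestEstimatorInterface:
    def test_params_roundtrip_and_clone(self):
        from sklearn.base import clone

        clf = HeterogeneityBeatClassifier(theta_af=0.6)
        assert clone(clf).get_params()["theta_af"] == 0.6
        clf.set_params(window_n=16)
        assert clf.fit().params_.window_n == 16

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            HeterogeneityBeatClassifier().predict([800.0] * 40)

    def test_invalid_parameters_rejected_at_fit(self):
        with pytest.raises(ValueError):
            HeterogeneityBeatClassifier(window_n=4).fit()
        with pytest.raises(ValueError):
            HeterogeneityBeatClassifier(theta_af=0.2, theta_sr=0.3).fit()
        with pytest.raises(ValueError):
            HeterogeneityBeatClassifier(w_v=0.8, w_r=0.4).fit()

    def test_transform_shape_and_warmup_nans(self, params):
        clf = HeterogeneityBeatClassifier().fit()
        F = clf.transform(np.full(50, 800.0))
        assert F.shape == (50, 4)
        assert np.isnan(F[: params.window_n - 1]).all()
        assert np.isfinite(F[params.window_n - 1 :]).all()
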