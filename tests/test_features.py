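"""Windowing arithmetic, feature definitions, normalization and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import skidetect as sk
from skidetect.features import CHANNELS, GRID_SLIDING_RATES, GRID_WINDOW_SIZES
from skidetect.orientation import WorldFrameRecording


def _world(duration=60.0, rate=50.0, fill=0.0):
    n = int(duration * rate)
    accel = np.full((n, 3), fill)
    return WorldFrameRecording(np.arange(n) / rate, accel, np.zeros((n, 3)), rate)


def _window(values_by_channel, rate=50.0):
    first = next(iter(values_by_channel.values()))
    samples = {ch: np.asarray(values_by_channel.get(ch, np.zeros_like(first)), float)
               for ch in CHANNELS}
    n = len(first)
    return sk.Window(0.0, n / rate, samples, rate)


class TestSegmentWindows:
    def test_disjoint_count(self):
        windows = sk.segment_windows(_world(60.0), sk.WindowConfig(6.0, 1.0))
        assert len(windows) == 10
        assert windows[0].start == 0.0 and windows[0].end == 6.0
        assert windows[-1].start == 54.0

    def test_half_overlap_count(self):
        windows = sk.segment_windows(_world(60.0), sk.WindowConfig(6.0, 0.5))
        assert len(windows) == 19
        assert windows[1].start == pytest.approx(3.0)

    def test_too_short_recording(self):
        with pytest.warns(UserWarning, match="shorter than one window"):
            assert sk.segment_windows(_world(5.0), sk.WindowConfig(6.0, 1.0)) == []

    @settings(max_examples=60, deadline=None)
    @given(
        ws=st.sampled_from(GRID_WINDOW_SIZES),
        rate=st.sampled_from(GRID_SLIDING_RATES),
        duration=st.integers(min_value=10, max_value=120),
    )
    def test_count_matches_closed_form(self, ws, rate, duration):
        windows = sk.segment_windows(_world(float(duration)), sk.WindowConfig(float(ws), rate))
        n = len(_world(float(duration)).timestamps)
        true_duration = n / 50.0  # n samples at 50 Hz span n/50 seconds
        step = ws * rate
        expected = max(int(np.floor((true_duration - ws) / step + 1e-9)) + 1, 0)
        if expected == 0:
            assert windows == []
        else:
            assert len(windows) == expected
            for w in windows:
                assert w.end - w.start == pytest.approx(ws)
                assert len(w) == pytest.approx(ws * 50.0, abs=1)


class TestAutocorrelate:
    def test_periodic_signal_peaks_at_period(self):
        # biased-estimator oracle: M periods of a sine give an autocorrelation
        # ~(1 - k/N) cos(2 pi k / P); at the period lag that is 1 - 1/M
        rate, freq, periods = 50.0, 1.0, 4
        n = int(periods * rate / freq)
        t = np.arange(n) / rate
        ac = sk.autocorrelate(np.sin(2 * np.pi * freq * t))
        period_lag = int(rate / freq)
        assert ac[period_lag] >= 0.7
        expected = (1 - period_lag / n) * np.cos(2 * np.pi * freq * period_lag / rate)
        assert ac[period_lag] == pytest.approx(expected, abs=0.05)

    def test_white_noise_decorrelates(self, rng):
        ac = sk.autocorrelate(rng.normal(size=5000))
        assert np.max(np.abs(ac[1:])) < 0.1

    def test_lag_zero_is_one(self, rng):
        assert sk.autocorrelate(rng.normal(size=100))[0] == 1.0

    def test_constant_input_convention(self):
        ac = sk.autocorrelate(np.full(50, 3.0))
        assert ac[0] == 1.0
        np.testing.assert_array_equal(ac[1:], 0.0)


class TestCrossings:
    def test_constant_signal(self):
        assert sk.crossings(np.full(100, 2.0), 5.0) == 0

    def test_two_period_sine_about_mean(self):
        # enumerate sign changes: 2 periods starting at an extremum cross
        # the mean at T/4, 3T/4, 5T/4, 7T/4 - 4 times, endpoints excluded
        t = np.arange(200) / 100.0
        x = np.cos(2 * np.pi * t)  # exactly 2 periods
        assert sk.crossings(x, float(x.mean())) == 4

    def test_monotone_ramp(self):
        assert sk.crossings(np.linspace(0, 1, 100), 0.5) == 1

    def test_sample_at_level_inherits_previous_sign(self):
        # touches the level without crossing: no count
        x = np.array([1.0, 0.5, 0.0, 0.5, 1.0])
        assert sk.crossings(x, 0.0) == 0


class TestWindowFeatures:
    def test_constant_window(self):
        w = _window({"acc_x": np.full(100, 4.0)})
        f = sk.window_features(w)
        assert f["acc_x__raw__mean"] == 4.0
        assert f["acc_x__raw__sd"] == 0.0
        assert f["acc_x__raw__rms"] == 4.0
        assert f["acc_x__raw__variance"] == 0.0
        assert f["acc_x__raw__mad"] == 0.0
        assert f["acc_x__raw__mean_crossings"] == 0

    def test_energy_of_unit_sine(self):
        t = np.arange(200) / 50.0  # 4 s, full periods of 1 Hz
        w = _window({"acc_x": np.sin(2 * np.pi * t)})
        f = sk.window_features(w)
        assert f["acc_x__raw__energy"] == pytest.approx(0.5, abs=1e-12)

    def test_sma_definition(self):
        w = _window(
            {"acc_x": np.full(50, -1.0), "acc_y": np.full(50, 2.0), "acc_z": np.full(50, -3.0)}
        )
        assert sk.window_features(w)["sma"] == pytest.approx(6.0)

    def test_translation_covariance(self, rng):
        x = rng.normal(size=200)
        f0 = sk.window_features(_window({"acc_x": x}))
        f1 = sk.window_features(_window({"acc_x": x + 10.0}))
        for name in ("mean", "min", "max", "median"):
            assert f1[f"acc_x__raw__{name}"] == pytest.approx(f0[f"acc_x__raw__{name}"] + 10.0)
        for name in ("sd", "variance", "mad"):
            assert f1[f"acc_x__raw__{name}"] == pytest.approx(f0[f"acc_x__raw__{name}"], abs=1e-9)
        for name in ("mean_crossings", "p25_crossings", "p50_crossings", "p75_crossings"):
            assert f1[f"acc_x__raw__{name}"] == f0[f"acc_x__raw__{name}"]

    def test_sign_flip_invariance_of_even_ac_features(self, rng):
        x = rng.normal(size=200)
        f0 = sk.window_features(_window({"acc_x": x}))
        f1 = sk.window_features(_window({"acc_x": -x}))
        for name in ("energy", "sd"):
            assert f1[f"acc_x__ac__{name}"] == pytest.approx(f0[f"acc_x__ac__{name}"], abs=1e-12)

    def test_empty_window_rejected(self):
        w = sk.Window(0.0, 1.0, {ch: np.array([]) for ch in CHANNELS}, 50.0)
        with pytest.raises(ValueError):
            sk.window_features(w)


class TestNormalizeMinmax:
    @staticmethod
    def _fm(df):
        n = len(df)
        return sk.FeatureMatrix(df, np.arange(n, dtype=float), np.arange(n, dtype=float) + 1, "raw")

    def test_closed_form(self):
        out = sk.normalize_minmax(self._fm(pd.DataFrame({"a": [2.0, 4.0, 6.0]})))
        np.testing.assert_allclose(out.values["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = sk.normalize_minmax(self._fm(pd.DataFrame({"a": [3.0, 3.0, 3.0]})))
        np.testing.assert_array_equal(out.values["a"], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            sk.normalize_minmax(self._fm(pd.DataFrame({"a": [1.0]})))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=3),
            min_size=2,
            max_size=30,
        )
    )
    def test_bounds_and_attainment(self, rows):
        df = pd.DataFrame(rows, columns=["a", "b", "c"])
        out = sk.normalize_minmax(self._fm(df)).values
        assert out.to_numpy().min() >= -1.0 - 1e-12
        assert out.to_numpy().max() <= 1.0 + 1e-12
        for col in out:
            lo, hi = df[col].min(), df[col].max()
            span = hi - lo
            if span > 1e-9 * max(abs(lo), abs(hi), 1.0):  # numerically non-constant
                assert out[col].min() == pytest.approx(-1.0)
                assert out[col].max() == pytest.approx(1.0)


class TestPCAReduce:
    @staticmethod
    def _fm(arr):
        n = len(arr)
        return sk.FeatureMatrix(
            pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])]),
            np.arange(n, dtype=float),
            np.arange(n, dtype=float) + 1,
            "NFS",
        )

    def test_two_directions_of_variance(self, rng):
        # constructed covariance oracle: variance lives in exactly 2
        # orthogonal directions embedded in 5 dimensions
        scores = rng.normal(size=(200, 2)) * [5.0, 3.0]
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        X = scores @ basis.T
        out = sk.pca_reduce(self._fm(X), variance_kept=0.95)
        assert out.values.shape[1] == 2
        assert out.feature_set == "PCA"

    def test_full_variance_reconstructs(self, rng):
        X = rng.normal(size=(50, 4))
        out = sk.pca_reduce(self._fm(X), variance_kept=1.0)
        # keeping all variance preserves total variance exactly
        assert out.values.to_numpy().var(axis=0).sum() == pytest.approx(
            X.var(axis=0).sum()
        )

    def test_component_variances_non_increasing(self, rng):
        X = rng.normal(size=(100, 6)) * np.arange(1, 7)
        out = sk.pca_reduce(self._fm(X), variance_kept=0.999)
        variances = out.values.to_numpy().var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_invalid_variance_kept(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            sk.pca_reduce(self._fm(X), variance_kept=0.0)
        with pytest.raises(ValueError):
            sk.pca_reduce(self._fm(X), variance_kept=1.5)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(60, 5))
        a = sk.pca_reduce(self._fm(X), 0.95).values.to_numpy()
        b = sk.pca_reduce(self._fm(X.copy()), 0.95).values.to_numpy()
        np.testing.assert_array_equal(a, b)


class TestSkiingSignature:
    def test_ac_energy_higher_in_skiing_windows(self, two_run_session, two_run_result):
        # the premise of the autocorrelation features: periodic turn patterns
        # keep high autocorrelation, idle noise does not
        _, _, truth = two_run_session
        filtered = two_run_result.world
        windows = sk.segment_windows(filtered, sk.WindowConfig(8.0, 1.0))
        raw = sk.extract_features(windows)
        ski_spans = [(s.start, s.end) for s in truth if s.label == sk.SKIING]
        in_run = np.array(
            [any(s <= w.start and w.end <= e for s, e in ski_spans) for w in windows]
        )
        fully_idle = np.array(
            [all(w.end <= s or w.start >= e for s, e in ski_spans) for w in windows]
        )
        ac_energy = raw.values[[f"{ch}__ac__energy" for ch in ("acc_x", "acc_y", "acc_z")]].sum(axis=1)
        assert ac_energy[in_run].mean() > ac_energy[fully_idle].mean()
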