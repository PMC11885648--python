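import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridephysio.eeg import (
    EpochSet,
    Recording,
    arousal,
    band_power,
    bandpass,
    epoch_features,
    faa,
    make_epochs,
    reject_amplitude,
    remove_outliers,
    segment_means,
)
from ridephysio.segmentation import Interval, RideLayout, eeg_segments


def tone(freq: float, amp: float, duration: float, rate: float = 200.0) -> np.ndarray:
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def recording_from(x: np.ndarray, rate: float = 200.0, channels=("F3",)) -> Recording:
    vals = np.tile(x, (len(channels), 1))
    return Recording(values=vals, rate=rate, channel_names=channels)


class TestBandpass:
    def test_stopband_2hz(self):
        rec = recording_from(tone(2.0, 1.0, 20.0))
        out = bandpass(rec)
        assert np.abs(out.values).max() < 0.1

    def test_passband_10hz(self):
        rec = recording_from(tone(10.0, 1.0, 20.0))
        out = bandpass(rec)
        mid = out.values[0, 1000:-1000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.1)

    def test_zero_in_zero_out(self):
        rec = recording_from(np.zeros(4000))
        assert np.all(bandpass(rec).values == 0)

    def test_octave_attenuation(self):
        # one octave below the 7 Hz edge: 3.5 Hz, >= 20 dB down (zero-phase
        # doubles the single-pass attenuation)
        rec = recording_from(tone(3.5, 1.0, 30.0))
        out = bandpass(rec)
        assert np.abs(out.values[0, 1000:-1000]).max() < 0.1

    def test_rate_guard(self):
        rec = recording_from(np.zeros(1000), rate=90.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec)


class TestMakeEpochs:
    def test_180s_gives_179(self):
        rec = recording_from(np.zeros(36000))
        assert make_epochs(rec).n_epochs == 179

    def test_exact_length_single_epoch(self):
        rec = recording_from(np.zeros(400))
        assert make_epochs(rec).n_epochs == 1

    def test_partial_tail_dropped(self):
        rec = recording_from(np.zeros(500))  # 2.5 s
        assert make_epochs(rec).n_epochs == 1

    def test_too_short_errors(self):
        rec = recording_from(np.zeros(399))
        with pytest.raises(ValueError):
            make_epochs(rec)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(400, 20000))
    def test_property_count_formula(self, n):
        rec = recording_from(np.zeros(n))
        assert make_epochs(rec).n_epochs == (n - 400) // 200 + 1


class TestRejectAmplitude:
    def _epochs(self, peak: float) -> EpochSet:
        x = np.zeros(1000)
        x[500] = peak
        return make_epochs(recording_from(x))

    def test_99uv_retained(self):
        ep = reject_amplitude(self._epochs(99.0))
        assert ep.retained.all()

    def test_200uv_rejected(self):
        ep = reject_amplitude(self._epochs(200.0))
        assert not ep.retained.all()

    def test_clean_mask_all_true(self):
        ep = reject_amplitude(make_epochs(recording_from(np.zeros(1000))))
        assert ep.retained.all()

    def test_idempotent(self):
        ep = reject_amplitude(self._epochs(200.0))
        again = reject_amplitude(ep)
        np.testing.assert_array_equal(ep.retained, again.retained)

    def test_monotone_adding_spike_never_readmits(self):
        ep1 = reject_amplitude(self._epochs(200.0))
        x = np.zeros(1000)
        x[500] = 200.0
        x[100] = 300.0
        ep2 = reject_amplitude(make_epochs(recording_from(x)))
        assert np.all(ep2.retained <= ep1.retained)


class TestBandPower:
    def test_alpha_tone_power(self):
        x = tone(10.0, 2.0, 2.0)
        assert band_power(x, 200, "alpha") == pytest.approx(2.0, rel=0.15)

    def test_out_of_band_near_zero(self):
        x = tone(10.0, 2.0, 2.0)
        assert band_power(x, 200, "gamma") < 0.01

    def test_white_noise_power_scaling(self, rng):
        x = rng.standard_normal(4000)
        p1 = band_power(x, 200, "beta")
        p2 = band_power(2 * x, 200, "beta")
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_band_guard(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(400), 200, (0.0, 50.0))


class TestIndices:
    def test_faa_log_ratio_10(self):
        assert faa(0.2, 0.02) == pytest.approx(1.0)

    def test_faa_equal_powers(self):
        assert faa(1.5, 1.5) == 0.0

    def test_faa_antisymmetry(self):
        assert faa(0.3, 0.07) == pytest.approx(-faa(0.07, 0.3))

    def test_faa_nonpositive_power_nan(self):
        assert np.isnan(faa(0.0, 1.0))

    def test_arousal_definition(self):
        # mean alpha 2, mean beta 3, mean gamma 1 -> (3+1)/2 = 2
        assert arousal(2, 2, 3, 3, 1, 1) == pytest.approx(2.0)

    def test_arousal_scale_invariance(self):
        a = arousal(2, 2, 3, 3, 1, 1)
        b = arousal(20, 20, 30, 30, 10, 10)
        assert a == pytest.approx(b, abs=1e-12)

    def test_arousal_zero_numerator(self):
        assert arousal(1, 1, 0, 0, 0, 0) == 0.0

    def test_arousal_zero_alpha_nan(self):
        assert np.isnan(arousal(0, 0, 1, 1, 1, 1))

    @settings(max_examples=50, deadline=None)
    @given(
        p4=st.floats(1e-6, 1e6),
        p3=st.floats(1e-6, 1e6),
    )
    def test_property_faa_antisymmetric(self, p4, p3):
        assert faa(p4, p3) == pytest.approx(-faa(p3, p4), rel=1e-9, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(1e-3, 1e3),
        b=st.floats(0, 1e3),
        g=st.floats(0, 1e3),
        c=st.floats(1e-3, 1e3),
    )
    def test_property_arousal_scale_invariant(self, a, b, g, c):
        assert arousal(a, a, b, b, g, g) == pytest.approx(
            arousal(c * a, c * a, c * b, c * b, c * g, c * g), rel=1e-9, abs=1e-12
        )


class TestRemoveOutliers:
    def test_ten_zeros_one_ten_removed(self):
        # direct computation: mean 0.909, SD(ddof=1) 3.015 -> z = 3.015 >= 3
        x = np.array([0.0] * 10 + [10.0])
        keep = remove_outliers(x)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_constant_series_kept(self):
        assert remove_outliers(np.full(8, 2.5)).all()

    def test_idempotent(self):
        x = np.array([0.0] * 10 + [10.0])
        keep = remove_outliers(x)
        keep2 = remove_outliers(x[keep])
        assert keep2.all()  # single pass, no re-iteration

    def test_nan_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 1.5])
        assert not remove_outliers(x)[2]


class TestSegmentMeans:
    def _features(self, values, onsets):
        return pd.DataFrame(
            {
                "epoch_onset_s": onsets,
                "faa": values,
                "arousal": values,
                "retained": [True] * len(values),
            }
        )

    def test_constant_everywhere(self, layout180):
        segs = eeg_segments(layout180)
        onsets = np.arange(0.0, 179.0)
        feats = self._features(np.full(179, 0.7), onsets)
        out = segment_means(feats, segs, "faa")
        assert np.allclose(out["mean"], 0.7)
        assert list(out["tag"]) == ["smooth", "unexpected", "smooth", "unexpected"]

    def test_empty_segments_nan(self, layout180):
        segs = eeg_segments(layout180)
        feats = self._features([0.5, 0.6], [1.0, 2.0])  # only segment 1
        out = segment_means(feats, segs, "faa")
        assert np.isfinite(out["mean"].iloc[0])
        assert out["mean"].iloc[1:].isna().all()

    def test_planted_step_shifts_late_segments(self, layout180):
        segs = eeg_segments(layout180)
        onsets = np.arange(0.0, 179.0)
        values = np.where(onsets < 0.6 * 180, 0.0, 1.0)
        out = segment_means(self._features(values, onsets), segs, "faa")
        assert out["mean"].iloc[0] == pytest.approx(0.0)
        assert out["mean"].iloc[2] == pytest.approx(1.0)
        assert out["mean"].iloc[3] == pytest.approx(1.0)


def test_epoch_features_roundtrip_faa_sign(rng):
    # F4 alpha bigger than F3 -> positive mean FAA
    t = np.arange(4000) / 200.0
    alpha = np.sin(2 * np.pi * 10 * t)
    vals = np.vstack([alpha * 1.0, alpha * 3.0, alpha, alpha])
    rec = Recording(values=vals, rate=200.0, channel_names=("F3", "F4", "FPz", "Oz"))
    feats = epoch_features(make_epochs(rec))
    assert feats["faa"].mean() == pytest.approx(np.log10(9.0), abs=0.05)
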