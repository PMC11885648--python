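import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridephysio.eeg import bandpass, epoch_features, make_epochs, reject_amplitude
from ridephysio.oculomotor import detect_blinks, interpolate_gaps, velocity_filter
from ridephysio.pipeline import raw_to_trace
from ridephysio.segmentation import RideLayout
from ridephysio.stats import rm_anova
from ridephysio.synthetic import (
    CascadeSpec,
    CohortSpec,
    SyntheticEEGSpec,
    cascade_modulated_noise,
    gen_binomial_cascade,
    gen_cohort,
    gen_fgn,
    gen_gaze_trace,
    gen_synthetic_eeg,
)


class TestCascade:
    def test_uniform_p05(self):
        m = gen_binomial_cascade(CascadeSpec(p=0.5, depth=10))
        np.testing.assert_allclose(m, 2.0**-10)

    def test_depth3_enumeration(self):
        # oracle: all 2^3 products of factors drawn from {0.3, 0.7}
        m = gen_binomial_cascade(CascadeSpec(p=0.3, depth=3))
        products = sorted(
            a * b * c for a in (0.3, 0.7) for b in (0.3, 0.7) for c in (0.3, 0.7)
        )
        np.testing.assert_allclose(sorted(m), products)
        assert m.max() == pytest.approx(0.343)

    @pytest.mark.parametrize("p,depth", [(0.1, 5), (0.3, 12), (0.49, 8), (0.9, 10)])
    def test_conservation(self, p, depth):
        m = gen_binomial_cascade(CascadeSpec(p=p, depth=depth))
        assert m.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(m >= 0)
        assert m.size == 2**depth

    def test_depth_guard(self):
        with pytest.raises(ValueError, match="depth"):
            CascadeSpec(p=0.3, depth=25)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            CascadeSpec(p=1.0, depth=3)

    def test_randomized_is_permutation_and_seeded(self):
        a = gen_binomial_cascade(CascadeSpec(p=0.3, depth=6, seed=7, randomize=True))
        b = gen_binomial_cascade(CascadeSpec(p=0.3, depth=6, seed=7, randomize=True))
        c = gen_binomial_cascade(CascadeSpec(p=0.3, depth=6, seed=8, randomize=True))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        np.testing.assert_allclose(
            sorted(a), sorted(gen_binomial_cascade(CascadeSpec(p=0.3, depth=6)))
        )


class TestFGn:
    def test_white_noise_limit_h05(self):
        rs = [
            np.corrcoef(x[:-1], x[1:])[0, 1]
            for x in (gen_fgn(0.5, 4096, seed=s) for s in range(5))
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_lag1_autocorrelation_h07(self):
        # fGn autocovariance: rho(1) = 2^(2H-1) - 1
        rs = [
            np.corrcoef(x[:-1], x[1:])[0, 1]
            for x in (gen_fgn(0.7, 4096, seed=s) for s in range(10))
        ]
        assert np.mean(rs) == pytest.approx(2 ** (2 * 0.7 - 1) - 1, abs=0.05)

    def test_determinism(self):
        np.testing.assert_array_equal(gen_fgn(0.7, 512, seed=3), gen_fgn(0.7, 512, seed=3))

    def test_unit_variance_batch(self):
        v = np.mean([gen_fgn(0.7, 4096, seed=s).var() for s in range(20)])
        assert v == pytest.approx(1.0, rel=0.1)

    def test_zero_mean(self):
        assert abs(np.mean([gen_fgn(0.6, 4096, seed=s).mean() for s in range(10)])) < 0.1

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_fgn(1.2, 100)
        with pytest.raises(ValueError):
            gen_fgn(0.5, 0)


class TestSyntheticEEG:
    def test_faa_target_recovered_downstream(self):
        # batch-mean recovery within +/-0.05 at 60 s
        means = []
        for seed in range(5):
            rec = gen_synthetic_eeg(
                SyntheticEEGSpec(duration=60, faa_target=1.0, seed=seed)
            )
            feats = epoch_features(reject_amplitude(make_epochs(bandpass(rec))))
            means.append(feats.loc[feats.retained, "faa"].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_alpha_amp_ratio_gives_faa_1(self):
        amps = {
            "F3": {"alpha": 2.0},
            "F4": {"alpha": 2.0 * np.sqrt(10.0)},
        }
        rec = gen_synthetic_eeg(SyntheticEEGSpec(duration=60, band_amplitudes=amps, seed=0))
        feats = epoch_features(reject_amplitude(make_epochs(bandpass(rec))))
        assert feats.loc[feats.retained, "faa"].mean() == pytest.approx(1.0, abs=0.05)

    def test_artifact_epochs_rejected(self):
        rec = gen_synthetic_eeg(
            SyntheticEEGSpec(duration=60, artifact_epochs=[(10.0, 200.0)], seed=1)
        )
        ep = reject_amplitude(make_epochs(bandpass(rec)))
        rejected = set(ep.onsets[~ep.retained])
        # burst spans [10, 10.5): exactly the 2-s epochs overlapping it
        assert rejected == {9.0, 10.0}

    def test_pure_alpha_gives_zero_arousal(self):
        amps = {ch: {"beta": 0.0, "gamma": 0.0} for ch in ("F3", "F4", "FPz", "Oz")}
        rec = gen_synthetic_eeg(SyntheticEEGSpec(duration=30, band_amplitudes=amps, seed=2))
        feats = epoch_features(reject_amplitude(make_epochs(bandpass(rec))))
        assert feats.loc[feats.retained, "arousal"].mean() == pytest.approx(0.0, abs=0.02)

    def test_rate_guard(self):
        with pytest.raises(ValueError, match="rate"):
            SyntheticEEGSpec(duration=10, rate=90.0)

    def test_determinism(self):
        a = gen_synthetic_eeg(SyntheticEEGSpec(duration=5, seed=4)).values
        b = gen_synthetic_eeg(SyntheticEEGSpec(duration=5, seed=4)).values
        np.testing.assert_array_equal(a, b)


class TestGazeTrace:
    def _clean(self, raw):
        return interpolate_gaps(velocity_filter(raw_to_trace(raw)))

    def test_scheduled_blinks_detected(self):
        l, r = gen_gaze_trace(
            30, blink_schedule=[(5, 0.1), (12, 0.1), (20, 0.1)], seed=0
        )
        assert len(detect_blinks(self._clean(l), self._clean(r))) == 3

    def test_monocular_dropout_not_a_blink(self):
        l, r = gen_gaze_trace(
            30,
            blink_schedule=[(5, 0.1)],
            monocular_dropouts=[("left", 15, 0.1)],
            seed=0,
        )
        assert len(detect_blinks(self._clean(l), self._clean(r))) == 1

    def test_supra_threshold_saccade_flagged(self):
        l, _r = gen_gaze_trace(10, saccade_spec=[(5.0, 6.0, 0.0)], seed=1)
        v = velocity_filter(raw_to_trace(l))
        i = int(round(5.0 * 120))
        assert not v.valid[i]

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_gaze_trace(10, blink_schedule=[(5, 0.2), (5.1, 0.2)], seed=0)

    def test_determinism(self):
        a, _ = gen_gaze_trace(5, seed=9)
        b, _ = gen_gaze_trace(5, seed=9)
        np.testing.assert_array_equal(a.x, b.x)


class TestCascadeModulatedNoise:
    def test_length_and_determinism(self):
        spec = CascadeSpec(p=0.3, depth=10, seed=5)
        a = cascade_modulated_noise(spec, 5000)
        b = cascade_modulated_noise(spec, 5000)
        assert a.size == 5000
        np.testing.assert_array_equal(a, b)

    def test_mean_variance_near_one(self):
        v = np.mean(
            [
                cascade_modulated_noise(CascadeSpec(p=0.4, depth=10, seed=s), 4096).var()
                for s in range(10)
            ]
        )
        assert v == pytest.approx(1.0, rel=0.2)


class TestCohort:
    def test_minimal_two_subjects_dfs(self, rng):
        layout = RideLayout(total_duration=120.0)
        cohort = gen_cohort(
            CohortSpec(n_subjects=2, noise_sd=0.1, seed=0), layout,
            window_length=16.0, modalities=(),
        )
        res = rm_anova(cohort.truth.rename(columns={"faa": "value"}))
        assert (res.effects["condition"].df_num, res.effects["condition"].df_den) == (1, 1)
        assert (res.effects["event"].df_num, res.effects["event"].df_den) == (2, 2)

    def test_planted_effect_in_truth(self):
        layout = RideLayout(total_duration=120.0)
        spec = CohortSpec(n_subjects=40, condition_effect_faa=0.3, noise_sd=0.01, seed=3)
        cohort = gen_cohort(spec, layout, window_length=16.0, modalities=())
        t = cohort.truth
        diff = (
            t[t.condition == "human"].faa.mean()
            - t[t.condition == "selfdriving"].faa.mean()
        )
        assert diff == pytest.approx(0.3, abs=0.02)

    def test_null_calibration_truth_level(self):
        # condition effect 0, noise only -> rejection rate near alpha
        layout = RideLayout(total_duration=120.0)
        rejections = 0
        n_reps = 300
        for seed in range(n_reps):
            spec = CohortSpec(n_subjects=8, noise_sd=0.2, subject_sd=0.1, seed=seed)
            cohort = gen_cohort(spec, layout, window_length=16.0, modalities=())
            res = rm_anova(cohort.truth.rename(columns={"faa": "value"}))
            rejections += res.effects["condition"].p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_full_bundle_determinism(self):
        layout = RideLayout(total_duration=120.0)
        spec = CohortSpec(n_subjects=2, noise_sd=0.1, seed=11)
        c1 = gen_cohort(spec, layout, window_length=16.0)
        c2 = gen_cohort(spec, layout, window_length=16.0)
        np.testing.assert_array_equal(c1.bundles[0].eeg.values, c2.bundles[0].eeg.values)
        np.testing.assert_array_equal(c1.bundles[1].head_x, c2.bundles[1].head_x)
        np.testing.assert_array_equal(
            np.nan_to_num(c1.bundles[0].gaze_left.x), np.nan_to_num(c2.bundles[0].gaze_left.x)
        )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=4, noise_sd=-0.1)


@settings(max_examples=15, deadline=None)
@given(
    p=st.floats(0.05, 0.95),
    depth=st.integers(1, 12),
)
def test_property_cascade_sum_one(p, depth):
    m = gen_binomial_cascade(CascadeSpec(p=p, depth=depth))
    assert m.sum() == pytest.approx(1.0, abs=1e-12)
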