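"""Signal chain: deinterleaving, smoothing, detrending, z-scoring, dF/F."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fiberphot as fp
from fiberphot.preprocess import (
    CHANNEL_CA,
    CHANNEL_ISO,
    deinterleave,
    fit_exponential_baseline,
    interleave,
    scale_isosbestic,
    smooth_moving_average,
)


class TestDeinterleave:
    def test_sixty_fps_splits_into_two_thirty_fps_series(self):
        rec, _ = fp.generate_recording(fp.SyntheticSpec(duration_s=10.0, seed=0))
        assert len(rec) == 600
        iso, ca = deinterleave(rec)
        assert len(iso) == len(ca) == 300
        assert iso.rate == ca.rate == 30.0

    def test_single_frame(self):
        frames = pd.DataFrame(
            {"frame": [0], "system_time_s": [0.0], "channel": [CHANNEL_ISO], "value": [1.0]}
        )
        iso, ca = deinterleave(fp.PhotometryRecording(frames, 60.0))
        assert len(iso) == 1 and len(ca) == 0

    def test_round_trip_identity(self):
        rec, _ = fp.generate_recording(fp.SyntheticSpec(duration_s=7.0, seed=11))
        iso, ca = deinterleave(rec)
        rebuilt = interleave(iso, ca, combined_rate=rec.combined_rate)
        np.testing.assert_array_equal(
            rebuilt.frames["value"].to_numpy(), rec.frames["value"].to_numpy()
        )
        np.testing.assert_array_equal(
            rebuilt.frames["channel"].to_numpy(), rec.frames["channel"].to_numpy()
        )
        np.testing.assert_array_equal(
            rebuilt.frames["system_time_s"].to_numpy(),
            rec.frames["system_time_s"].to_numpy(),
        )

    def test_consecutive_same_channel_reports_frame_index(self):
        frames = pd.DataFrame(
            {
                "frame": range(4),
                "system_time_s": np.arange(4) / 60.0,
                "channel": [CHANNEL_ISO, CHANNEL_CA, CHANNEL_CA, CHANNEL_ISO],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(fp.RecordingCorruptionError, match="frames 1 and 2"):
            deinterleave(fp.PhotometryRecording(frames, 60.0))


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(smooth_moving_average(x, 1), x)

    def test_constant_series_unchanged(self):
        x = np.full(20, 7.5)
        np.testing.assert_allclose(smooth_moving_average(x, 5), x)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(9)
        x[4] = 9.0
        out = smooth_moving_average(x, 3)
        np.testing.assert_allclose(out[3:6], 3.0)
        np.testing.assert_allclose(out[:3], 0.0)

    def test_edges_use_shrinking_windows(self):
        x = np.arange(5, dtype=float)
        out = smooth_moving_average(x, 5)
        # first sample averages only the 3 available samples in its half-window
        assert out[0] == pytest.approx(np.mean(x[:3]))
        assert out[-1] == pytest.approx(np.mean(x[2:]))

    @pytest.mark.parametrize("window", [0, 2, 11])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(fp.ValidationError):
            smooth_moving_average(np.zeros(9), window)


class TestExponentialBaseline:
    def test_recovers_noise_free_parameters(self):
        t = np.arange(0, 600, 1 / 30)
        y = 100.0 * np.exp(-t / 300.0) + 10.0
        fit, detrended = fit_exponential_baseline(y, t)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(300.0, rel=1e-6)
        assert fit.offset == pytest.approx(10.0, rel=1e-6)
        np.testing.assert_allclose(detrended, 0.0, atol=1e-6)

    def test_constant_series_degenerates_gracefully(self):
        t = np.arange(0, 10, 0.1)
        fit, detrended = fit_exponential_baseline(np.full(t.size, 5.0), t)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.offset == pytest.approx(5.0)
        np.testing.assert_allclose(detrended, 0.0, atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(fp.ValidationError):
            fit_exponential_baseline(np.arange(5.0), np.arange(5.0))


class TestStandardize:
    def test_two_point_symmetry_population_sd(self):
        np.testing.assert_allclose(fp.standardize(np.array([0.0, 2.0])), [-1.0, 1.0])

    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.0, 1.0, 3.0, -2.0, 5.0, 0.5])
        np.testing.assert_allclose(
            fp.standardize(a * x + b), fp.standardize(x), atol=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(fp.ZeroVarianceError):
            fp.standardize(np.ones(10))


class TestScaleIsosbestic:
    def test_exact_line_recovered(self):
        rng = np.random.default_rng(0)
        iso = rng.normal(size=200)
        fit, fitted = scale_isosbestic(iso, 0.5 * iso)
        assert fit.slope == pytest.approx(0.5, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fitted, 0.5 * iso, atol=1e-7)

    def test_negative_relationship_clamps_to_zero(self):
        rng = np.random.default_rng(1)
        iso = rng.normal(size=200)
        ca = -0.8 * iso + 0.05 * rng.normal(size=200)
        fit, fitted = scale_isosbestic(iso, ca)
        assert fit.slope == 0.0
        assert fit.clamped
        np.testing.assert_allclose(fitted, fit.intercept)

    def test_gross_outliers_tolerated(self):
        rng = np.random.default_rng(2)
        iso = rng.normal(size=1000)
        ca = 0.7 * iso + 0.1 + 0.05 * rng.normal(size=1000)
        ca[::20] += 25.0  # 5% gross outliers
        fit, _ = scale_isosbestic(iso, ca)
        assert fit.slope == pytest.approx(0.7, rel=0.05)

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        iso = rng.normal(size=800)
        ca = 0.4 * iso - 0.2 + rng.normal(size=800)
        ca[::30] -= 12.0
        fit, _ = scale_isosbestic(iso, ca)
        ref = sm.RLM(
            ca, sm.add_constant(iso), M=sm.robust.norms.HuberT(t=1.345)
        ).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(fp.ValidationError, match="mismatch"):
            scale_isosbestic(np.zeros(20), np.zeros(21))


class TestDff:
    def test_perfect_prediction_gives_zero(self):
        x = np.linspace(-1, 1, 50)
        np.testing.assert_array_equal(fp.compute_dff(x, x), np.zeros(50))

    def test_zero_reference_passthrough(self):
        x = np.linspace(-1, 1, 50)
        np.testing.assert_array_equal(fp.compute_dff(x, np.zeros(50)), x)

    def test_divide_mode_guards_near_zero_denominator(self):
        x = np.linspace(-1, 1, 50)
        with pytest.raises(fp.ValidationError, match="near zero"):
            fp.compute_dff(x, np.zeros(50), method="divide")


class TestReferenceZscore:
    def test_zero_outside_window_when_trace_equals_reference_mean(self):
        t = np.arange(100) / 10.0
        x = np.zeros(100)
        x[10:20] = [1, -1] * 5  # reference window content, mean 0
        z = fp.zscore_reference(x, t, (1.0, 2.0))
        np.testing.assert_allclose(z[t >= 2.0], 0.0)

    def test_injected_step_measured_in_reference_sd_units(self):
        rng = np.random.default_rng(4)
        t = np.arange(3000) / 10.0
        x = rng.normal(0.0, 2.0, 3000)
        sd_ref = np.std(x[(t >= 0) & (t < 100)])
        mean_ref = np.mean(x[(t >= 0) & (t < 100)])
        x[t >= 150] += -3.0 * sd_ref
        z = fp.zscore_reference(x, t, (0.0, 100.0))
        expected = (np.mean(x[t >= 150]) - mean_ref) / sd_ref
        assert np.mean(z[t >= 150]) == pytest.approx(expected, abs=1e-9)
        assert np.mean(z[t >= 150]) == pytest.approx(-3.0, abs=0.2)

    def test_full_window_equals_plain_standardize(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        t = np.arange(500) / 30.0
        z_ref = fp.zscore_reference(x, t, (0.0, 500 / 30.0))
        np.testing.assert_allclose(z_ref, fp.standardize(x), atol=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(fp.ValidationError):
            fp.zscore_reference(np.zeros(10), np.arange(10.0), (20.0, 30.0))


class TestPreprocessPipeline:
    def test_bleach_only_recording_yields_no_signal(self, quiet_spec):
        spec = fp.SyntheticSpec(
            duration_s=120.0, noise_sd=0.0, artifact_rate_hz=0.0, seed=0
        )
        rec, _ = fp.generate_recording(spec)
        pt = fp.preprocess(rec)
        assert pt.mode == "baseline_corrected"
        # residual is dominated by the moving-average edge bias, which is
        # O(slope * window) ~ 3e-3 here; everything is tiny vs the bleach
        np.testing.assert_allclose(pt.ca_detrended, 0.0, atol=0.01)
        # dF/F mapped back to raw fluorescence units is negligible vs the bleach
        sd_ca = pt.standardization[CHANNEL_CA][1]
        assert np.max(np.abs(pt.dff * sd_ca)) < 1e-3 * spec.bleach_amplitude

    def test_transient_timing_survives_the_chain(self):
        spec = fp.SyntheticSpec(
            duration_s=600.0,
            noise_sd=0.0,
            artifact_rate_hz=0.2,
            artifact_amplitude_sd=6.0,
            transient_events=(fp.TransientEvent(300.0, 30.0, 0.5, 2.0),),
            seed=9,
        )
        rec, _ = fp.generate_recording(spec)
        pt = fp.preprocess(rec)
        t_peak = 300.0 + fp.kernel_peak_time(0.5, 2.0)
        got = pt.time_s[np.argmax(pt.dff)]
        assert abs(got - t_peak) <= 1.0 / pt.sample_rate + 1e-9

    def test_no_spurious_transients_created_or_destroyed(self):
        onsets = (100.0, 250.0, 400.0)
        spec = fp.SyntheticSpec(
            duration_s=600.0,
            noise_sd=0.0,
            artifact_rate_hz=0.0,
            transient_events=tuple(
                fp.TransientEvent(t0, 40.0, 0.5, 2.0) for t0 in onsets
            ),
            seed=1,
        )
        rec, _ = fp.generate_recording(spec)
        pt = fp.preprocess(rec)
        above = pt.dff > 3.0
        n_bouts = int(np.sum(above[1:] & ~above[:-1]) + above[0])
        assert n_bouts == len(onsets)

    def test_step_suppression_analyzed_in_reference_mode(self):
        spec, _ = fp.feeding_protocol(drop_z=3.0, seed=2)
        rec, _ = fp.generate_recording(spec)
        pt = fp.preprocess(
            rec, fp.PreprocessConfig(mode="reference", reference_window=(0.0, 300.0))
        )
        assert pt.mode == "reference_z"
        assert pt.baseline_params is None and pt.dff is None
        post = pt.time_s > 310.0
        assert np.mean(pt.ca_z[post]) < -2.0
        assert abs(np.mean(pt.iso_z[post])) < 1.0

    def test_step_change_triggers_fallback_from_baseline_mode(self):
        spec, _ = fp.feeding_protocol(drop_z=5.0, seed=2)
        rec, _ = fp.generate_recording(spec)
        pt = fp.preprocess(rec)  # default: baseline mode with fallback allowed
        assert pt.mode == "reference_z"
        assert "R^2" in pt.fallback_reason
        with pytest.raises(fp.PipelineError, match="baseline fit"):
            fp.preprocess(rec, fp.PreprocessConfig(allow_fallback=False))

    def test_intermediates_all_present_and_aligned(self):
        rec, _ = fp.generate_recording(fp.SyntheticSpec(duration_s=300.0, seed=3))
        pt = fp.preprocess(rec)
        assert pt.mode == "baseline_corrected"
        df = pt.to_frame()
        assert {"ca_raw", "iso_raw", "ca_z", "iso_z", "iso_fitted", "dff"} <= set(
            df.columns
        )
        assert len(df) == len(pt.time_s)
        assert pt.scaling.slope >= 0.0
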