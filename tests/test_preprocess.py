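"""Signal-chain contracts: screening, denoising, MBLL, detrend, FIR, epochs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import freqz

from nirsgait import synthdata
from nirsgait.optics import OpticalParams, dpf_general
from nirsgait.preprocess import (
    PreprocessConfig,
    RecordingRejected,
    baseline_correct,
    extract_epochs,
    fir_lowpass,
    fir_taps,
    flag_invalid_voxels,
    mbll_convert,
    run_preprocess,
    spline_detrend,
    wavelet_denoise,
)

from conftest import ZERO_NOISE

FS = 2.0


def quiet_raw(seed=0, **overrides):
    cfg = synthdata.SynthConfig(**{**ZERO_NOISE, **overrides})
    return synthdata.make_recording(cfg, seed=seed), cfg


# ---------------------------------------------------------------------------
# voxel screening


class TestFlagInvalidVoxels:
    def test_clean_recording_flags_nothing(self):
        raw, _ = quiet_raw(shot_noise_frac=0.002)
        assert flag_invalid_voxels(raw, PreprocessConfig()) == set()

    def test_saturated_voxel_flagged(self):
        raw, _ = quiet_raw(shot_noise_frac=0.002)
        raw.intensities[0, 4, 100:110] = raw.detector_max  # 5 s at ceiling
        assert 5 in flag_invalid_voxels(raw, PreprocessConfig())

    def test_dark_voxel_flagged(self):
        raw, _ = quiet_raw(shot_noise_frac=0.002)
        raw.intensities[1, 7, 50:60] = 0.001 * raw.detector_max
        assert 8 in flag_invalid_voxels(raw, PreprocessConfig())

    def test_extreme_noise_voxel_flagged(self):
        raw, _ = quiet_raw(shot_noise_frac=0.002)
        rng = np.random.default_rng(0)
        noise_sd = 20 * raw.intensities[0].std(axis=-1).mean()
        raw.intensities[0, 2] += rng.standard_normal(raw.n_samples) * max(noise_sd, 40.0)
        raw.intensities = np.clip(raw.intensities, 1.0, raw.detector_max)
        assert 3 in flag_invalid_voxels(raw, PreprocessConfig())

    def test_all_voxels_bad_rejects_recording(self):
        raw, _ = quiet_raw(shot_noise_frac=0.002)
        raw.intensities[:, :, 100:110] = raw.detector_max
        with pytest.raises(RecordingRejected):
            flag_invalid_voxels(raw, PreprocessConfig())


# ---------------------------------------------------------------------------
# wavelet artifact removal


class TestWaveletDenoise:
    def test_zero_series_maps_to_zero(self):
        out = wavelet_denoise(np.zeros(256), PreprocessConfig())
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_slow_sinusoid_preserved_within_5pct_rms(self):
        t = np.arange(600) / FS
        x = np.sin(2 * np.pi * 0.02 * t) + 0.05 * np.random.default_rng(0).standard_normal(600)
        y = wavelet_denoise(x, PreprocessConfig())
        assert np.sqrt(np.mean((y - x) ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_spike_amplitude_reduced_80pct(self, seed):
        # spike amplitude = deviation from the local background (what makes
        # a spike spiky); any smooth low-frequency remnant is not a spike
        def sharp_amp(x, i=300):
            neigh = np.concatenate([x[i - 5:i], x[i + 1:i + 6]])
            return x[i] - np.median(neigh)

        t = np.arange(600) / FS
        rng = np.random.default_rng(seed)
        clean = np.sin(2 * np.pi * 0.02 * t) + 0.05 * rng.standard_normal(600)
        spiked = clean.copy()
        spiked[300] += 10 * 0.05  # 10 sigma of the noise floor
        y = wavelet_denoise(spiked, PreprocessConfig())
        assert abs(sharp_amp(y)) < 0.2 * abs(sharp_amp(spiked))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_denoise(np.zeros(20), PreprocessConfig())

    def test_output_length_matches_input(self):
        for n in (250, 256, 333):
            assert wavelet_denoise(np.ones(n), PreprocessConfig()).size == n


# ---------------------------------------------------------------------------
# MBLL


class TestMbll:
    def test_reference_intensity_maps_to_zero(self, default_optics):
        intens = np.stack([np.full((4, 50), 1000.0), np.full((4, 50), 1000.0)])
        hbo2, hb = mbll_convert(intens, default_optics)
        np.testing.assert_allclose(hbo2, 0.0, atol=1e-12)
        np.testing.assert_allclose(hb, 0.0, atol=1e-12)

    def test_forward_inverse_recovers_step(self, quiet_config, default_optics):
        hbo2 = np.full((16, 40), 1.0)
        hb = np.full((16, 40), -0.5)
        intens = synthdata.forward_intensity((hbo2, hb), default_optics, quiet_config, 0)
        out_o, out_h = mbll_convert(intens, default_optics)
        np.testing.assert_allclose(out_o, 1.0, atol=1e-8)
        np.testing.assert_allclose(out_h, -0.5, atol=1e-8)

    @settings(max_examples=60, deadline=None)
    @given(
        e00=st.floats(0.1, 2.0), e01=st.floats(2.0, 4.0),
        e10=st.floats(2.0, 4.0), e11=st.floats(0.1, 2.0),
        d=st.floats(1.0, 4.0), dpf1=st.floats(4.0, 8.0), dpf2=st.floats(4.0, 8.0),
        c1=st.floats(-2.0, 2.0), c2=st.floats(-2.0, 2.0),
    )
    def test_inversion_is_algebraic_inverse(self, e00, e01, e10, e11, d, dpf1, dpf2, c1, c2):
        """Closed-form 2x2 inversion oracle over random optical parameters."""
        eps = np.array([[e00, e01], [e10, e11]]) * 1e-3
        optics = OpticalParams(epsilon=eps, d=d, dpf=(dpf1, dpf2), i0=(800.0, 1200.0))
        hbo2 = np.full((1, 8), c1)
        hb = np.full((1, 8), c2)
        od = np.stack(
            [(eps[w, 0] * hbo2 + eps[w, 1] * hb) * d * (dpf1, dpf2)[w] for w in range(2)]
        )
        intens = np.asarray(optics.i0)[:, None, None] * 10.0 ** (-od)
        out_o, out_h = mbll_convert(intens, optics)
        # independent oracle: explicit adjugate inverse of the 2x2 system
        det = eps[0, 0] * eps[1, 1] - eps[0, 1] * eps[1, 0]
        s1 = od[0, 0, 0] / (d * dpf1)
        s2 = od[1, 0, 0] / (d * dpf2)
        want_o = (eps[1, 1] * s1 - eps[0, 1] * s2) / det
        want_h = (-eps[1, 0] * s1 + eps[0, 0] * s2) / det
        assert abs(out_o[0, 0] - want_o) <= 1e-8 * max(1.0, abs(want_o))
        assert abs(out_h[0, 0] - want_h) <= 1e-8 * max(1.0, abs(want_h))

    def test_doubling_dpf_halves_concentrations(self, quiet_config, default_optics):
        hbo2, hb = np.full((2, 30), 0.8), np.full((2, 30), -0.2)
        intens = synthdata.forward_intensity((hbo2, hb), default_optics, quiet_config, 0)
        doubled = OpticalParams(
            i0=default_optics.i0,
            dpf=tuple(2 * v for v in default_optics.dpf),
            d=default_optics.d,
        )
        out_o, out_h = mbll_convert(intens, doubled)
        np.testing.assert_allclose(out_o, 0.4, atol=1e-8)
        np.testing.assert_allclose(out_h, -0.1, atol=1e-8)

    def test_nonpositive_intensity_names_location(self, default_optics):
        intens = np.full((2, 3, 10), 500.0)
        intens[1, 2, 4] = 0.0
        with pytest.raises(ValueError, match="voxel 3, sample 4"):
            mbll_convert(intens, default_optics)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            OpticalParams(epsilon=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_dpf_decreases_with_wavelength_increases_with_age(self):
        assert dpf_general(730, 76) > dpf_general(850, 76)
        assert dpf_general(730, 85) > dpf_general(730, 65)


# ---------------------------------------------------------------------------
# spline detrend


class TestSplineDetrend:
    def test_linear_ramp_removed_below_1pct(self):
        ramp = np.linspace(0.0, 5.0, 800)
        out = spline_detrend(ramp, fs=FS)
        assert np.abs(out).max() < 0.01 * 5.0

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(spline_detrend(np.zeros(400), fs=FS), 0.0, atol=1e-12)

    def test_step_plateau_reduced_90pct(self):
        t = np.arange(1200) / FS
        step = np.where(t >= 300.0, 2.0, 0.0)
        out = spline_detrend(step, fs=FS)
        post = out[int(320 * FS):]
        assert np.abs(post.mean()) < 0.1 * 2.0

    def test_noisy_step_also_leveled(self):
        t = np.arange(1200) / FS
        x = np.where(t >= 300.0, 2.0, 0.0) + 0.05 * np.random.default_rng(3).standard_normal(1200)
        out = spline_detrend(x, fs=FS)
        assert np.abs(out[int(320 * FS):].mean()) < 0.1 * 2.0

    def test_task_scale_bump_survives(self):
        # 60-s plateau with 10-s ramps must not be absorbed as 'trend'
        t = np.arange(1200) / FS
        bump = np.clip(np.minimum((t - 150) / 10, (212 - t) / 10), 0, 1)
        noisy = bump + 0.1 * np.random.default_rng(4).standard_normal(1200)
        out = spline_detrend(noisy, fs=FS)
        interior = out[int(164 * FS): int(198 * FS)].mean()
        assert interior > 0.7

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            spline_detrend(np.zeros(100), p=0.0)
        with pytest.raises(ValueError):
            spline_detrend(np.zeros(100), p=1.5)


# ---------------------------------------------------------------------------
# FIR low-pass


class TestFirLowpass:
    def test_dc_gain_unity(self):
        taps = fir_taps(PreprocessConfig())
        assert abs(taps.sum() - 1.0) < 1e-6
        out = fir_lowpass(np.full(500, 3.7), PreprocessConfig())
        np.testing.assert_allclose(out, 3.7, atol=1e-6)
        assert out.size == 500

    def test_respiration_band_attenuated_40db(self):
        taps = fir_taps(PreprocessConfig())
        _, h = freqz(taps, worN=[0.25], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) <= -40.0

    def test_passband_within_5pct(self):
        taps = fir_taps(PreprocessConfig())
        _, h = freqz(taps, worN=[0.02], fs=FS)
        assert abs(np.abs(h[0]) - 1.0) < 0.05
        # and on an actual series
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        y = fir_lowpass(x, PreprocessConfig())
        assert abs(y[200:-200].std() / x[200:-200].std() - 1.0) < 0.05

    def test_zero_phase_alignment(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        y = fir_lowpass(x, PreprocessConfig())
        inner = slice(100, 900)
        lag = np.argmax(np.correlate(y[inner], x[inner], "full")) - (inner.stop - inner.start - 1)
        assert abs(lag) <= 1

    def test_causal_mode_delays(self):
        cfg = PreprocessConfig(zero_phase=False)
        x = np.zeros(300)
        x[0] = 1.0
        y = fir_lowpass(x, cfg)
        assert np.argmax(y) == pytest.approx(49.5, abs=1.5)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fir_lowpass(np.zeros(100), PreprocessConfig(fir_cutoff=1.5))


# ---------------------------------------------------------------------------
# epochs


class TestEpochs:
    def _hemo(self, schedule, n=None):
        from nirsgait.preprocess import HemoRecording

        end = int(round((schedule.end + 20) * FS)) if n is None else n
        rng = np.random.default_rng(0)
        return HemoRecording(
            hbo2=rng.standard_normal((16, end)),
            hb=rng.standard_normal((16, end)),
            fs=FS, schedule=schedule, missing_voxels=frozenset(),
        )

    def test_epoch_length_is_two_samples_per_second(self):
        blocks = (
            synthdata.TaskBlock("STW", 20.0, 30.0, 75.0),
            synthdata.TaskBlock("DTW", 95.0, 105.0, 167.5),
            synthdata.TaskBlock("STA", 187.5, 197.5, 227.5),
        )
        sched = synthdata.TaskSchedule(blocks=blocks)
        eps = extract_epochs(self._hemo(sched))
        by_cond = {e.condition: e for e in eps}
        assert by_cond["DTW"].n_samples == 125  # 62.5 s at 2 Hz
        assert by_cond["STA"].n_samples == 60  # 30-s recitation
        assert by_cond["STW"].n_samples == 90

    def test_empty_schedule_yields_no_epochs(self):
        import types

        sched = types.SimpleNamespace(blocks=())
        assert extract_epochs(self._hemo(sched, n=100)) == []

    def test_marker_outside_recording_rejected(self):
        blocks = (
            synthdata.TaskBlock("STW", 20.0, 30.0, 75.0),
            synthdata.TaskBlock("DTW", 95.0, 105.0, 167.5),
            synthdata.TaskBlock("STA", 187.5, 197.5, 227.5),
        )
        sched = synthdata.TaskSchedule(blocks=blocks)
        with pytest.raises(ValueError, match="outside"):
            extract_epochs(self._hemo(sched, n=300))

    def test_missing_voxels_excluded_from_rows(self):
        blocks = (
            synthdata.TaskBlock("STW", 20.0, 30.0, 75.0),
            synthdata.TaskBlock("DTW", 95.0, 105.0, 167.5),
            synthdata.TaskBlock("STA", 187.5, 197.5, 227.5),
        )
        sched = synthdata.TaskSchedule(blocks=blocks)
        hemo = self._hemo(sched)
        hemo.missing_voxels = frozenset({2, 9})
        eps = extract_epochs(hemo)
        assert all(e.n_valid == 14 for e in eps)
        assert all(2 not in e.voxels and 9 not in e.voxels for e in eps)

    def test_baseline_correction_definition(self):
        blocks = (
            synthdata.TaskBlock("STW", 20.0, 30.0, 75.0),
            synthdata.TaskBlock("DTW", 95.0, 105.0, 167.5),
            synthdata.TaskBlock("STA", 187.5, 197.5, 227.5),
        )
        sched = synthdata.TaskSchedule(blocks=blocks)
        hemo = self._hemo(sched)
        hemo.hbo2[:] = 0.0
        hemo.hbo2[4, :] = 0.7  # constant offset on one voxel
        ep = extract_epochs(hemo)[0]
        corrected = baseline_correct(ep, hemo)
        np.testing.assert_allclose(corrected.hbo2[4], 0.0, atol=1e-12)
        # recomputing the baseline mean after correction gives exactly zero
        a = int(round(ep.baseline_start * FS))
        rows = [v - 1 for v in ep.voxels]
        base_mean = hemo.hbo2[rows, a:a + 20].mean(axis=1, keepdims=True)
        resid = (hemo.hbo2[rows, a:a + 20] - base_mean).mean(axis=1)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_zero_baseline_leaves_epoch_unchanged(self):
        blocks = (
            synthdata.TaskBlock("STW", 20.0, 30.0, 75.0),
            synthdata.TaskBlock("DTW", 95.0, 105.0, 167.5),
            synthdata.TaskBlock("STA", 187.5, 197.5, 227.5),
        )
        sched = synthdata.TaskSchedule(blocks=blocks)
        hemo = self._hemo(sched)
        a = int(round(20.0 * FS))
        hemo.hbo2[:, a:a + 20] = 0.0
        hemo.hb[:, a:a + 20] = 0.0
        ep = extract_epochs(hemo)[0]
        corrected = baseline_correct(ep, hemo)
        np.testing.assert_array_equal(corrected.hbo2, ep.hbo2)


# ---------------------------------------------------------------------------
# full chain


class TestRunPreprocess:
    def test_noise_free_chain_matches_filtered_ground_truth(self, default_optics):
        """End to end, the pipeline equals the ground-truth concentrations
        pushed through the identical detrend/low-pass/baseline chain."""
        raw, cfg = quiet_raw()
        pcfg = PreprocessConfig()
        eps = run_preprocess(raw, pcfg, default_optics)
        ref = raw.ground_truth["hbo2"].copy()
        for v in range(16):
            ref[v] = fir_lowpass(spline_detrend(ref[v], fs=FS), pcfg)
        for e in eps:
            a = int(round(e.task_start * FS))
            b = a + e.n_samples
            ba = int(round(e.baseline_start * FS))
            expected = ref[:, a:b] - ref[:, ba:ba + 20].mean(axis=1, keepdims=True)
            scale = max(1.0, np.abs(expected).max())
            assert np.abs(e.hbo2 - expected).max() <= 0.02 * scale

    def test_epoch_means_recover_shift_ordering(self):
        raw, cfg = quiet_raw()
        eps = run_preprocess(raw)
        means = {e.condition: e.hbo2.mean() for e in eps}
        # most of each configured shift survives filtering, order intact
        assert means["STW"] < means["STA"] < means["DTW"]
        assert means["DTW"] > 0.75 * cfg.hbo2_shift["DTW"]
        assert means["STA"] > 0.75 * cfg.hbo2_shift["STA"]

    def test_all_saturated_recording_rejected(self):
        raw, _ = quiet_raw()
        raw.intensities[:] = raw.detector_max
        with pytest.raises(RecordingRejected):
            run_preprocess(raw)

    def test_deterministic(self, small_cohort):
        a = run_preprocess(small_cohort[0])
        b = run_preprocess(small_cohort[0])
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.hbo2, eb.hbo2)
            np.testing.assert_array_equal(ea.hb, eb.hb)

    def test_no_nans_on_valid_input(self, small_cohort):
        for rec in small_cohort[:4]:
            try:
                eps = run_preprocess(rec)
            except RecordingRejected:
                continue
            for e in eps:
                assert np.isfinite(e.hbo2).all()
                assert np.isfinite(e.hb).all()

    def test_epoch_lengths_depend_only_on_markers(self):
        # changing filter settings must never change epoch geometry
        raw, _ = quiet_raw()
        lengths = lambda eps: [(e.condition, e.n_samples) for e in eps]
        a = run_preprocess(raw, PreprocessConfig())
        b = run_preprocess(raw, PreprocessConfig(fir_cutoff=0.05, spline_p=0.9))
        assert lengths(a) == lengths(b)
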