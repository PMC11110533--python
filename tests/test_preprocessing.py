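"""Preprocessing chain: pruning, OD, artifact detection, wavelet
correction, filtering, MBLL inversion and CBSI."""
import numpy as np
import pytest

import fnirsglu as fg
from conftest import tiny_config
from oracles import cbsi_oracle, od_oracle


def make_recording(series_per_channel, fs=10.0, state_labels=None):
    """Build a RawRecording from a list of (T,) or (T,2) channel series."""
    cols = []
    for s in series_per_channel:
        s = np.asarray(s, dtype=float)
        if s.ndim == 1:
            s = np.stack([s, s], axis=-1)
        cols.append(s)
    arr = np.stack(cols, axis=1)          # (T, C, 2)
    t = np.arange(arr.shape[0]) / fs
    return fg.RawRecording("S01", "fasting", t, arr, fs,
                           state_labels=state_labels)


class TestPruneChannels:
    def test_drange_and_snr_rules(self):
        rng = np.random.default_rng(0)
        const = np.full(100, 0.5)                    # kept: infinite SNR
        too_bright = np.full(100, 5.0)               # pruned: above dRange
        noisy = 0.5 + rng.normal(0, 0.3, 100)        # pruned: SNR ≈ 1.67
        noisy = np.clip(noisy, 0.05, None)
        rec = make_recording([const, too_bright, noisy])
        mask = fg.prune_channels(rec)
        assert mask.tolist() == [True, False, False]

    def test_all_pruned_raises(self):
        rec = make_recording([np.full(50, 5.0)])
        with pytest.raises(fg.DataError, match="no usable channels"):
            fg.prune_channels(rec)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self):
        rec = make_recording([np.full(64, 0.3)])
        od = fg.intensity_to_od(rec)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_decade_drop_gives_unit_od(self):
        """A sample at one tenth of the temporal mean maps to ΔOD = 1."""
        n, a = 100, 0.5
        b = a * (n - 1) / (10 * n - 1)    # chosen so b = mean/10 exactly
        x = np.full(n, a)
        x[40] = b
        od = fg.intensity_to_od(make_recording([x]))
        assert od.od[40, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        x = rng.uniform(0.05, 0.9, 300)
        od = fg.intensity_to_od(make_recording([x]))
        np.testing.assert_allclose(od.od[:, 0, 0], od_oracle(x), atol=1e-12)

    def test_fasting_baseline_referencing(self):
        """With baseline='fasting' the fasting block has zero mean OD and
        the glucose block keeps its offset relative to it."""
        labels = np.array(["fasting"] * 50 + ["glucose"] * 50, dtype=object)
        x = np.concatenate([np.full(50, 0.5), np.full(50, 0.4)])
        od = fg.intensity_to_od(make_recording([x], state_labels=labels),
                                baseline="fasting")
        np.testing.assert_allclose(od.od[:50, 0, 0], 0.0, atol=1e-14)
        assert od.od[60, 0, 0] == pytest.approx(-np.log10(0.4 / 0.5))

    def test_nonpositive_sample_names_location(self):
        x = np.full(50, 0.5)
        x[7] = 0.0
        with pytest.raises(fg.DataError, match="channel 1.*sample 7"):
            fg.intensity_to_od(make_recording([x]))


class TestMotionDetection:
    def test_clean_signal_empty_mask(self):
        t = np.arange(600) / 10.0
        clean = 0.001 * np.sin(2 * np.pi * 0.05 * t)
        od = fg.intensity_to_od(make_recording([np.exp(-clean)]))
        mask = fg.detect_motion_artifacts(od)
        assert mask.shape == (600, 1)
        assert not mask.any()

    def test_injected_step_is_flagged_with_mask_extension(self):
        x = np.full(600, 0.5)
        x[300:] *= 1.6                    # huge step in OD terms
        od = fg.intensity_to_od(make_recording([x]))
        mask = fg.detect_motion_artifacts(od, t_mask=1.0)
        assert mask[300, 0]
        assert mask[295, 0] and mask[305, 0]   # ± t_mask coverage
        assert not mask[100, 0]


class TestWaveletCorrection:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(6000) / 10.0
        x = np.sin(2 * np.pi * 0.05 * t)
        od = fg.ODSeries(x[:, None, None].repeat(2, axis=2).copy(), t, 10.0,
                         np.array([True]))
        out = fg.wavelet_motion_correct(od)
        rms_in = np.sqrt((x ** 2).mean())
        rms_out = np.sqrt((out.od[:, 0, 0] ** 2).mean())
        assert abs(rms_out - rms_in) / rms_in < 0.10

    def test_spike_strongly_attenuated(self):
        t = np.arange(6000) / 10.0
        clean = 0.01 * np.sin(2 * np.pi * 0.05 * t)
        spike = np.zeros_like(clean)
        amp = 1.0
        spike[3000:3010] = amp * np.exp(-np.arange(10) / 3.0)
        od = fg.ODSeries((clean + spike)[:, None, None].repeat(2, axis=2).copy(),
                         t, 10.0, np.array([True]))
        out = fg.wavelet_motion_correct(od)
        residual = np.abs(out.od[:, 0, 0] - clean).max()
        assert residual <= 0.2 * amp

    def test_zero_in_zero_out(self):
        od = fg.ODSeries(np.zeros((512, 1, 2)), np.arange(512) / 10.0, 10.0,
                         np.array([True]))
        out = fg.wavelet_motion_correct(od)
        np.testing.assert_allclose(out.od, 0.0, atol=1e-12)

    def test_unsupported_wavelet_rejected(self):
        od = fg.ODSeries(np.zeros((64, 1, 2)), np.arange(64) / 10.0, 10.0,
                         np.array([True]))
        with pytest.raises(fg.ConfigError):
            fg.wavelet_motion_correct(od, wavelet="nosuchwavelet")
        with pytest.raises(fg.ConfigError):
            fg.wavelet_motion_correct(od, level=12)


class TestBandpass:
    def test_dc_removed_by_band_configuration(self):
        out = fg.bandpass_filter(np.ones(6000), 0.01, 0.1, 10.0)
        assert np.abs(out[1000:-1000]).max() < 1e-3

    def test_band_edges_validated(self):
        with pytest.raises(fg.ConfigError):
            fg.bandpass_filter(np.ones(100), 1.0, 20.0, 10.0)
        with pytest.raises(fg.ConfigError):
            fg.bandpass_filter(np.ones(100), None, None, 10.0)


class TestMBLLInversion:
    def test_zero_od_zero_concentration(self):
        o, r = fg.mbll_invert(np.zeros((10, 2)))
        np.testing.assert_array_equal(o, 0.0)
        np.testing.assert_array_equal(r, 0.0)

    def test_known_pair_round_trip(self):
        od = fg.forward_mbll_od(np.array([1.0]), np.array([-0.5]))
        o, r = fg.mbll_invert(od)
        assert o[0] == pytest.approx(1.0, abs=1e-8)
        assert r[0] == pytest.approx(-0.5, abs=1e-8)

    def test_linearity(self, rng):
        od = rng.normal(0, 0.01, (20, 2))
        o1, r1 = fg.mbll_invert(od)
        o2, r2 = fg.mbll_invert(2 * od)
        np.testing.assert_allclose(o2, 2 * o1, rtol=1e-12)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)


class TestCBSI:
    def _hemo(self, hbo, hbr):
        hbo = np.asarray(hbo, float)[:, None]
        hbr = np.asarray(hbr, float)[:, None]
        return fg.HemoTimeSeries(hbo, hbr, np.arange(len(hbo)) / 10.0, 10.0,
                                 np.array([True]))

    def test_perfect_anticorrelation_preserved(self):
        hbo = np.sin(np.arange(100) / 5.0)
        out = fg.cbsi_correct(self._hemo(hbo, -hbo))
        np.testing.assert_allclose(out.dhbo[:, 0], hbo, atol=1e-12)

    def test_output_perfectly_anticorrelated(self, rng):
        out = fg.cbsi_correct(self._hemo(rng.normal(size=200),
                                         rng.normal(size=200)))
        r = np.corrcoef(out.dhbo[:, 0], out.dhbr[:, 0])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        hbo = rng.normal(size=150)
        hbr = rng.normal(size=150)
        out = fg.cbsi_correct(self._hemo(hbo, hbr))
        exp_o, exp_r = cbsi_oracle(hbo, hbr)
        np.testing.assert_allclose(out.dhbo[:, 0], exp_o, atol=1e-12)
        np.testing.assert_allclose(out.dhbr[:, 0], exp_r, atol=1e-12)

    def test_zero_variance_channel_skipped_with_flag(self):
        hemo = self._hemo(np.ones(50), np.zeros(50))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = fg.cbsi_correct(hemo)
        assert out.provenance["cbsi_skipped_channels"] == [1]


class TestRunPreprocessing:
    def test_noise_free_channel_recovery(self):
        """A noise-free coupled channel survives the full default chain
        with r ≥ 0.95 against the generative ground truth."""
        cfg = tiny_config(cardiac_amp=0.0, respiratory_amp=0.0,
                          mayer_amp=0.0, vlf_amp=0.0, noise_sd=0.0,
                          hbr_noise_sd=0.0, artifact_spike_rate=0.0,
                          artifact_shift_rate=0.0)
        sub = fg.generate_cohort(cfg).subjects[0]
        hemo = fg.run_preprocessing(sub.session())
        c = 1          # channel 2 (coupled) → column index 1
        r = np.corrcoef(hemo.dhbo[:, c], sub.truth.dhbo[:, c])[0, 1]
        assert r >= 0.95

    def test_stage_order_recorded(self, small_cohort):
        hemo = fg.run_preprocessing(small_cohort.subjects[0].session())
        assert hemo.provenance["stages"] == [
            "prune_channels", "intensity_to_od", "detect_motion_artifacts",
            "wavelet_motion_correct", "bandpass_filter", "mbll", "cbsi"]

    def test_disabling_corrections_reduces_to_od_mbll(self, small_cohort):
        params = fg.PreprocessParams(do_prune=False, do_motion_detect=False,
                                     do_wavelet=False, do_bandpass=False,
                                     do_cbsi=False)
        hemo = fg.run_preprocessing(small_cohort.subjects[0].session(), params)
        assert hemo.provenance["stages"] == ["intensity_to_od", "mbll"]

    def test_stage_errors_carry_stage_name(self):
        bad = make_recording([np.full(50, 0.5)])
        bad.intensity[10] = -1.0
        params = fg.PreprocessParams(do_prune=False)
        with pytest.raises(fg.StageError) as err:
            fg.run_preprocessing(bad, params)
        assert err.value.stage == "intensity_to_od"
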