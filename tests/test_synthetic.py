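"""Synthetic cohort generator: curve shape, coupling, MBLL forward model,
artifact injection, determinism and serialization."""
import numpy as np
import pytest
from scipy import stats

import fnirsglu as fg
from conftest import tiny_config


def noise_free_config(**overrides):
    base = dict(fasting_glucose_sd=0.0, peak_delta_sd=0.0, peak_time_sd=0.0,
                glucose_curve_noise_sd=0.0, glucose_meter_sd=0.0,
                cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0,
                vlf_amp=0.0, noise_sd=0.0, hbr_noise_sd=0.0,
                coupling_beta_sd=0.0, artifact_spike_rate=0.0,
                artifact_shift_rate=0.0)
    base.update(overrides)
    return tiny_config(**base)


class TestGlucoseCurve:
    def test_deterministic_peak(self):
        """With all randomness off the curve peaks at exactly fasting+Δ at
        the configured peak time and starts at the fasting level."""
        cfg = noise_free_config(fasting_glucose_mean=5.0, peak_delta_mean=3.0,
                                peak_time_mean=180.0)
        t, g = fg.generate_glucose_curve(cfg, 0)
        assert g.max() == pytest.approx(8.0, abs=1e-12)
        peak_idx = int(np.argmax(g))
        assert t[peak_idx] == pytest.approx(cfg.fasting_duration + 180.0)
        assert g[0] == pytest.approx(5.0)
        # continuous at the state boundary: no jump at load time
        i0 = cfg.n_samples(cfg.fasting_duration)
        assert abs(g[i0] - g[i0 - 1]) < 0.05

    def test_decays_toward_plateau_above_fasting(self):
        cfg = noise_free_config(glucose_duration=3600.0, decay_tau=300.0)
        _, g = fg.generate_glucose_curve(cfg, 0)
        plateau = 5.0 + cfg.plateau_fraction * 3.0
        assert g[-1] == pytest.approx(plateau, rel=0.02)
        assert g[-1] > 5.0

    def test_fasting_variance_bounded_by_noise(self):
        """Monte-Carlo over 100 seeds: the fasting segment is a stationary
        level, so its sample variance stays within 3× the jitter variance."""
        cfg = tiny_config(glucose_duration=60.0)
        n_f = cfg.n_samples(cfg.fasting_duration)
        bound = 3.0 * cfg.glucose_curve_noise_sd ** 2
        for seed in range(100):
            _, g = fg.generate_glucose_curve(cfg, seed)
            assert g[:n_f].var() <= bound

    def test_seeded_determinism(self):
        cfg = tiny_config()
        t1, g1 = fg.generate_glucose_curve(cfg, 3)
        t2, g2 = fg.generate_glucose_curve(cfg, 3)
        np.testing.assert_array_equal(g1, g2)
        _, g3 = fg.generate_glucose_curve(cfg, 4)
        assert not np.array_equal(g1, g3)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(fg.ConfigError):
            fg.generate_glucose_curve(tiny_config(fasting_duration=-1.0), 0)


class TestHemoForwardModel:
    def test_zero_coupling_no_noise_is_flat(self):
        cfg = noise_free_config()
        t, g = fg.generate_glucose_curve(cfg, 0)
        dhbo, dhbr, beta = fg.hemo_forward_model(t, g, cfg, channel=1,
                                                 rng=0)  # uncoupled
        assert beta == 0.0
        np.testing.assert_allclose(dhbo, 0.0, atol=1e-12)

    def test_pure_coupling_is_affine_in_glucose(self):
        cfg = noise_free_config()
        t, g = fg.generate_glucose_curve(cfg, 0)
        dhbo, _, _ = fg.hemo_forward_model(t, g, cfg, channel=2, rng=0,
                                           beta=0.1)
        assert stats.pearsonr(dhbo, g)[0] == pytest.approx(1.0, abs=1e-12)

    def test_hbo_hbr_anticorrelated(self):
        """Coupled-channel ΔHbO and ΔHbR are negatively correlated under
        the default noise model (checked over 20 seeds)."""
        cfg = tiny_config()
        t, g = fg.generate_glucose_curve(cfg, 0)
        for seed in range(20):
            dhbo, dhbr, _ = fg.hemo_forward_model(t, g, cfg, channel=2,
                                                  rng=seed)
            assert stats.pearsonr(dhbo, dhbr)[0] < 0


class TestForwardMBLL:
    def test_zero_concentration_gives_baseline(self):
        I = fg.forward_mbll_intensity(np.zeros(50), np.zeros(50),
                                      baseline_intensity=0.25)
        np.testing.assert_allclose(I, 0.25, atol=1e-15)

    def test_round_trip_inversion(self):
        rng = np.random.default_rng(0)
        dhbo = rng.normal(0, 1.0, 200)
        dhbr = rng.normal(0, 0.5, 200)
        od = fg.forward_mbll_od(dhbo, dhbr)
        rec_o, rec_r = fg.mbll_invert(od)
        np.testing.assert_allclose(rec_o, dhbo, atol=1e-10)
        np.testing.assert_allclose(rec_r, dhbr, atol=1e-10)

    def test_pathlength_linearity(self):
        o1 = fg.forward_mbll_od([1.0], [-0.5], fg.OpticsModel(dpf=(6.0, 6.0)))
        o2 = fg.forward_mbll_od([1.0], [-0.5], fg.OpticsModel(dpf=(12.0, 12.0)))
        np.testing.assert_allclose(o2, 2.0 * o1, rtol=1e-14)

    def test_singular_extinction_rejected(self):
        bad = fg.OpticsModel(extinction=((1.0, 2.0), (0.5, 1.0)))
        with pytest.raises(fg.OpticsError):
            fg.forward_mbll_od([1.0], [0.0], bad)


class TestArtifacts:
    def test_zero_rates_identity(self):
        cfg = tiny_config(artifact_spike_rate=0.0, artifact_shift_rate=0.0)
        x = np.linspace(1.0, 2.0, 500)
        out, log = fg.inject_artifacts(x, cfg, 0)
        np.testing.assert_array_equal(out, x)
        assert log == []

    def test_poisson_event_count(self):
        """6 spikes/min over 10 min → count inside the Poisson(60) 99%
        interval."""
        cfg = tiny_config(artifact_spike_rate=6.0, artifact_shift_rate=0.0,
                          sampling_rate=10.0)
        x = np.ones(6000)  # 600 s at 10 Hz
        _, log = fg.inject_artifacts(x, cfg, 2024)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 60)
        assert lo <= len(log) <= hi

    def test_event_log_deterministic(self):
        cfg = tiny_config()
        x = np.ones((800, 2))
        _, log1 = fg.inject_artifacts(x, cfg, 99)
        _, log2 = fg.inject_artifacts(x, cfg, 99)
        assert log1 == log2


class TestCohort:
    def test_cohort_structure_matches_study_design(self):
        """15 subjects × 2 states × 21 channels × 2 wavelengths with the
        fasting block exactly fasting_duration × sampling_rate samples."""
        cfg = fg.SyntheticConfig(rng_seed=5)
        cohort = fg.generate_cohort(cfg)
        assert len(cohort) == 15
        for sub in cohort:
            assert sub.fasting.intensity.shape == (6000, 21, 2)
            assert sub.glucose.intensity.shape == (36000, 21, 2)
            assert sub.truth is not None
            # coupling confined to the configured channels
            coupled = np.flatnonzero(sub.truth.betas > 0) + 1
            assert set(coupled) <= set(cfg.coupled_channels)

    def test_bit_identical_under_same_seed(self, small_cohort):
        again = fg.generate_cohort(tiny_config())
        for a, b in zip(small_cohort, again):
            np.testing.assert_array_equal(a.fasting.intensity,
                                          b.fasting.intensity)
            np.testing.assert_array_equal(a.glucose.intensity,
                                          b.glucose.intensity)
            np.testing.assert_array_equal(
                a.glucose_refs["glucose_mmol_per_l"].to_numpy(),
                b.glucose_refs["glucose_mmol_per_l"].to_numpy())

    def test_coupled_channels_carry_larger_state_contrast(self):
        """Across 20 replicates the true fasting-vs-glucose mean-ΔHbO gap
        is larger on coupled channels than on uncoupled ones."""
        gaps_c, gaps_u = [], []
        for seed in range(20):
            cfg = tiny_config(seed=seed)
            sub = fg.generate_cohort(cfg).subjects[0]
            n_f = cfg.n_samples(cfg.fasting_duration)
            gap = np.abs(sub.truth.dhbo[n_f:].mean(axis=0)
                         - sub.truth.dhbo[:n_f].mean(axis=0))
            coupled = sub.truth.betas > 0
            gaps_c.append(gap[coupled].mean())
            gaps_u.append(gap[~coupled].mean())
        assert np.mean(gaps_c) > np.mean(gaps_u)

    def test_serialization_round_trip(self, small_cohort, tmp_path):
        fg.write_cohort(small_cohort, tmp_path / "c")
        back = fg.read_cohort(tmp_path / "c")
        assert len(back) == len(small_cohort)
        for a, b in zip(small_cohort, back):
            np.testing.assert_array_equal(a.fasting.intensity,
                                          b.fasting.intensity)
            np.testing.assert_array_equal(a.glucose.times, b.glucose.times)
        # second write is byte-identical
        fg.write_cohort(back, tmp_path / "c2")
        for name in ("intensity.csv", "glucose.csv"):
            assert (tmp_path / "c" / name).read_bytes() == \
                (tmp_path / "c2" / name).read_bytes()
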