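"""Generator: determinism, calibration bands, adaptive labels, serialization."""

import dataclasses

import numpy as np
import pytest

from yolobt import synthetic_eeg as se


class TestGenerateBackground:
    def test_seeded_determinism(self):
        cfg = se.GenConfig(seed=42)
        s1, s2 = se.generate_background(cfg), se.generate_background(cfg)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_different_seeds_differ(self):
        a = se.generate_background(se.GenConfig(seed=1))
        b = se.generate_background(se.GenConfig(seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_zero_noise_limit_is_erp_template(self):
        cfg = se.GenConfig(noise_gain=0.0, quality_level=1.0, seed=9)
        s = se.generate_background(cfg)
        tpl = se.erp_template(cfg)
        np.testing.assert_allclose(s.data, np.broadcast_to(
            tpl, s.data.shape), atol=1e-12)

    def test_clean_trials_occupy_lowest_band(self):
        # Monte-Carlo calibration: default noise_gain keeps the median trial
        # Max PTP at or below the 500 uV band edge over many seeded screens
        medians = []
        for seed in range(100):
            s = se.generate_background(se.GenConfig(seed=seed))
            medians.append(np.median(s.trial_stats[:, 0]))
        assert np.median(medians) <= 500.0

    def test_invalid_config_rejected(self):
        with pytest.raises(se.ConfigurationError):
            se.GenConfig(sfreq=0)
        with pytest.raises(se.ConfigurationError):
            se.GenConfig(trial_len=-1)
        with pytest.raises(se.ConfigurationError):
            se.GenConfig(quality_level=1.5)
        with pytest.raises(se.ConfigurationError):
            se.GenConfig(trials_per_screen=8)

    def test_all_labels_good(self, clean_screen):
        assert not clean_screen.trial_labels.any()
        assert np.isfinite(clean_screen.data).all()


class TestInjectArtifact:
    def test_zero_amplitude_identity(self, clean_screen):
        spec = se.ArtifactSpec("emg", (0,), 0.2, 0.3, 0.0)
        out = se.inject_artifact(clean_screen, 2, spec)
        np.testing.assert_array_equal(out.data, clean_screen.data)

    def test_locality(self, clean_screen):
        cfg = clean_screen.config
        spec = se.ArtifactSpec("signal_noise", (1, 3), 0.2, 0.3, 1000.0)
        out = se.inject_artifact(clean_screen, 4, spec)
        diff = out.data != clean_screen.data
        # untouched trials bitwise identical
        assert not diff[:, [t for t in range(10) if t != 4], :].any()
        # unlisted channels bitwise identical
        assert not diff[[c for c in range(cfg.n_channels) if c not in (1, 3)],
                        4, :].any()
        # samples outside the window untouched
        i0 = int(0.2 * cfg.sfreq)
        i1 = i0 + int(0.3 * cfg.sfreq)
        assert not diff[1, 4, :i0].any() and not diff[1, 4, i1 + 1:].any()

    def test_emg_4000uv_exceeds_severe_band(self, clean_screen):
        spec = se.ArtifactSpec("emg", (2,), 0.1, 0.4, 4000.0)
        out = se.inject_artifact(clean_screen, 0, spec)
        # brute-force max-min over samples of the modified trial
        ptp = max((out.data[c, 0].max() - out.data[c, 0].min())
                  for c in range(out.data.shape[0]))
        assert ptp > 3000.0
        assert out.trial_stats[0, 0] == pytest.approx(ptp)

    def test_out_of_range_rejected(self, clean_screen):
        spec = se.ArtifactSpec("emg", (0,), 0.1, 0.2, 100.0)
        with pytest.raises(IndexError):
            se.inject_artifact(clean_screen, 99, spec)
        bad = se.ArtifactSpec("emg", (10_000,), 0.1, 0.2, 100.0)
        with pytest.raises(IndexError):
            se.inject_artifact(clean_screen, 0, bad)

    def test_invalid_spec_rejected(self):
        with pytest.raises(se.ConfigurationError):
            se.ArtifactSpec("blink", (0,), 0.1, 0.2, 10.0)
        with pytest.raises(se.ConfigurationError):
            se.ArtifactSpec("emg", (0,), 0.1, -0.2, 10.0)
        with pytest.raises(se.ConfigurationError):
            se.ArtifactSpec("emg", (0,), 0.1, 0.2, -1.0)


class TestCalibrateSeverity:
    @pytest.mark.parametrize("kind", se.ARTIFACT_KINDS)
    def test_severe_band(self, kind):
        cfg = se.GenConfig(seed=5)
        spec = se.calibrate_severity(kind, "severe", cfg)
        out = se.inject_artifact(se.generate_background(cfg), 3, spec)
        assert out.trial_stats[3, 0] > 3000.0

    @pytest.mark.parametrize("kind", se.ARTIFACT_KINDS)
    def test_moderate_band(self, kind):
        cfg = se.GenConfig(seed=6)
        spec = se.calibrate_severity(kind, "moderate", cfg)
        out = se.inject_artifact(se.generate_background(cfg), 7, spec)
        assert 500.0 < out.trial_stats[7, 0] <= 3000.0

    def test_clean_band(self):
        cfg = se.GenConfig(seed=7)
        spec = se.calibrate_severity("emg", "clean", cfg)
        assert spec.amplitude == 0.0

    def test_severe_amplitude_exceeds_moderate(self):
        cfg = se.GenConfig(seed=8)
        sev = se.calibrate_severity("movement", "severe", cfg)
        mod = se.calibrate_severity("movement", "moderate", cfg)
        assert sev.amplitude > mod.amplitude

    def test_unreachable_band_raises(self):
        noisy = se.GenConfig(quality_level=0.0, seed=3)
        with pytest.raises(se.CalibrationError):
            se.calibrate_severity("emg", "clean", noisy)

    def test_unknown_band_rejected(self):
        with pytest.raises(se.ConfigurationError):
            se.calibrate_severity("emg", "catastrophic", se.GenConfig())


class TestComputeTrialStats:
    def _blank(self, nch=4):
        cfg = se.GenConfig(n_channels=nch, noise_gain=0, erp_amplitude=0)
        s = se.generate_background(cfg)
        s.data[:] = 0.0
        return s

    def test_constant_signal_zero_stats(self):
        s = self._blank()
        s.data[:] = 7.5
        stats = se.compute_trial_stats(s)
        np.testing.assert_allclose(stats, 0.0)

    def test_single_spike(self):
        s = self._blank()
        s.data[2, 5, 100] = 123.0
        stats = se.compute_trial_stats(s)
        assert stats[5, 0] == pytest.approx(123.0)

    def test_bad_channel_excluded(self):
        s = self._blank()
        base = se.compute_trial_stats(s)[3, 0]
        s.bad_channel_mask[1] = True
        s.data[1, 3, 10] = 9999.0
        assert se.compute_trial_stats(s)[3, 0] == pytest.approx(base)

    def test_all_bad_channels_error(self):
        s = self._blank()
        s.bad_channel_mask[:] = True
        with pytest.raises(se.StatsError):
            se.compute_trial_stats(s)


class TestMakeScreenDataset:
    def test_ten_trials_per_screen(self):
        screens = se.make_screen_dataset(se.GenConfig(n_channels=8, seed=1), 5,
                                         {"clean": 0.5, "severe": 0.5})
        assert all(s.data.shape[1] == 10 for s in screens)
        assert all(len(s.trial_labels) == 10 for s in screens)

    def test_all_clean_no_bad_labels(self):
        screens = se.make_screen_dataset(se.GenConfig(n_channels=8, seed=2), 5,
                                         {"clean": 1.0})
        assert not any(s.trial_labels.any() for s in screens)

    def test_bad_fraction_tracks_mix(self):
        # Monte-Carlo: on clean backgrounds the realized bad fraction tracks
        # the requested non-clean proportion within +-5 percentage points
        screens = se.make_screen_dataset(
            se.GenConfig(n_channels=16, seed=3), 200,
            {"clean": 0.7, "moderate": 0.15, "severe": 0.15},
            quality_range=(0.9, 1.0))
        frac = np.concatenate([s.trial_labels for s in screens]).mean()
        assert abs(frac - 0.30) <= 0.05

    def test_invalid_args(self):
        with pytest.raises(se.ConfigurationError):
            se.make_screen_dataset(se.GenConfig(), 0, {"clean": 1.0})
        with pytest.raises(se.ConfigurationError):
            se.make_screen_dataset(se.GenConfig(), 2, {"clean": 0.4})

    def test_determinism(self):
        cfg = se.GenConfig(n_channels=8, seed=4)
        mix = {"clean": 0.6, "severe": 0.4}
        a = se.make_screen_dataset(cfg, 3, mix)
        b = se.make_screen_dataset(cfg, 3, mix)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)
            np.testing.assert_array_equal(x.trial_labels, y.trial_labels)


class TestAdaptiveLabeling:
    def test_moderate_bad_on_clean_good_on_noisy(self):
        spec = se.ArtifactSpec("eye_movement", (2, 3), 0.2, 0.5, 1200.0)
        clean_cfg = se.GenConfig(n_channels=16, quality_level=1.0, seed=21)
        noisy_cfg = se.GenConfig(n_channels=16, quality_level=0.0, seed=21)
        s_clean = se.inject_artifact(se.generate_background(clean_cfg), 4, spec)
        s_noisy = se.inject_artifact(se.generate_background(noisy_cfg), 4, spec)
        lab_clean = se.adaptive_labels(s_clean, {4})
        lab_noisy = se.adaptive_labels(s_noisy, {4})
        med_noisy = np.median(np.delete(s_noisy.trial_stats[:, 0], 4))
        assert med_noisy > spec.amplitude / 3.0
        assert lab_clean[4]
        assert not lab_noisy[4]

    def test_severe_bad_everywhere(self):
        spec = se.ArtifactSpec("emg", (1,), 0.1, 0.5, 6000.0)
        for q in (0.0, 1.0):
            cfg = se.GenConfig(n_channels=16, quality_level=q, seed=22)
            s = se.inject_artifact(se.generate_background(cfg), 2, spec)
            assert se.adaptive_labels(s, {2})[2]


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        screens = se.make_screen_dataset(
            se.GenConfig(n_channels=8, seed=13), 3,
            {"clean": 0.5, "moderate": 0.25, "severe": 0.25})
        se.save_screens(screens, tmp_path / "ds")
        loaded = se.load_screens(tmp_path / "ds")
        assert len(loaded) == len(screens)
        for a, b in zip(screens, loaded):
            np.testing.assert_allclose(a.data, b.data, rtol=1e-6)
            np.testing.assert_array_equal(a.trial_labels, b.trial_labels)
            np.testing.assert_array_equal(a.bad_channel_mask, b.bad_channel_mask)
            assert len(a.injected) == len(b.injected)
            assert a.config == b.config
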