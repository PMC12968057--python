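"""Synthetic source and scene generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, hilbert, periodogram, sosfiltfilt, welch

from rumblekit import synth
from rumblekit.synth import (
    AliasingError,
    FootfallSpec,
    NoiseModel,
    RumbleSpec,
    SceneConfig,
)


class TestSynthRumble:
    def test_band_energy_in_fundamental_and_harmonic_bands(self):
        """A call at 18 Hz with one overtone puts its band-power maxima in
        the 10-25 Hz fundamental and 25-45 Hz first-harmonic bands."""
        spec = RumbleSpec(0.0, 18.0, 4.0, n_harmonics=1, harmonic_decay=0.5,
                          peak_ground_velocity=5.0)
        seg = synth.synth_rumble(spec, 200.0)
        f, p = periodogram(seg, fs=200.0)
        fund = (f >= 10) & (f <= 25)
        harm = (f > 25) & (f <= 45)
        rest = ~(fund | harm)
        assert p[fund].max() > p[rest].max()
        assert p[harm].max() > p[rest].max()

    def test_zero_amplitude_gives_zero_segment(self):
        spec = RumbleSpec(0.0, 18.0, 4.0, peak_ground_velocity=0.0)
        assert not synth.synth_rumble(spec, 200.0).any()

    def test_instantaneous_frequency_peaks_at_apex(self):
        """Analytic-signal phase derivative on the isolated fundamental
        reaches the apex frequency at the call centre (oracle)."""
        spec = RumbleSpec(0.0, 20.0, 4.0, n_harmonics=0, contour_depth=0.1,
                          peak_ground_velocity=5.0)
        seg = synth.synth_rumble(spec, 200.0)
        sos = butter(4, [10, 30], btype="bandpass", fs=200, output="sos")
        fund = sosfiltfilt(sos, seg)
        phase = np.unwrap(np.angle(hilbert(fund)))
        f_inst = np.diff(phase) / (2 * np.pi) * 200.0
        mid = f_inst[len(f_inst) // 4 : 3 * len(f_inst) // 4]
        assert abs(mid.max() - 20.0) <= 0.5

    def test_aliasing_harmonic_rejected(self):
        spec = RumbleSpec(0.0, 24.0, 4.0, n_harmonics=4)  # 120 Hz > Nyquist
        with pytest.raises(AliasingError):
            synth.synth_rumble(spec, 200.0)

    def test_peak_amplitude_calibrated_per_domain(self):
        spec = RumbleSpec(0.0, 15.0, 3.0, peak_ground_velocity=7.0,
                          peak_pressure=0.04)
        seis = synth.synth_rumble(spec, 200.0, "seismic")
        infra = synth.synth_rumble(spec, 200.0, "infrasound")
        assert np.max(np.abs(seis)) == pytest.approx(7.0)
        assert np.max(np.abs(infra)) == pytest.approx(0.04)

    def test_spectral_placement_of_random_specs(self):
        """Fundamental band-power maximum lands within one spectral bin of
        the apex for at least 99 of 100 prior draws (periodogram oracle)."""
        rng = np.random.default_rng(123)
        ok = 0
        for _ in range(100):
            spec = synth.draw_rumble_spec(rng, 0.0)
            iso = RumbleSpec(0.0, spec.apex_frequency, spec.duration,
                             n_harmonics=0, harmonic_decay=1.0,
                             peak_ground_velocity=5.0,
                             contour_depth=spec.contour_depth)
            seg = synth.synth_rumble(iso, 200.0)
            f, p = periodogram(seg, fs=200.0)
            ok += abs(f[np.argmax(p)] - spec.apex_frequency) <= 1.0 / spec.duration
        assert ok >= 99

    def test_prior_draws_respect_observed_ranges(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            s = synth.draw_rumble_spec(rng, 0.0)
            assert 10.0 <= s.apex_frequency <= 25.0
            assert 1.0 <= s.duration <= 8.0
            assert 1.0 <= s.peak_ground_velocity <= 10.0


class TestSynthFootfall:
    def test_mostly_high_frequency_energy(self):
        """The damped broadband impulse keeps at least half its energy
        above 20 Hz (band-energy oracle on the default pulse shape)."""
        seg = synth.synth_footfall(FootfallSpec(0.0, 0.1, 8.0), 200.0, seed=1)
        f, p = periodogram(seg, fs=200.0)
        assert p[f > 20].sum() / p.sum() >= 0.5

    def test_zero_peak_gives_zeros(self):
        seg = synth.synth_footfall(
            FootfallSpec(0.0, 0.1, peak_ground_velocity=0.0), 200.0, seed=1
        )
        assert not seg.any()

    def test_deterministic_given_seed(self):
        spec = FootfallSpec(0.0, 0.2, 5.0)
        a = synth.synth_footfall(spec, 200.0, seed=9)
        b = synth.synth_footfall(spec, 200.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_short_impulse_rejected(self):
        with pytest.raises(ValueError):
            synth.synth_footfall(FootfallSpec(0.0, 0.01), 200.0)


class TestSynthNoise:
    def test_night_rms_matches_model(self, night_clock):
        model = NoiseModel()
        seg = synth.synth_noise(model, "seismic", 0, 3600, night_clock, seed=1)
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(
            model.night_rms_seismic, rel=0.05
        )

    def test_day_night_rms_ratio_tracks_day_factor(self, night_clock, day_clock):
        model = NoiseModel(day_factor_seismic=7.0)
        night = synth.synth_noise(model, "seismic", 0, 3600, night_clock, seed=1)
        day = synth.synth_noise(model, "seismic", 0, 3600, day_clock, seed=1)
        ratio = np.sqrt(np.mean(day**2)) / np.sqrt(np.mean(night**2))
        assert ratio == pytest.approx(7.0, rel=0.10)

    def test_daytime_machine_lines_stand_out(self, day_clock):
        """Machine lines at 12/25/30 Hz exceed neighbouring spectral bins
        by at least 10 dB in daytime seismic noise."""
        model = NoiseModel()
        seg = synth.synth_noise(model, "seismic", 0, 3600, day_clock, seed=2)
        f, p = welch(seg, fs=200.0, nperseg=1600)
        for line in (12.0, 25.0, 30.0):
            at = p[np.argmin(np.abs(f - line))]
            neighbour = p[np.argmin(np.abs(f - (line + 2.0)))]
            assert 10 * np.log10(at / neighbour) >= 10.0

    def test_infrasound_noise_carries_no_machine_lines(self, day_clock):
        model = NoiseModel()
        seg = synth.synth_noise(model, "infrasound", 0, 3600, day_clock, seed=2)
        f, p = welch(seg, fs=200.0, nperseg=1600)
        at = p[np.argmin(np.abs(f - 12.0))]
        neighbour = p[np.argmin(np.abs(f - 14.0))]
        assert 10 * np.log10(at / neighbour) < 6.0

    def test_invalid_window_rejected(self, night_clock):
        with pytest.raises(ValueError):
            synth.synth_noise(NoiseModel(), "seismic", 10, 10, night_clock, 1)


class TestRenderScene:
    def test_truth_catalog_bookkeeping(self):
        """Explicitly injected sources come back in the truth catalog with
        exactly the injected counts."""
        rumbles = [RumbleSpec(50.0 + 20 * i, 15.0, 3.0) for i in range(20)]
        feet = [FootfallSpec(30.0 + 25 * i, 0.1, 5.0) for i in range(15)]
        cfg = SceneConfig(duration=600.0, seed=1, rumble_specs=rumbles,
                          footfall_specs=feet)
        bundle = synth.render_scene(cfg)
        assert len(bundle.truth.rumbles) == 20
        assert len(bundle.truth.footfalls) == 15
        df = bundle.truth.to_frame()
        assert (df["type"] == "rumble").sum() == 20
        assert df["onset_time"].is_monotonic_increasing

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(duration=300.0, seed=11)
        a, b = synth.render_scene(cfg), synth.render_scene(cfg)
        for tr_a, tr_b in zip(a.seismic + [a.infrasound], b.seismic + [b.infrasound]):
            np.testing.assert_array_equal(tr_a.data, tr_b.data)

    def test_different_seeds_differ(self):
        base = dict(duration=300.0, rumble_specs=[RumbleSpec(100.0, 15.0, 3.0)],
                    footfall_specs=[])
        a = synth.render_scene(SceneConfig(seed=1, **base))
        b = synth.render_scene(SceneConfig(seed=2, **base))
        assert not np.array_equal(a.seismic_Z.data, b.seismic_Z.data)
        assert len(a.truth.rumbles) == len(b.truth.rumbles) == 1

    def test_rumble_vector_amplitude_calibration(self):
        """The vector-sum seismic amplitude of an isolated call matches the
        spec's peak ground velocity within 2 %."""
        spec = RumbleSpec(100.0, 15.0, 4.0, peak_ground_velocity=6.0)
        cfg = SceneConfig(duration=300.0, seed=3, rumble_specs=[spec],
                          footfall_specs=[],
                          noise=NoiseModel(night_rms_seismic=1e-4,
                                           night_rms_infrasound=1e-6))
        b = synth.render_scene(cfg)
        mag = np.sqrt(sum(tr.data**2 for tr in b.seismic))
        assert mag.max() == pytest.approx(6.0, rel=0.02)

    def test_footfalls_absent_from_infrasound(self):
        """A footfall-only scene leaves the pressure channel at its noise
        floor while the seismic channels carry the impulses."""
        feet = [FootfallSpec(20.0 + 10 * i, 0.15, 8.0) for i in range(10)]
        cfg = SceneConfig(duration=200.0, seed=4, rumble_specs=[],
                          footfall_specs=feet)
        b = synth.render_scene(cfg)
        seis_peak = max(np.abs(tr.data).max() for tr in b.seismic)
        assert seis_peak > 10 * b.config.noise.night_rms_seismic
        infra_rms = b.infrasound.rms()
        assert infra_rms == pytest.approx(
            b.config.noise.night_rms_infrasound, rel=0.1
        )

    def test_scheduled_scene_respects_housing_nights(self):
        """With an alternating housing schedule, active nights carry more
        calls than quiet nights (rate factor 4 vs 1)."""
        cfg = SceneConfig(duration=2 * 86400.0, seed=6, rumble_rate=12.0,
                          footfall_coupling=0.0,
                          housing_schedule=(1.0, 4.0))
        rng_specs = synth._schedule_rumbles(cfg, np.random.default_rng(6))
        onsets = np.array([s.onset_time for s in rng_specs])
        night1 = ((onsets % 86400 < 7 * 3600) | (onsets % 86400 >= 17 * 3600)) & (
            onsets < 86400
        )
        night2 = ((onsets % 86400 < 7 * 3600) | (onsets % 86400 >= 17 * 3600)) & (
            onsets >= 86400
        )
        assert night2.sum() > 2 * night1.sum()


class TestSceneConfigIO:
    def test_yaml_roundtrip_and_mandatory_seed(self, tmp_path):
        p = tmp_path / "scene.yaml"
        p.write_text(
            "duration: 600\nseed: 42\nrumble_rate: 20\n"
            "noise:\n  day_factor_seismic: 8\n  opening_hours: [7, 17]\n"
        )
        cfg = SceneConfig.from_file(p)
        assert cfg.seed == 42
        assert cfg.noise.day_factor_seismic == 8

        bad = tmp_path / "bad.yaml"
        bad.write_text("duration: 600\n")
        with pytest.raises(ValueError, match="seed"):
            SceneConfig.from_file(bad)

    def test_scene_write_and_truth_csv(self, tmp_path, small_scene):
        paths = small_scene.write(tmp_path / "scene")
        df = pd.read_csv(paths["truth"])
        assert set(df.columns) == {
            "type", "onset_time", "apex_frequency", "duration", "peak_amplitude"
        }
        assert len(df) == len(small_scene.truth.rumbles) + len(
            small_scene.truth.footfalls
        )
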