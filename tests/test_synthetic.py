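"""Tests of the synthetic plantar-pressure generator."""

import warnings

import numpy as np
import pytest
from scipy.signal import argrelmax, argrelmin

from gaitmse import (
    GaitGeneratorConfig,
    SensorLayout,
    generate_cycle_waveform,
    generate_paired_plate_signal,
    generate_recording,
    speed_preset,
)
from gaitmse.errors import ConfigurationError, InvalidParameterError
from gaitmse.synthetic import STANCE_FRACTION


def _config(**kw):
    defaults = dict(speed_kmh=4.0, n_cycles=10, seed=0)
    defaults.update(kw)
    return GaitGeneratorConfig(**defaults)


class TestCycleWaveform:
    def test_zero_amplitude_gives_zero_cycle(self, layout):
        cfg = _config(
            region_amplitude_scale={"hindfoot": 0.0, "midfoot": 0.0, "forefoot": 0.0}
        )
        wave = generate_cycle_waveform(cfg, layout, 1.1)
        assert np.all(wave == 0)

    def test_swing_phase_is_exactly_zero(self, layout):
        cfg = _config()
        wave = generate_cycle_waveform(cfg, layout, cfg.mean_stride_s)
        n = wave.shape[0]
        n_stance = int(round(STANCE_FRACTION * n))
        assert np.all(wave[n_stance:] == 0)
        assert np.all(wave >= 0)

    def test_regional_peak_ordering_within_stance(self, layout):
        cfg = _config()
        wave = generate_cycle_waveform(cfg, layout, cfg.mean_stride_s)
        peak_time = {}
        for region in ("hindfoot", "midfoot", "forefoot"):
            idx = layout.sensors_in(region)
            peak_time[region] = int(np.argmax(wave[:, idx].mean(axis=1)))
        assert peak_time["hindfoot"] < peak_time["midfoot"] < peak_time["forefoot"]

    @pytest.mark.parametrize("speed", [2, 4, 6])
    def test_total_has_exactly_two_stance_peaks(self, layout, speed):
        cfg = speed_preset(speed, noise_sd=0.0)
        wave = generate_cycle_waveform(cfg, layout, cfg.mean_stride_s)
        total = wave.sum(axis=1)
        n_stance = int(round(STANCE_FRACTION * len(total)))
        stance = total[:n_stance]
        maxima = argrelmax(stance)[0]
        interior_minima = argrelmin(stance)[0]
        assert maxima.size == 2
        assert interior_minima.size == 1
        assert maxima[0] < interior_minima[0] < maxima[1]

    def test_invalid_stride_raises(self, layout):
        with pytest.raises(InvalidParameterError):
            generate_cycle_waveform(_config(), layout, 0.0)
        with pytest.raises(InvalidParameterError):
            generate_cycle_waveform(_config(), layout, -1.0)


class TestRecording:
    def test_noiseless_recording_has_constant_strides(self, layout):
        cfg = _config(jitter_sd_s=0.0, noise_sd=0.0, n_cycles=20)
        rec = generate_recording(cfg, layout)
        durations = rec.meta["cycle_duration_s"]
        np.testing.assert_allclose(durations, cfg.mean_stride_s, atol=1.0 / cfg.fs_hz)

    def test_determinism_bit_exact(self, layout):
        cfg = _config(jitter_sd_s=0.02, noise_sd=0.5, n_cycles=15)
        rec1 = generate_recording(cfg, layout)
        rec2 = generate_recording(cfg, layout)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)

    def test_nonnegative_samples(self, layout):
        cfg = _config(noise_sd=2.0, n_cycles=15, seed=11)
        rec = generate_recording(cfg, layout)
        assert rec.samples.min() >= 0

    def test_short_recording_warns(self, layout):
        with pytest.warns(UserWarning, match="too short"):
            generate_recording(_config(n_cycles=2), layout)

    def test_programmed_jitter_sd_recovered(self, layout):
        # Monte-Carlo across seeds: realized stride SD tracks jitter_sd_s
        target = 0.02
        sds = []
        for seed in range(20):
            cfg = _config(jitter_sd_s=target, noise_sd=0.0, n_cycles=200, seed=seed)
            rec = generate_recording(cfg, layout)
            sds.append(np.std(rec.meta["cycle_duration_s"], ddof=1))
        assert abs(np.mean(sds) - target) / target < 0.3

    def test_ar1_jitter_is_autocorrelated(self, layout):
        cfg = _config(
            jitter_structure="autocorrelated",
            jitter_ar1_phi=0.9,
            jitter_sd_s=0.02,
            noise_sd=0.0,
            n_cycles=300,
        )
        d = generate_recording(cfg, layout).meta["programmed_duration_s"]
        e = d - np.mean(d)
        lag1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert lag1 > 0.7


class TestPairedPlate:
    def _two_peak_cycle(self):
        cfg = speed_preset(2, noise_sd=0.0)
        wave = generate_cycle_waveform(cfg, SensorLayout.default(), cfg.mean_stride_s)
        return wave.sum(axis=1)

    def test_identity_when_no_distortion(self):
        total = self._two_peak_cycle()
        out = generate_paired_plate_signal(total, bias=0.0, noise_sd=0.0, second_peak_attenuation=1.0)
        np.testing.assert_array_equal(out, total)

    def test_attenuation_scales_only_second_peak(self):
        from gaitmse import segment_stance

        total = self._two_peak_cycle()
        lm = segment_stance(total)
        out = generate_paired_plate_signal(total, second_peak_attenuation=1.1)
        assert out[lm.second_peak_idx] == pytest.approx(1.1 * total[lm.second_peak_idx])
        assert out[lm.first_peak_idx] == total[lm.first_peak_idx]

    def test_noise_mean_absolute_difference(self):
        # |N(0, sigma)| has mean sigma * sqrt(2/pi)
        total = self._two_peak_cycle()
        sigma = 2.0
        mads = []
        for seed in range(30):
            out = generate_paired_plate_signal(total, noise_sd=sigma, seed=seed)
            mads.append(np.mean(np.abs(out - total)))
        assert np.mean(mads) == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.1)

    def test_zero_trace_passes_through(self):
        out = generate_paired_plate_signal(np.zeros(100), second_peak_attenuation=1.3)
        np.testing.assert_array_equal(out, np.zeros(100))


class TestPresets:
    def test_stride_duration_decreases_with_speed(self):
        assert speed_preset(2).mean_stride_s > speed_preset(4).mean_stride_s > speed_preset(6).mean_stride_s

    def test_irregularity_increases_with_speed(self):
        assert speed_preset(2).jitter_sd_s < speed_preset(4).jitter_sd_s < speed_preset(6).jitter_sd_s
        assert speed_preset(2).jitter_ar1_phi > speed_preset(4).jitter_ar1_phi > speed_preset(6).jitter_ar1_phi

    def test_forefoot_calibration_ratio(self):
        # 6 km/h forefoot multiplier is 26.7% above the 2 km/h one
        f2 = speed_preset(2).region_amplitude_scale["forefoot"]
        f6 = speed_preset(6).region_amplitude_scale["forefoot"]
        assert f6 / f2 == pytest.approx(1.267, abs=1e-4)

    def test_unsupported_speed_raises(self):
        with pytest.raises(InvalidParameterError):
            speed_preset(3)
        with pytest.raises(InvalidParameterError):
            speed_preset(0)

    def test_overrides(self):
        cfg = speed_preset(4, n_cycles=10, noise_sd=0.0, seed=7)
        assert cfg.n_cycles == 10 and cfg.noise_sd == 0.0 and cfg.seed == 7


class TestLayoutValidation:
    def test_default_layout_regions(self, layout):
        assert len(layout.sensor_ids) == 8
        for region in ("hindfoot", "midfoot", "forefoot"):
            assert layout.sensors_in(region)

    def test_missing_region_rejected(self):
        with pytest.raises(ConfigurationError):
            SensorLayout(
                tuple(f"s{i}" for i in range(8)),
                tuple("x" for _ in range(8)),
                tuple(["hindfoot"] * 8),
            )

    def test_yaml_round_trip(self, layout, tmp_path):
        path = tmp_path / "layout.yaml"
        layout.to_yaml(path)
        assert SensorLayout.from_yaml(path) == layout


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(fs_hz=0),
            dict(n_cycles=0),
            dict(mean_stride_s=-1),
            dict(jitter_sd_s=-0.1),
            dict(weight_kg=0),
            dict(jitter_structure="pink"),
            dict(region_amplitude_scale={"hindfoot": -1, "midfoot": 1, "forefoot": 1}),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            _config(**kw)
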