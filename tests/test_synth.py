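"""Motion synthesis, noise generation, and sensor-model behaviour."""

import math

import numpy as np
import pytest

from apneasim.synth import (
    BreathingProtocol,
    NoiseModel,
    SensorModel,
    accelerometer_decode,
    accelerometer_read,
    adc_sensitivity,
    breath_boundaries,
    breathing_displacement,
    couple_noise,
    displacement_to_body_accel,
    hammer_noise,
    ir_read,
    simulate_recording,
    strike_waveform,
)

FS = 1000.0


class TestBreathingDisplacement:
    def test_peak_to_peak_equals_amplitude(self):
        p = BreathingProtocol(amplitude_um=1000.0, rate_bpm=40.0, n_breaths=1)
        d = breathing_displacement(p, sample_rate_hz=FS)
        # stepper quantization allows at most half a step of slack
        assert np.ptp(d) == pytest.approx(1000.0, abs=p.step_resolution_um / 2)

    def test_motion_frozen_during_apnea(self):
        p = BreathingProtocol(n_breaths=20, apnea_events=[(7.3, 20.0)])
        d = breathing_displacement(p, sample_rate_hz=FS)
        t = np.arange(len(d)) / FS
        inside = (t >= 7.3) & (t < 27.3)
        assert np.ptp(d[inside]) == 0.0
        # and motion resumes afterwards
        assert np.ptp(d[t >= 27.3]) > 0.0

    def test_values_quantized_to_step_resolution(self):
        p = BreathingProtocol(amplitude_um=731.0, rate_bpm=33.0, n_breaths=4)
        d = breathing_displacement(p, sample_rate_hz=FS)
        steps = d / p.step_resolution_um
        assert np.allclose(steps, np.round(steps), atol=1e-6)

    def test_commanded_breath_count_conserved(self):
        p = BreathingProtocol(n_breaths=7, apnea_events=[(2.0, 20.0)])
        bounds = breath_boundaries(p)
        assert len(bounds) == 7
        # windows are ordered, non-overlapping, and cover breathing time
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            assert a1 <= b0 and a0 < a1

    def test_apnea_shifts_later_breath_boundaries(self):
        period = 60.0 / 40.0
        p = BreathingProtocol(rate_bpm=40.0, n_breaths=4,
                              apnea_events=[(2 * period, 20.0)])
        bounds = breath_boundaries(p)
        assert bounds[1] == (period, 2 * period)
        assert bounds[2][0] == pytest.approx(2 * period + 20.0)

    def test_overlapping_apneas_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BreathingProtocol(apnea_events=[(5.0, 20.0), (10.0, 20.0)])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate_bpm"):
            BreathingProtocol(rate_bpm=0.0)

    def test_too_short_duration_rejected(self):
        p = BreathingProtocol(n_breaths=10)
        with pytest.raises(ValueError, match="does not cover"):
            breathing_displacement(p, duration_s=5.0, sample_rate_hz=FS)


class TestBodyProjection:
    @pytest.fixture
    def disp(self):
        p = BreathingProtocol(amplitude_um=1000.0, n_breaths=4)
        return breathing_displacement(p, sample_rate_hz=FS)

    def test_supine_puts_all_energy_on_z(self, disp):
        axes = displacement_to_body_accel(disp, FS, 90.0, include_gravity=False)
        assert np.allclose(axes[0], 0.0, atol=1e-12)
        assert np.allclose(axes[1], 0.0)
        assert np.ptp(axes[2]) > 0.0

    def test_inclined_positions_mirror_in_x(self, disp):
        a45 = displacement_to_body_accel(disp, FS, 45.0, include_gravity=False)
        a135 = displacement_to_body_accel(disp, FS, 135.0, include_gravity=False)
        assert np.allclose(np.abs(a45[2]), np.abs(a135[2]))
        assert np.allclose(a45[0], -a135[0])

    def test_inclined_position_splits_energy_across_axes(self, disp):
        axes = displacement_to_body_accel(disp, FS, 45.0, include_gravity=False)
        assert np.ptp(axes[0]) > 0.0 and np.ptp(axes[2]) > 0.0

    @pytest.mark.parametrize("angle", [30.0, 45.0, 90.0, 135.0])
    def test_rotation_preserves_energy(self, disp, angle):
        axes = displacement_to_body_accel(disp, FS, angle, include_gravity=False)
        motion = displacement_to_body_accel(disp, FS, 90.0, include_gravity=False)[2]
        assert np.allclose((axes ** 2).sum(axis=0), motion ** 2, atol=1e-18)

    def test_gravity_adds_static_projection(self, disp):
        axes = displacement_to_body_accel(disp, FS, 90.0, include_gravity=True)
        assert np.mean(axes[2]) == pytest.approx(1.0, abs=1e-3)


class TestHammerNoise:
    def test_zero_rate_gives_silence(self):
        out = hammer_noise(NoiseModel(strike_rate_hz=0.0), 10.0, FS, seed=3)
        assert not np.any(out)

    def test_seeded_determinism(self):
        m = NoiseModel()
        a = hammer_noise(m, 30.0, FS, seed=11)
        b = hammer_noise(m, 30.0, FS, seed=11)
        assert np.array_equal(a, b)
        c = hammer_noise(m, 30.0, FS, seed=12)
        assert not np.array_equal(a, c)

    def test_single_strike_envelope_decays_by_e(self):
        m = NoiseModel(decay_tau_s=0.5, ring_freq_hz=40.0)
        fs = 4000.0
        burst = strike_waveform(m, fs)
        # envelope measured as the peak within one ring period
        period = int(fs / m.ring_freq_hz)
        i_tau = int(m.decay_tau_s * fs)
        early = np.max(np.abs(burst[:period]))
        at_tau = np.max(np.abs(burst[i_tau : i_tau + period]))
        assert at_tau / early == pytest.approx(math.exp(-1.0), rel=0.05)

    def test_coupling_identity_and_zero(self):
        ceiling = hammer_noise(NoiseModel(), 20.0, FS, seed=5)
        bed, body = couple_noise(ceiling, NoiseModel(coupling_bed=1.0, coupling_body=0.0))
        assert np.array_equal(bed, ceiling)
        assert not np.any(body)

    def test_coupling_scales_linearly(self):
        ceiling = hammer_noise(NoiseModel(), 20.0, FS, seed=5)
        bed, body = couple_noise(ceiling, NoiseModel(coupling_bed=0.5, coupling_body=0.25))
        assert np.max(np.abs(bed)) == pytest.approx(0.5 * np.max(np.abs(ceiling)))
        assert np.max(np.abs(body)) == pytest.approx(0.25 * np.max(np.abs(ceiling)))
        # amplitude ordering ceiling >= bed >= body additive
        assert np.max(np.abs(ceiling)) >= np.max(np.abs(bed)) >= np.max(np.abs(body))


class TestQuantizer:
    def test_zero_maps_to_mid_scale(self):
        s = SensorModel()
        assert accelerometer_read(np.array([0.0]), s)[0] == 2048

    def test_rail_clipping(self):
        s = SensorModel()
        assert accelerometer_read(np.array([3.0]), s)[0] == 4095
        assert accelerometer_read(np.array([-3.0]), s)[0] == 0
        assert accelerometer_read(np.array([50.0]), s)[0] == 4095

    def test_round_trip_within_half_lsb(self):
        s = SensorModel()
        rng = np.random.default_rng(0)
        x = rng.uniform(-2.99, 2.99, 5000)
        err = np.abs(accelerometer_decode(accelerometer_read(x, s), s) - x)
        assert np.max(err) <= s.lsb_g / 2 + 1e-12  # <= ~0.73 mg

    @pytest.mark.parametrize(
        "bits,range_g,expected",
        [
            (12, 3.0, (682, 1.46)),
            (10, 2.0, (256, 3.9)),
            (10, 1.0, (512, 1.95)),
        ],
    )
    def test_adc_sensitivity_matches_datasheet(self, bits, range_g, expected):
        assert adc_sensitivity(bits, range_g) == expected


class TestIrSensor:
    def test_monotone_decreasing_in_distance(self):
        s = SensorModel(ir_noise_sd_v=0.0)
        v = ir_read(np.array([3.0, 5.0, 10.0, 30.0]), s)
        assert np.all(np.diff(v) < 0)

    def test_unit_voltage_identity(self):
        s = SensorModel(ir_noise_sd_v=0.0)
        d = s.ir_gain_vcm - s.ir_offset_cm
        assert ir_read(np.array([d]), s)[0] == pytest.approx(1.0)

    def test_nonphysical_distance_rejected(self):
        s = SensorModel()
        with pytest.raises(ValueError, match="non-physical"):
            ir_read(np.array([-1.0]), s)

    def test_larger_swing_gives_larger_ir_peak_to_peak(self, sensor, quiet_noise):
        pp = {}
        for disp in (500.0, 1500.0):
            p = BreathingProtocol(amplitude_um=disp, n_breaths=4)
            rec = simulate_recording((90.0, disp), p, quiet_noise,
                                     SensorModel(sample_rate_hz=FS, ir_noise_sd_v=0.0),
                                     seed=1)
            pp[disp] = np.ptp(rec.channels["ir"])
        assert pp[1500.0] > pp[500.0]


class TestSimulateRecording:
    def test_duration_arithmetic(self, quiet_noise, sensor):
        p = BreathingProtocol(
            rate_bpm=40.0, n_breaths=100,
            apnea_events=[(30.0, 20.0), (80.0, 20.0), (130.0, 20.0)],
        )
        assert p.duration_s == pytest.approx(150.0 + 60.0)
        rec = simulate_recording((90.0, 1000.0), p, quiet_noise, sensor, seed=0)
        assert rec.duration_s == pytest.approx(210.0, abs=1e-3)
        assert len(rec.breaths) == 100

    def test_same_seed_identical_recording(self, short_protocol, sensor):
        noise = NoiseModel()
        a = simulate_recording((45.0, 1000.0), short_protocol, noise, sensor, seed=9)
        b = simulate_recording((45.0, 1000.0), short_protocol, noise, sensor, seed=9)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])
        assert a.breaths == b.breaths

    def test_channel_codes_within_adc_range(self, short_protocol, sensor):
        rec = simulate_recording((45.0, 1500.0), short_protocol, NoiseModel(), sensor, 3)
        for ch in ("body_x", "body_y", "body_z", "bed_z", "ceiling_z"):
            assert rec.channels[ch].min() >= 0
            assert rec.channels[ch].max() <= 2 ** sensor.adc_bits - 1

    def test_serialization_round_trip(self, tmp_path, short_protocol, sensor):
        rec = simulate_recording((135.0, 500.0), short_protocol, NoiseModel(), sensor, 4)
        path = tmp_path / "rec.csv"
        rec.save(path)
        back = rec.load(path)
        for ch in rec.channels:
            assert np.allclose(back.channels[ch], rec.channels[ch])
        assert [tuple(b) for b in back.breaths] == [tuple(b) for b in rec.breaths]
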