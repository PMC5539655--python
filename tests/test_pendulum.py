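"""Pendulum rig: dynamics, ray-plane geometry, stream generation."""

import math

import numpy as np
import pytest

from tofbench import (
    NO_HIT,
    PendulumRig,
    ToFSensorSpec,
    generate_condition,
    generate_static,
    line_of_sight_distance,
    simulate_pendulum,
)
from tofbench.pendulum import _refine_peaks


class TestDynamics:
    def test_undamped_peak_matches_energy_conservation(self):
        # uniform rod released from horizontal: peak omega = sqrt(3g/l)
        rig = PendulumRig(imposed_distance_mm=100.0, damping_1_s=0.0)
        _, _, omega = simulate_pendulum(rig, 5.0)
        expected = math.sqrt(3 * rig.gravity_m_s2 / (rig.length_mm / 1000.0))
        assert np.abs(omega).max() == pytest.approx(expected, rel=1e-3)

    def test_undamped_peaks_identical(self):
        rig = PendulumRig(imposed_distance_mm=100.0, damping_1_s=0.0)
        t, th, w = simulate_pendulum(rig, 20.0)
        _, peaks, _ = _refine_peaks(t, th, w)
        assert np.ptp(np.abs(peaks)) < 1e-4

    def test_damped_peaks_strictly_decreasing(self, rig_aoi0):
        t, th, w = simulate_pendulum(rig_aoi0, 40.0)
        _, peaks, _ = _refine_peaks(t, th, w)
        assert np.all(np.diff(np.abs(peaks)) < 0)

    def test_default_damping_gives_about_30_oscillations_in_window(self, rig_aoi0):
        # the analysis window spans peak angular velocities of 1-6 rad/s
        t, th, w = simulate_pendulum(rig_aoi0, 40.0)
        _, peaks, _ = _refine_peaks(t, th, w)
        n = int(np.sum((np.abs(peaks) >= 1.0) & (np.abs(peaks) <= 6.0)))
        assert 25 <= n <= 35

    def test_peak_signs_alternate(self, rig_aoi0):
        t, th, w = simulate_pendulum(rig_aoi0, 40.0)
        _, peaks, _ = _refine_peaks(t, th, w)
        assert np.all(np.sign(peaks[1:]) != np.sign(peaks[:-1]))

    def test_unstable_step_detected(self):
        rig = PendulumRig(imposed_distance_mm=100.0, internal_step_s=1.0,
                          damping_1_s=0.0)
        with pytest.raises(RuntimeError):
            simulate_pendulum(rig, 40.0)


class TestCollisionGuard:
    @pytest.mark.parametrize("aoi,d", [(30.0, 40.0), (-30.0, 60.0), (60.0, 70.0), (-60.0, 99.0)])
    def test_illegal_pairs_rejected(self, aoi, d):
        with pytest.raises(ValueError):
            PendulumRig(imposed_distance_mm=d, aoi_deg=aoi)

    @pytest.mark.parametrize("aoi,d", [(0.0, 40.0), (30.0, 70.0), (-60.0, 100.0)])
    def test_legal_pairs_accepted(self, aoi, d):
        PendulumRig(imposed_distance_mm=d, aoi_deg=aoi)


class TestLineOfSight:
    @pytest.mark.parametrize("aoi", [0.0, 30.0, -30.0, 60.0, -60.0])
    def test_lowest_point_gives_imposed_distance(self, aoi):
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=aoi)
        lowest = rig.sensor_position(0.0)
        assert line_of_sight_distance(lowest, [0, 1, 0], rig) == pytest.approx(100.0)

    def test_lateral_offset_tilted_target(self):
        # 18 mm offset against a 60 deg target adds 18*tan(60) ~ 31.2 mm
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=60.0)
        theta = math.asin(18.0 / rig.length_mm)
        d = line_of_sight_distance(rig.sensor_position(theta), [0, 1, 0], rig)
        assert d == pytest.approx(100.0 + 18.0 * math.tan(math.radians(60)), abs=0.05)

    def test_beyond_face_half_width_is_no_hit(self):
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=0.0)
        theta = math.asin(100.0 / rig.length_mm)  # 100 mm > 90 mm half-width
        assert math.isnan(line_of_sight_distance(rig.sensor_position(theta), [0, 1, 0], rig))

    def test_parallel_ray_is_no_hit(self):
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=0.0)
        assert math.isnan(line_of_sight_distance(rig.sensor_position(0.0), [1, 0, 0], rig))

    @pytest.mark.parametrize("aoi", [30.0, -30.0, 60.0])
    @pytest.mark.parametrize("x_mm", [-25.0, -10.0, 5.0, 25.0])
    def test_linearized_small_offset(self, aoi, x_mm):
        # for small lateral offsets: los - d = x * tan(AoI) within 1%
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=aoi)
        theta = math.asin(x_mm / rig.length_mm)
        d = line_of_sight_distance(rig.sensor_position(theta), [0, 1, 0], rig)
        expected = x_mm * math.tan(math.radians(aoi))
        assert d - 100.0 == pytest.approx(expected, rel=0.01, abs=0.01)


class TestGenerateCondition:
    def test_noiseless_aoi0_constant_trace(self, noiseless_spec, rig_aoi0):
        _, tof, _ = generate_condition(rig_aoi0, noiseless_spec, seed=1)
        assert np.all(tof.values[tof.valid] == 100.0)
        assert tof.valid.any()

    def test_noiseless_tilted_trace_varies(self, noiseless_spec):
        rig = PendulumRig(imposed_distance_mm=100.0, aoi_deg=30.0)
        _, tof, _ = generate_condition(rig, noiseless_spec, seed=1)
        vals = tof.values[tof.valid]
        assert vals.min() < 95.0 < 105.0 < vals.max()

    def test_stream_rates_and_clock(self, noiseless_spec, rig_aoi0):
        gyro, tof, _ = generate_condition(rig_aoi0, noiseless_spec, seed=1, duration_s=10.0)
        assert gyro.rate_hz == 100.0 and tof.rate_hz == 50.0
        assert len(gyro) == 1001 and len(tof) == 501
        assert gyro.times[0] == tof.times[0] == 0.0

    def test_fixed_seed_bit_identical(self, default_spec, rig_aoi0):
        g1, t1, _ = generate_condition(rig_aoi0, default_spec, seed=42, duration_s=10.0)
        g2, t2, _ = generate_condition(rig_aoi0, default_spec, seed=42, duration_s=10.0)
        assert np.array_equal(g1.values, g2.values)
        assert np.array_equal(t1.values, t2.values)

    def test_truth_peak_times_increasing_and_on_target(self, noiseless_spec, rig_aoi0):
        _, _, truth = generate_condition(rig_aoi0, noiseless_spec, seed=1)
        assert np.all(np.diff(truth.peak_times_s) > 0)
        # at every peak the sensor passes (close to) the lowest point
        finite = truth.peak_d_true_mm[np.isfinite(truth.peak_d_true_mm)]
        assert np.allclose(finite, 100.0, atol=1e-6)


class TestGenerateStatic:
    def test_noiseless_readings_equal_distance(self, noiseless_spec):
        s = generate_static(100.0, 0.0, noiseless_spec, seed=1)
        assert np.all(s.values == 100.0)

    def test_mean_within_clt_bound_of_biased_distance(self):
        spec = ToFSensorSpec(noise_sd_mm=1.4, bias_table_mm={0.0: 0.2})
        s = generate_static(100.0, 0.0, spec, seed=3, n=30)
        bound = 3 * 1.4 / math.sqrt(30) + 0.3  # CLT + quantization slack
        assert abs(s.values.mean() - 100.2) < bound

    def test_black_at_160_all_sentinel(self):
        spec = ToFSensorSpec(noise_sd_mm=0.0, color="black")
        s = generate_static(160.0, 0.0, spec, seed=1)
        assert np.all(s.values == 0.0)
        assert not s.valid.any()
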