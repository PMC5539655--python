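"""Marker-based IFD reference geometry and the synthetic gait generator."""

import math

import numpy as np
import pytest

from tofbench.gait import (
    GaitParams,
    MarkerFrame,
    RigidCluster,
    SensorPose,
    TargetPlane,
    calibrate_pose,
    check_cluster_rigidity,
    generate_synthetic_gait,
    phase_means_and_errors,
    reference_ifd,
    reference_series,
)
from tofbench.sensor import ToFSensorSpec
from tofbench.streams import SensorStream


def _identity_frame(extra=None):
    """Clusters whose frames coincide with the world frame."""
    pos = {
        "R1": np.zeros(3), "R2": np.array([100.0, 0, 0]), "R3": np.array([0, 100.0, 0]),
        "L1": np.zeros(3), "L2": np.array([100.0, 0, 0]), "L3": np.array([0, 100.0, 0]),
    }
    if extra:
        pos.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    return MarkerFrame(index=0, time_s=0.0, positions=pos)


_RC = RigidCluster("R1", "R2", "R3")
_LC = RigidCluster("L1", "L2", "L3")


def _plane(point, normal, u=(1.0, 0, 0), half_u=1000.0, half_v=1000.0):
    n = np.asarray(normal, dtype=float)
    u = np.asarray(u, dtype=float)
    return TargetPlane(np.asarray(point, dtype=float), n, u, np.cross(n, u),
                       half_u_mm=half_u, half_v_mm=half_v)


class TestReferenceIfd:
    def test_orthogonal_plane_on_boresight(self):
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        plane = _plane([0, 83.6, 0], [0, -1.0, 0])
        assert reference_ifd(_identity_frame(), pose, plane, _RC, _LC) == pytest.approx(83.6)

    def test_hand_solved_tilted_plane(self):
        # boresight +Y from the origin; plane through (10, 100, 0) with
        # normal (sin30, cos30, 0): t = (10 sin30 + 100 cos30)/cos30 = 105.77
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        a = math.radians(30.0)
        plane = _plane([10.0, 100.0, 0.0], [math.sin(a), math.cos(a), 0.0],
                       u=(math.cos(a), -math.sin(a), 0.0))
        d = reference_ifd(_identity_frame(), pose, plane, _RC, _LC)
        assert d == pytest.approx(10 * math.tan(a) + 100, abs=0.01)
        assert d == pytest.approx(105.77, abs=0.01)

    def test_pivot_about_point_on_boresight(self):
        # tilting the plane about a point that lies on the ray leaves the
        # intersection distance unchanged
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        for tilt in (0.0, 15.0, 40.0):
            a = math.radians(tilt)
            plane = _plane([0.0, 90.0, 0.0], [math.sin(a), math.cos(a), 0.0],
                           u=(math.cos(a), -math.sin(a), 0.0))
            assert reference_ifd(_identity_frame(), pose, plane, _RC, _LC) == pytest.approx(90.0)

    def test_outside_bounds_is_no_hit(self):
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        plane = _plane([150.0, 90.0, 0.0], [0, -1.0, 0], half_u=100.0, half_v=50.0)
        assert math.isnan(reference_ifd(_identity_frame(), pose, plane, _RC, _LC))

    def test_behind_sensor_is_no_hit(self):
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        plane = _plane([0.0, -90.0, 0.0], [0, 1.0, 0])
        assert math.isnan(reference_ifd(_identity_frame(), pose, plane, _RC, _LC))

    def test_parallel_is_no_hit(self):
        pose = SensorPose(np.zeros(3), np.array([0, 1.0, 0]))
        plane = _plane([0.0, 90.0, 0.0], [1.0, 0, 0], u=(0, 1.0, 0))
        assert math.isnan(reference_ifd(_identity_frame(), pose, plane, _RC, _LC))

    def test_invariant_under_rigid_world_motion(self, rng):
        gait = generate_synthetic_gait(GaitParams(n_cycles=2, marker_noise_mm=0.0), seed=5)
        pose, plane = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
        frame = next(
            f for f, v in zip(gait.frames, gait.true_ifd_mm) if np.isfinite(v)
        )
        d0 = reference_ifd(frame, pose, plane, gait.right_cluster, gait.left_cluster)
        # random rotation (QR of a Gaussian matrix) + translation of all markers
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(scale=500.0, size=3)
        moved = MarkerFrame(
            index=frame.index, time_s=frame.time_s,
            positions={k: q @ v + shift for k, v in frame.positions.items()},
        )
        d1 = reference_ifd(moved, pose, plane, gait.right_cluster, gait.left_cluster)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestCalibratePose:
    def test_world_aligned_clusters_pass_through(self):
        frame = _identity_frame(extra={
            "SENS": [50.0, 10.0, 20.0],
            "S1": [20.0, 5.0, 20.0], "S2": [80.0, 5.0, 20.0], "S3": [50.0, 5.0, 60.0],
            # left cluster centroid must sit on the +Y side for the sign rule
            "L1": [0.0, 200.0, 0.0], "L2": [100.0, 200.0, 0.0], "L3": [0.0, 300.0, 0.0],
            "T1": [-40.0, 150.0, 20.0], "T2": [140.0, 150.0, 20.0], "T3": [50.0, 150.0, 70.0],
        })
        pose, plane = calibrate_pose(frame, _RC, _LC)
        assert pose.center_local_mm == pytest.approx([50.0, 10.0, 20.0])
        assert pose.boresight_local == pytest.approx([0.0, 1.0, 0.0])
        # target centroid expressed in the left cluster frame (origin at L1)
        assert plane.point_local_mm == pytest.approx([50.0, -50.0, 36.0 + 2 / 3])
        assert plane.normal_local == pytest.approx([0.0, -1.0, 0.0])

    def test_support_marker_order_does_not_flip_boresight(self):
        gait = generate_synthetic_gait(GaitParams(n_cycles=1, marker_noise_mm=0.0), seed=1)
        p1, _ = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
        p2, _ = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster,
                               support_markers=("S2", "S1", "S3"))
        assert p2.boresight_local == pytest.approx(p1.boresight_local)

    def test_recovery_within_marker_noise(self):
        noiseless = generate_synthetic_gait(GaitParams(n_cycles=1, marker_noise_mm=0.0), seed=2)
        noisy = generate_synthetic_gait(GaitParams(n_cycles=1, marker_noise_mm=0.5), seed=2)
        p0, _ = calibrate_pose(noiseless.static_frame, noiseless.right_cluster, noiseless.left_cluster)
        p1, _ = calibrate_pose(noisy.static_frame, noisy.right_cluster, noisy.left_cluster)
        assert np.linalg.norm(p1.center_local_mm - p0.center_local_mm) < 3.0
        assert p1.boresight_local @ p0.boresight_local > math.cos(math.radians(3.0))

    def test_collinear_triad_rejected(self):
        frame = _identity_frame(extra={
            "SENS": [50.0, 10.0, 20.0],
            "S1": [0.0, 5.0, 0.0], "S2": [10.0, 5.0, 0.0], "S3": [20.0, 5.0, 0.0],
            "T1": [-40.0, 150.0, 20.0], "T2": [140.0, 150.0, 20.0], "T3": [50.0, 150.0, 70.0],
        })
        with pytest.raises(ValueError):
            calibrate_pose(frame, _RC, _LC)


class TestClusterRigidity:
    def test_rigid_translation_not_flagged(self):
        gait = generate_synthetic_gait(GaitParams(n_cycles=2, marker_noise_mm=0.0), seed=3)
        assert check_cluster_rigidity(gait.frames, gait.right_cluster) == []

    def test_drifted_marker_flagged(self):
        gait = generate_synthetic_gait(GaitParams(n_cycles=1, marker_noise_mm=0.0), seed=3)
        bad = gait.frames[50]
        bad.positions["R2"] = bad.positions["R2"] + np.array([5.0, 0, 0])
        flagged = check_cluster_rigidity(gait.frames, gait.right_cluster)
        assert flagged == [50]


class TestPhaseMeans:
    def _simple_setup(self, tof_offset=0.0):
        gait = generate_synthetic_gait(
            GaitParams(n_cycles=4, marker_noise_mm=0.0, ifd_sd_mm=0.0),
            spec=ToFSensorSpec(noise_sd_mm=0.0, bias_table_mm={0.0: 0.0},
                               quantization_step_mm=1e-9),
            seed=4,
        )
        ref = gait.true_ifd_mm
        tof = SensorStream(
            "tof", gait.tof.rate_hz, gait.tof.values + tof_offset,
            valid=gait.tof.valid,
        )
        return gait, ref, tof

    def test_identical_streams_zero_error(self):
        gait, ref, tof = self._simple_setup()
        report = phase_means_and_errors(tof, ref, gait.frame_times_s, gait.phases)
        assert report.E_mm == pytest.approx(0.0, abs=1e-6)
        assert report.MAE_mm == pytest.approx(0.0, abs=1e-6)
        assert report.ifd_mean_mm == pytest.approx(83.6, abs=1e-6)

    def test_constant_offset_recovered(self):
        gait, ref, tof = self._simple_setup(tof_offset=3.0)
        report = phase_means_and_errors(tof, ref, gait.frame_times_s, gait.phases)
        assert report.E_mm == pytest.approx(3.0, abs=1e-6)
        assert report.MAE_mm == pytest.approx(3.0, abs=1e-6)

    def test_injected_bias_recovered_within_ci(self):
        # paired runs: only the sensor bias differs, so the difference of
        # the phase-mean errors isolates the injected 3.0 mm
        params = GaitParams(n_cycles=10)
        spec0 = ToFSensorSpec(noise_sd_mm=1.4, bias_table_mm={0.0: 0.0})
        spec3 = ToFSensorSpec(noise_sd_mm=1.4, bias_table_mm={0.0: 3.0})
        reports = []
        for spec in (spec0, spec3):
            gait = generate_synthetic_gait(params, spec=spec, seed=6)
            pose, plane = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
            ref = reference_series(gait.frames, pose, plane, gait.right_cluster, gait.left_cluster)
            reports.append(phase_means_and_errors(gait.tof, ref, gait.frame_times_s, gait.phases))
        n = len(reports[0].records)
        ci = 2.58 * math.sqrt(2) * (1.5 / math.sqrt(3)) / math.sqrt(n) + 0.3
        assert reports[1].E_mm - reports[0].E_mm == pytest.approx(3.0, abs=ci)

    def test_empty_phase_dropped_with_survivors(self):
        gait, ref, tof = self._simple_setup()
        # blank the reference of the first cycle's stance entirely
        i0, i1 = gait.phases[0].stance
        ref = ref.copy()
        ref[i0:i1] = np.nan
        report = phase_means_and_errors(tof, ref, gait.frame_times_s, gait.phases)
        assert all(not (r.cycle == 0 and r.phase == "stance") for r in report.records)


class TestGenerator:
    def test_zero_noise_constant_ifd_reference_constant(self):
        gait = generate_synthetic_gait(GaitParams(n_cycles=3, marker_noise_mm=0.0, ifd_sd_mm=0.0), seed=7)
        pose, plane = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
        ref = reference_series(gait.frames, pose, plane, gait.right_cluster, gait.left_cluster)
        finite = ref[np.isfinite(ref)]
        assert finite.size > 0
        assert np.allclose(finite, 83.6, atol=1e-6)

    def test_fixed_seed_reproducible(self):
        g1 = generate_synthetic_gait(GaitParams(n_cycles=2), seed=8)
        g2 = generate_synthetic_gait(GaitParams(n_cycles=2), seed=8)
        assert np.array_equal(g1.tof.values, g2.tof.values)
        assert np.allclose(g1.frames[10].positions["R2"], g2.frames[10].positions["R2"])

    def test_round_trip_recovers_truth_within_noise_bound(self):
        gait = generate_synthetic_gait(GaitParams(n_cycles=6), seed=9)
        pose, plane = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
        ref = reference_series(gait.frames, pose, plane, gait.right_cluster, gait.left_cluster)
        both = np.isfinite(ref) & np.isfinite(gait.true_ifd_mm)
        assert both.sum() > 50
        err = ref[both] - gait.true_ifd_mm[both]
        assert np.abs(np.mean(err)) < 3 * 0.5
        assert np.abs(err).max() < 3 * 3 * 0.5  # 3x the propagated marker noise
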