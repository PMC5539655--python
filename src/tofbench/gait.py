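"""Inter-foot distance (IFD) during gait: reference geometry and synthesis.

During walking, the sensing platform sits on the right foot with its
boresight pointing medially at a rectangular target (200 x 100 mm)
attached to the medial side of the left foot.  The marker-based reference
for the sensor's reading is the distance from the sensor centre to the
intersection of the sensor-plane normal (through the centre) with the
target plane.  Both geometries are expressed in foot-fixed coordinate
systems built from three-marker rigid clusters, calibrated once from a
static acquisition with seven additional markers (one on the sensor,
three on its support plane, three on the target), and reconstructed in
every dynamic frame from the clusters alone.

Per gait cycle, the mean sensor and reference distances over the swing
and stance phases of the right foot are compared; the module also ships a
synthetic two-foot gait generator so the whole stage is testable without
motion-capture data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import plane_normal, ray_plane_parameter, unit
from .sensor import NO_HIT, ToFSensorSpec, measure
from .streams import SensorStream

__all__ = [
    "MarkerFrame",
    "RigidCluster",
    "SensorPose",
    "TargetPlane",
    "GaitCyclePhases",
    "GaitPhaseAnnotation",
    "GaitParams",
    "SyntheticGait",
    "PhaseMeanRecord",
    "IfdReport",
    "calibrate_pose",
    "reference_ifd",
    "reference_series",
    "check_cluster_rigidity",
    "phase_means_and_errors",
    "generate_synthetic_gait",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerFrame:
    """Named marker positions (mm, world frame) of one captured frame."""

    index: int
    time_s: float
    positions: dict[str, np.ndarray]
    missing: frozenset[str] = frozenset()

    def pos(self, name: str) -> np.ndarray:
        if name in self.missing or name not in self.positions:
            raise KeyError(f"marker {name!r} missing in frame {self.index}")
        return np.asarray(self.positions[name], dtype=float)


@dataclass(frozen=True)
class RigidCluster:
    """Three-marker cluster defining a foot-fixed coordinate system.

    Origin at ``marker_1``; first axis toward ``marker_2``; third axis
    along the cluster-plane normal; second axis completing a right-handed
    orthonormal triad (orthogonalized toward ``marker_3``).
    """

    marker_1: str
    marker_2: str
    marker_3: str

    @property
    def names(self) -> tuple[str, str, str]:
        return (self.marker_1, self.marker_2, self.marker_3)

    def axes(self, frame: MarkerFrame) -> tuple[np.ndarray, np.ndarray]:
        """(origin, rotation) in the given frame; columns of the rotation
        are the cluster axes in world coordinates, so
        ``world = origin + R @ local``."""
        p1 = frame.pos(self.marker_1)
        p2 = frame.pos(self.marker_2)
        p3 = frame.pos(self.marker_3)
        x = unit(p2 - p1)
        z = np.cross(x, p3 - p1)
        if np.linalg.norm(z) < 1e-6:
            raise ValueError(f"collinear cluster markers {self.names}")
        z = unit(z)
        y = np.cross(z, x)
        return p1, np.column_stack([x, y, z])

    def to_local(self, frame: MarkerFrame, p_world) -> np.ndarray:
        o, rot = self.axes(frame)
        return rot.T @ (np.asarray(p_world, dtype=float) - o)

    def to_world(self, frame: MarkerFrame, p_local) -> np.ndarray:
        o, rot = self.axes(frame)
        return o + rot @ np.asarray(p_local, dtype=float)


@dataclass(frozen=True)
class SensorPose:
    """Sensor centre and boresight, expressed in the right-foot cluster frame."""

    center_local_mm: np.ndarray
    boresight_local: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "boresight_local", unit(self.boresight_local))


@dataclass(frozen=True)
class TargetPlane:
    """Finite target rectangle, expressed in the left-foot cluster frame."""

    point_local_mm: np.ndarray
    normal_local: np.ndarray
    u_local: np.ndarray
    v_local: np.ndarray
    half_u_mm: float = 100.0
    half_v_mm: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "normal_local", unit(self.normal_local))
        object.__setattr__(self, "u_local", unit(self.u_local))
        object.__setattr__(self, "v_local", unit(self.v_local))


@dataclass(frozen=True)
class GaitCyclePhases:
    """Right-foot stance and swing frame ranges of one gait cycle
    (half-open ``[start, stop)`` frame indices)."""

    cycle: int
    stance: tuple[int, int]
    swing: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.stance[0] < self.stance[1] <= self.swing[0] < self.swing[1]):
            raise ValueError("phases must be ordered and non-overlapping")


GaitPhaseAnnotation = list[GaitCyclePhases]


# ---------------------------------------------------------------------------
# calibration and reference geometry
# ---------------------------------------------------------------------------

def calibrate_pose(
    static_frame: MarkerFrame,
    right_cluster: RigidCluster,
    left_cluster: RigidCluster,
    sensor_marker: str = "SENS",
    support_markers: tuple[str, str, str] = ("S1", "S2", "S3"),
    target_markers: tuple[str, str, str] = ("T1", "T2", "T3"),
    target_size_mm: tuple[float, float] = (200.0, 100.0),
) -> tuple[SensorPose, TargetPlane]:
    """Sensor pose and target plane from the static calibration frame.

    The sensor centre is the sensor marker expressed in the right cluster
    frame.  The boresight is the unit normal of the plane through the
    three support markers, signed to point toward the left-foot cluster
    centroid.  The target plane passes through the centroid of the three
    target markers with the normal of their plane (signed toward the
    right foot); its in-plane axes are the first target edge direction
    and the completing cross product, with the given half-extents.
    """
    sensor_w = static_frame.pos(sensor_marker)
    sup = [static_frame.pos(m) for m in support_markers]
    tgt = [static_frame.pos(m) for m in target_markers]
    left_centroid = np.mean([static_frame.pos(m) for m in left_cluster.names], axis=0)
    right_centroid = np.mean([static_frame.pos(m) for m in right_cluster.names], axis=0)

    bore_w = plane_normal(*sup)
    if bore_w @ (left_centroid - sensor_w) < 0:
        bore_w = -bore_w

    norm_w = plane_normal(*tgt)
    if norm_w @ (right_centroid - np.mean(tgt, axis=0)) < 0:
        norm_w = -norm_w
    u_w = unit(np.asarray(tgt[1], dtype=float) - np.asarray(tgt[0], dtype=float))
    v_w = np.cross(norm_w, u_w)

    _, rot_r = right_cluster.axes(static_frame)
    _, rot_l = left_cluster.axes(static_frame)
    pose = SensorPose(
        center_local_mm=right_cluster.to_local(static_frame, sensor_w),
        boresight_local=rot_r.T @ bore_w,
    )
    plane = TargetPlane(
        point_local_mm=left_cluster.to_local(static_frame, np.mean(tgt, axis=0)),
        normal_local=rot_l.T @ norm_w,
        u_local=rot_l.T @ u_w,
        v_local=rot_l.T @ v_w,
        half_u_mm=target_size_mm[0] / 2.0,
        half_v_mm=target_size_mm[1] / 2.0,
    )
    return pose, plane


def reference_ifd(
    frame: MarkerFrame,
    pose: SensorPose,
    plane: TargetPlane,
    right_cluster: RigidCluster,
    left_cluster: RigidCluster,
) -> float:
    """Marker-based reference distance for one frame, or ``NO_HIT``.

    Reconstructs both cluster frames, maps the sensor centre/boresight and
    the target plane to world coordinates, and returns the distance from
    the sensor centre to the boresight-line / target-plane intersection.
    ``NO_HIT`` when the line is parallel to the plane, the intersection
    lies behind the sensor, or it falls outside the target rectangle.
    """
    o_r, rot_r = right_cluster.axes(frame)
    o_l, rot_l = left_cluster.axes(frame)
    center = o_r + rot_r @ pose.center_local_mm
    bore = rot_r @ pose.boresight_local
    point = o_l + rot_l @ plane.point_local_mm
    normal = rot_l @ plane.normal_local
    t = ray_plane_parameter(center, bore, point, normal)
    if not math.isfinite(t) or t < 0:
        return NO_HIT
    hit = center + t * bore
    du = abs(float((hit - point) @ (rot_l @ plane.u_local)))
    dv = abs(float((hit - point) @ (rot_l @ plane.v_local)))
    if du > plane.half_u_mm or dv > plane.half_v_mm:
        return NO_HIT
    return t


def reference_series(
    frames: list[MarkerFrame],
    pose: SensorPose,
    plane: TargetPlane,
    right_cluster: RigidCluster,
    left_cluster: RigidCluster,
) -> np.ndarray:
    """Per-frame reference IFD (mm, NaN where no intersection)."""
    return np.array(
        [reference_ifd(f, pose, plane, right_cluster, left_cluster) for f in frames]
    )


def check_cluster_rigidity(
    frames: list[MarkerFrame], cluster: RigidCluster, tol_mm: float = 2.0
) -> list[int]:
    """Frame indices where any inter-marker distance drifts beyond tol.

    The reference inter-marker distances are taken from the first frame.
    """
    if not frames:
        return []
    a, b, c = cluster.names

    def dists(f: MarkerFrame) -> np.ndarray:
        pa, pb, pc = f.pos(a), f.pos(b), f.pos(c)
        return np.array(
            [np.linalg.norm(pa - pb), np.linalg.norm(pb - pc), np.linalg.norm(pc - pa)]
        )

    ref = dists(frames[0])
    return [
        f.index for f in frames if np.any(np.abs(dists(f) - ref) > tol_mm)
    ]


# ---------------------------------------------------------------------------
# phase-averaged comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseMeanRecord:
    cycle: int
    phase: str
    tof_mean_mm: float
    ref_mean_mm: float

    @property
    def error_mm(self) -> float:
        return self.tof_mean_mm - self.ref_mean_mm


@dataclass
class IfdReport:
    """Phase-averaged IFD comparison: per-cycle records and overall stats."""

    records: list[PhaseMeanRecord]
    ifd_mean_mm: float
    ifd_sd_mm: float
    E_mm: float
    SD_mm: float
    MAE_mm: float
    MAE_pct: float


def phase_means_and_errors(
    tof: SensorStream,
    reference_mm: np.ndarray,
    frame_times_s: np.ndarray,
    phases: GaitPhaseAnnotation,
) -> IfdReport:
    """Compare phase-mean sensor and reference distances per gait cycle.

    For every cycle and phase (right-foot stance and swing) the mean of
    the valid sensor readings and of the finite reference values inside
    the phase's time interval are taken; cycle-phases where either side is
    empty after exclusions are dropped with a warning.  Overall E, SD,
    MAE are computed across the surviving cycle-phase errors; MAE% is
    normalized by the mean reference distance.
    """
    reference_mm = np.asarray(reference_mm, dtype=float)
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    tof_t = tof.times
    records: list[PhaseMeanRecord] = []
    for cyc in phases:
        for phase_name, (i0, i1) in (("stance", cyc.stance), ("swing", cyc.swing)):
            t0, t1 = frame_times_s[i0], frame_times_s[i1 - 1]
            ref_vals = reference_mm[i0:i1]
            ref_vals = ref_vals[np.isfinite(ref_vals)]
            m_tof = tof.valid & (tof_t >= t0) & (tof_t <= t1)
            if ref_vals.size == 0 or not m_tof.any():
                logger.warning(
                    "cycle %d %s dropped: no valid samples after exclusions",
                    cyc.cycle, phase_name,
                )
                continue
            records.append(
                PhaseMeanRecord(
                    cycle=cyc.cycle,
                    phase=phase_name,
                    tof_mean_mm=float(np.mean(tof.values[m_tof])),
                    ref_mean_mm=float(np.mean(ref_vals)),
                )
            )
    if not records:
        raise ValueError("no cycle-phase survived the exclusions")
    errs = np.array([r.error_mm for r in records])
    refs = np.array([r.ref_mean_mm for r in records])
    mae = float(np.mean(np.abs(errs)))
    return IfdReport(
        records=records,
        ifd_mean_mm=float(np.mean(refs)),
        ifd_sd_mm=float(np.std(refs, ddof=1)) if refs.size > 1 else float("nan"),
        E_mm=float(np.mean(errs)),
        SD_mm=float(np.std(errs, ddof=1)) if errs.size > 1 else float("nan"),
        MAE_mm=mae,
        MAE_pct=100.0 * mae / float(np.mean(refs)),
    )


# ---------------------------------------------------------------------------
# synthetic gait generator
# ---------------------------------------------------------------------------

@dataclass
class GaitParams:
    """Synthetic walking-trial parameters.

    Defaults emulate a single healthy adult walking straight at
    comfortable speed: mean IFD 83.6 mm with 11.0 mm cycle-to-cycle
    variability, 0.9 m/s progression, 1.1 s gait cycles (60% stance),
    markers captured at 100 Hz with isotropic 0.5 mm noise.
    """

    mean_ifd_mm: float = 83.6
    ifd_sd_mm: float = 11.0
    cycle_duration_s: float = 1.1
    n_cycles: int = 10
    marker_noise_mm: float = 0.5
    speed_m_s: float = 0.9
    marker_rate_hz: float = 100.0
    stance_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.mean_ifd_mm <= 0 or self.ifd_sd_mm < 0:
            raise ValueError("mean_ifd_mm must be positive, ifd_sd_mm non-negative")
        if self.n_cycles < 1 or self.cycle_duration_s <= 0:
            raise ValueError("need at least one cycle of positive duration")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.marker_noise_mm < 0:
            raise ValueError("marker_noise_mm must be non-negative")


# fixed generator geometry (mm, foot frames; feet translate without rotating)
_RIGHT_MARKERS = {"R1": (0.0, 0.0, 25.0), "R2": (95.0, 30.0, 40.0), "R3": (30.0, -25.0, 70.0)}
_LEFT_MARKERS = {"L1": (0.0, 0.0, 25.0), "L2": (90.0, -35.0, 45.0), "L3": (25.0, 20.0, 65.0)}
_SENSOR_OFF = np.array([110.0, 15.0, 30.0])      # near the 1st metatarsal head
_TARGET_OFF = np.array([80.0, -40.0, 30.0])      # target centre, medial side
_SUPPORT_OFF = [(-30.0, -5.0, 0.0), (30.0, -5.0, 0.0), (0.0, -5.0, 40.0)]
_TARGET_MARK_OFF = [(-90.0, 0.0, -25.0), (90.0, 0.0, -25.0), (0.0, 0.0, 50.0)]


@dataclass
class SyntheticGait:
    """Everything the IFD stage needs, plus ground truth for tests."""

    params: GaitParams
    frames: list[MarkerFrame]
    static_frame: MarkerFrame
    right_cluster: RigidCluster
    left_cluster: RigidCluster
    tof: SensorStream
    phases: GaitPhaseAnnotation
    frame_times_s: np.ndarray
    true_ifd_mm: np.ndarray           # per frame; NaN where the ray misses
    cycle_ifd_mm: np.ndarray          # realized per-cycle IFD draws


def _forward_progression(tau: np.ndarray, cycle_s: float, stance_frac: float,
                         stride_mm: float) -> np.ndarray:
    """Caterpillar foot progression: stationary in stance, a smooth
    cosine-ramp advance of one stride during swing."""
    k = np.floor(tau / cycle_s)
    u = tau / cycle_s - k
    s = np.clip((u - stance_frac) / (1.0 - stance_frac), 0.0, 1.0)
    return (k + 0.5 * (1.0 - np.cos(np.pi * s))) * stride_mm


def generate_synthetic_gait(
    params: GaitParams,
    spec: ToFSensorSpec | None = None,
    seed=0,
) -> SyntheticGait:
    """Simulate a straight walk of two rigid feet with known IFD.

    The right foot (sensor, boresight medial/+Y) and left foot (target
    plane on its medial side) alternate stance and swing half a cycle out
    of phase while progressing forward at the prescribed speed.  The
    lateral separation follows a per-cycle IFD profile drawn from
    N(mean_ifd, ifd_sd) and interpolated between cycle centres.  Marker
    positions (clusters in every dynamic frame; clusters plus the seven
    calibration markers in the static frame) carry isotropic Gaussian
    noise; ToF readings are produced by the sensor forward model against
    the moving target plane.
    """
    if spec is None:
        spec = ToFSensorSpec()
    rng = np.random.default_rng(seed)
    p = params
    cycle_s, fs = p.cycle_duration_s, p.marker_rate_hz
    stride_mm = p.speed_m_s * 1000.0 * cycle_s
    duration = p.n_cycles * cycle_s
    frame_t = np.arange(int(round(duration * fs))) / fs

    cycle_ifd = rng.normal(p.mean_ifd_mm, p.ifd_sd_mm, size=p.n_cycles)
    cycle_ifd = np.clip(cycle_ifd, 30.0, None)  # feet cannot interpenetrate
    cycle_centers = (np.arange(p.n_cycles) + 0.5) * cycle_s

    def ifd_profile(t):
        return np.interp(t, cycle_centers, cycle_ifd)

    def foot_positions(t):
        """Right and left foot origins (world, mm) at times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x_r = _forward_progression(t, cycle_s, p.stance_fraction, stride_mm)
        x_l = _forward_progression(t + 0.5 * cycle_s, cycle_s, p.stance_fraction,
                                   stride_mm) - stride_mm / 2.0
        y_l = ifd_profile(t) + _SENSOR_OFF[1] - _TARGET_OFF[1]
        right = np.stack([x_r, np.zeros_like(t), np.zeros_like(t)], axis=-1)
        left = np.stack([x_l, y_l, np.zeros_like(t)], axis=-1)
        return right, left

    def true_los(t):
        """True sensor-to-target-plane distance along the boresight; NaN
        when the intersection misses the finite target face."""
        right, left = foot_positions(t)
        sx = right[..., 0] + _SENSOR_OFF[0]
        px = left[..., 0] + _TARGET_OFF[0]
        dist = left[..., 1] + _TARGET_OFF[1] - _SENSOR_OFF[1]  # = ifd_profile(t)
        facing = np.abs(sx - px) <= 100.0
        return np.where(facing, dist, NO_HIT)

    # dynamic marker frames (clusters only)
    right_pos, left_pos = foot_positions(frame_t)
    frames: list[MarkerFrame] = []
    for i, t in enumerate(frame_t):
        pos: dict[str, np.ndarray] = {}
        for name, off in _RIGHT_MARKERS.items():
            pos[name] = right_pos[i] + np.asarray(off)
        for name, off in _LEFT_MARKERS.items():
            pos[name] = left_pos[i] + np.asarray(off)
        if p.marker_noise_mm > 0:
            for name in pos:
                pos[name] = pos[name] + rng.normal(0.0, p.marker_noise_mm, 3)
        frames.append(MarkerFrame(index=i, time_s=float(t), positions=pos))

    # static calibration frame: feet side by side at the nominal IFD
    r0 = np.zeros(3)
    l0 = np.array([0.0, p.mean_ifd_mm + _SENSOR_OFF[1] - _TARGET_OFF[1], 0.0])
    sensor_w = r0 + _SENSOR_OFF
    target_w = l0 + _TARGET_OFF
    static_pos: dict[str, np.ndarray] = {}
    for name, off in _RIGHT_MARKERS.items():
        static_pos[name] = r0 + np.asarray(off)
    for name, off in _LEFT_MARKERS.items():
        static_pos[name] = l0 + np.asarray(off)
    static_pos["SENS"] = sensor_w.copy()
    for j, off in enumerate(_SUPPORT_OFF, start=1):
        static_pos[f"S{j}"] = sensor_w + np.asarray(off)
    for j, off in enumerate(_TARGET_MARK_OFF, start=1):
        static_pos[f"T{j}"] = target_w + np.asarray(off)
    if p.marker_noise_mm > 0:
        for name in static_pos:
            static_pos[name] = static_pos[name] + rng.normal(0.0, p.marker_noise_mm, 3)
    static_frame = MarkerFrame(index=-1, time_s=0.0, positions=static_pos)

    # ToF stream against the moving target plane
    tof_t = np.arange(int(round(duration * spec.output_rate_hz))) / spec.output_rate_hz
    readings = measure(true_los(tof_t), spec, rng, aoi_deg=0.0)
    tof = SensorStream(
        "tof", spec.output_rate_hz, readings.astype(float), "mm",
        valid=readings != spec.no_reflection_value,
    )

    # phase annotation (generator ground truth; real use imports it)
    phases: GaitPhaseAnnotation = []
    for k in range(p.n_cycles):
        i0 = int(round(k * cycle_s * fs))
        im = int(round((k + p.stance_fraction) * cycle_s * fs))
        i1 = min(int(round((k + 1) * cycle_s * fs)), len(frames))
        phases.append(GaitCyclePhases(cycle=k, stance=(i0, im), swing=(im, i1)))

    return SyntheticGait(
        params=p,
        frames=frames,
        static_frame=static_frame,
        right_cluster=RigidCluster("R1", "R2", "R3"),
        left_cluster=RigidCluster("L1", "L2", "L3"),
        tof=tof,
        phases=phases,
        frame_times_s=frame_t,
        true_ifd_mm=true_los(frame_t),
        cycle_ifd_mm=cycle_ifd,
    )
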