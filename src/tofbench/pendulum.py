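"""Pendulum benchmark rig: synthetic generator for the dynamic accuracy tests.

The benchmark swings the sensing platform on a wooden pendulum (length
600 mm, released from horizontal) past a stationary rectangular cuboid
target, emulating the oscillation of a leg during gait.  The rig emits a
gyroscope stream at 100 Hz and a ToF distance stream at 50 Hz on a shared
clock, together with a ground-truth record used as test oracle.

Model
-----
The pendulum is a uniform rod pivoted at one end with viscous damping:

    theta_dd = -(3 g / (2 l)) sin(theta) - gamma * theta_d

integrated with a fixed-step classical Runge-Kutta (RK4) scheme on a 1 ms
internal grid, then decimated to the sensor rates by nearest-node
selection.  Released from horizontal with no damping, energy conservation
for a uniform rod gives a peak angular velocity sqrt(3 g / l)
(about 7.0 rad/s for l = 600 mm); the default damping is tuned so the peak
angular velocity decays through the 1-6 rad/s analysis window in roughly
30 half-oscillations.

Frames and target geometry
--------------------------
World frame: X along the swing direction, Y along the sensor boresight,
Z up, origin at the pivot.  The sensor sits at the distal end with its
boresight fixed perpendicular to the swing plane, so the angle of
incidence (AoI) is purely a yaw of the target: the target-plane normal is
the boresight rotated by AoI about the vertical, and the plane is placed
so the line-of-sight distance at the pendulum's lowest point (where the
angular velocity is maximal) equals the imposed distance ``d``.  The
target face is a finite 180 x 70 mm rectangle centred on the boresight at
the lowest point; rays missing it return ``NO_HIT``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ray_plane_parameter, unit
from .sensor import NO_HIT, ToFSensorSpec, measure
from .streams import SensorStream

__all__ = [
    "DEFAULT_DAMPING",
    "PendulumRig",
    "RigGroundTruth",
    "simulate_pendulum",
    "line_of_sight_distance",
    "generate_condition",
    "generate_static",
]

DEFAULT_DAMPING = 0.18
"""Default viscous damping coefficient (1/s): peak angular velocity decays
from ~6.5 to 1 rad/s over ~30 half-oscillations."""


@dataclass
class PendulumRig:
    """Pendulum + target geometry for one experimental condition.

    ``imposed_distance_mm`` is the sensor-target distance at the lowest
    point of the swing, set with a ruler in the physical protocol;
    ``aoi_deg`` is the signed target yaw.  Conditions where the swinging
    pendulum would collide with the tilted target are rejected
    (|AoI| = 30 deg requires d >= 70 mm, |AoI| = 60 deg requires
    d >= 100 mm).
    """

    imposed_distance_mm: float = 100.0
    aoi_deg: float = 0.0
    length_mm: float = 600.0
    gravity_m_s2: float = 9.81
    damping_1_s: float = DEFAULT_DAMPING
    initial_angle_rad: float = math.pi / 2
    target_width_mm: float = 180.0
    target_height_mm: float = 70.0
    gyro_rate_hz: float = 100.0
    internal_step_s: float = 1e-3

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.imposed_distance_mm <= 0:
            raise ValueError("imposed_distance_mm must be positive")
        if self.internal_step_s <= 0 or self.gyro_rate_hz <= 0:
            raise ValueError("internal_step_s and gyro_rate_hz must be positive")
        if self.damping_1_s < 0:
            raise ValueError("damping_1_s must be non-negative")
        a = abs(self.aoi_deg)
        if a >= 90:
            raise ValueError("aoi_deg must lie in (-90, 90)")
        if a >= 60 and self.imposed_distance_mm < 100:
            raise ValueError(
                f"collision: |AoI| = {a} deg requires d >= 100 mm, "
                f"got {self.imposed_distance_mm} mm"
            )
        if 30 <= a < 60 and self.imposed_distance_mm < 70:
            raise ValueError(
                f"collision: |AoI| = {a} deg requires d >= 70 mm, "
                f"got {self.imposed_distance_mm} mm"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def omega0_sq(self) -> float:
        """(3g / 2l), the squared small-angle frequency of a uniform rod."""
        return 3.0 * self.gravity_m_s2 / (2.0 * self.length_mm / 1000.0)

    @property
    def plane_point(self) -> np.ndarray:
        """Target centre C (mm): on the boresight at the lowest point."""
        return np.array([0.0, self.imposed_distance_mm, -self.length_mm])

    @property
    def plane_normal(self) -> np.ndarray:
        a = math.radians(self.aoi_deg)
        return np.array([-math.sin(a), math.cos(a), 0.0])

    def sensor_position(self, theta) -> np.ndarray:
        """Sensor position (mm) for swing angle(s) theta (rad from vertical)."""
        theta = np.asarray(theta, dtype=float)
        l = self.length_mm
        return np.stack(
            [l * np.sin(theta), np.zeros_like(theta), -l * np.cos(theta)], axis=-1
        )


@dataclass
class RigGroundTruth:
    """Per-step truth of a simulated condition (test oracle).

    ``peak_times_s`` are the refined times of the per-half-oscillation
    |angular velocity| extrema, strictly increasing; ``peak_omegas`` keep
    the sign of the swing direction; ``peak_d_true_mm`` is the true
    line-of-sight distance at each peak (NaN when the ray misses).
    """

    t_s: np.ndarray
    theta_rad: np.ndarray
    omega_rad_s: np.ndarray
    los_mm: np.ndarray
    peak_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_omegas_rad_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_d_true_mm: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate_pendulum(
    rig: PendulumRig, duration_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the damped rigid-pendulum equation of motion.

    Fixed-step RK4 at ``rig.internal_step_s`` from theta(0) = initial
    angle, theta_d(0) = 0.  Returns (t, theta, omega) on the internal
    grid.  An energy-growth check guards against an unstable step size.
    """
    h = rig.internal_step_s
    n = int(round(duration_s / h))
    k = rig.omega0_sq
    gam = rig.damping_1_s

    theta = np.empty(n + 1)
    omega = np.empty(n + 1)
    th, w = rig.initial_angle_rad, 0.0
    theta[0], omega[0] = th, w
    sin = math.sin
    for i in range(n):
        k1t, k1w = w, -k * sin(th) - gam * w
        th2, w2 = th + 0.5 * h * k1t, w + 0.5 * h * k1w
        k2t, k2w = w2, -k * sin(th2) - gam * w2
        th3, w3 = th + 0.5 * h * k2t, w + 0.5 * h * k2w
        k3t, k3w = w3, -k * sin(th3) - gam * w3
        th4, w4 = th + h * k3t, w + h * k3w
        k4t, k4w = w4, -k * sin(th4) - gam * w4
        th += h * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
        w += h * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0
        theta[i + 1], omega[i + 1] = th, w

    t = np.arange(n + 1) * h
    energy = 0.5 * omega**2 + k * (1.0 - np.cos(theta))
    e0 = 0.5 * omega[0] ** 2 + k * (1.0 - math.cos(theta[0]))
    if not np.isfinite(energy).all() or energy.max() > e0 * (1.0 + 1e-6):
        raise RuntimeError(
            "integration unstable: mechanical energy grew; reduce internal_step_s"
        )
    return t, theta, omega


def _los_from_theta(theta, rig: PendulumRig) -> np.ndarray:
    """Vectorized line-of-sight distance for swing angles; NaN marks a miss.

    For the fixed +Y boresight the ray-plane solve reduces to
    ``t = d + x tan(AoI)`` with x the lateral sensor offset; the in-plane
    hit offsets are |x| / cos(AoI) horizontally and l (1 - cos theta)
    vertically, checked against the half-extents of the target face.
    """
    theta = np.asarray(theta, dtype=float)
    a = math.radians(rig.aoi_deg)
    x = rig.length_mm * np.sin(theta)
    dist = rig.imposed_distance_mm + x * math.tan(a)
    u_off = np.abs(x) / math.cos(a)
    v_off = rig.length_mm * (1.0 - np.cos(theta))
    ok = (
        (dist >= 0)
        & (u_off <= rig.target_width_mm / 2.0)
        & (v_off <= rig.target_height_mm / 2.0)
    )
    return np.where(ok, dist, NO_HIT)


def line_of_sight_distance(sensor_position, ray_direction, rig: PendulumRig) -> float:
    """Distance along a ray to the finite target face, or ``NO_HIT``.

    ``ray_direction`` is the sensor boresight (a unit vector; +Y for this
    rig).  Returns the ray parameter of the intersection with the target
    plane when the hit lies inside the 180 x 70 mm face and in front of
    the sensor, otherwise ``NO_HIT``.
    """
    p = np.asarray(sensor_position, dtype=float)
    b = unit(ray_direction)
    n = rig.plane_normal
    c = rig.plane_point
    t = ray_plane_parameter(p, b, c, n)
    if not math.isfinite(t) or t < 0:
        return NO_HIT
    hit = p + t * b
    u = unit(np.cross([0.0, 0.0, 1.0], n))
    v = np.array([0.0, 0.0, 1.0])
    du = abs(float((hit - c) @ u))
    dv = abs(float((hit - c) @ v))
    if du > rig.target_width_mm / 2.0 or dv > rig.target_height_mm / 2.0:
        return NO_HIT
    return t


def _refine_peaks(
    t: np.ndarray, theta: np.ndarray, omega: np.ndarray, min_abs: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-step |omega| extrema via parabolic interpolation.

    Returns refined (times, signed omegas, thetas) of every
    half-oscillation peak with |omega| above ``min_abs``.
    """
    s = np.abs(omega)
    i = np.nonzero((s[1:-1] >= s[:-2]) & (s[1:-1] > s[2:]) & (s[1:-1] > min_abs))[0] + 1
    if i.size == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    dt = t[1] - t[0]
    denom = s[i - 1] - 2 * s[i] + s[i + 1]
    delta = np.where(denom != 0, 0.5 * (s[i - 1] - s[i + 1]) / denom, 0.0)
    tt = t[i] + delta * dt
    ww = s[i] - 0.25 * (s[i - 1] - s[i + 1]) * delta
    th = (
        theta[i]
        + delta * 0.5 * (theta[i + 1] - theta[i - 1])
        + 0.5 * delta**2 * (theta[i + 1] - 2 * theta[i] + theta[i - 1])
    )
    return tt, np.sign(omega[i]) * ww, th


def generate_condition(
    rig: PendulumRig,
    spec: ToFSensorSpec,
    seed,
    duration_s: float = 40.0,
) -> tuple[SensorStream, SensorStream, RigGroundTruth]:
    """Simulate one dynamic condition end to end.

    Integrates the pendulum, samples the angular velocity at the gyro rate
    and the line-of-sight distance at the ToF output rate (nearest-node
    decimation of the internal grid), passes the latter through the sensor
    forward model, and records ground truth (including refined per-peak
    times, angular velocities and true distances).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    h = rig.internal_step_s
    gyro_dec = 1.0 / (rig.gyro_rate_hz * h)
    tof_dec = 1.0 / (spec.output_rate_hz * h)
    if abs(gyro_dec - round(gyro_dec)) > 1e-9 or abs(tof_dec - round(tof_dec)) > 1e-9:
        raise ValueError("internal_step_s must evenly divide both sensor periods")
    ratio = rig.gyro_rate_hz / spec.output_rate_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("gyro rate must be an integer multiple of the ToF rate")

    t, theta, omega = simulate_pendulum(rig, duration_s)
    los = _los_from_theta(theta, rig)

    gyro = SensorStream("gyro", rig.gyro_rate_hz, omega[:: int(round(gyro_dec))], "rad/s")

    rng = np.random.default_rng(seed)
    los_tof = los[:: int(round(tof_dec))]
    readings = measure(los_tof, spec, rng, aoi_deg=rig.aoi_deg)
    tof = SensorStream(
        "tof",
        spec.output_rate_hz,
        readings.astype(float),
        "mm",
        valid=readings != spec.no_reflection_value,
    )

    pk_t, pk_w, pk_th = _refine_peaks(t, theta, omega)
    truth = RigGroundTruth(
        t_s=t,
        theta_rad=theta,
        omega_rad_s=omega,
        los_mm=los,
        peak_times_s=pk_t,
        peak_omegas_rad_s=pk_w,
        peak_d_true_mm=_los_from_theta(pk_th, rig),
    )
    return gyro, tof, truth


def generate_static(
    d_mm: float,
    aoi_deg: float,
    spec: ToFSensorSpec,
    seed,
    n: int = 30,
) -> SensorStream:
    """n independent readings with the target held stationary at distance d."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    readings = measure(np.full(n, float(d_mm)), spec, rng, aoi_deg=aoi_deg)
    return SensorStream(
        "tof_static",
        spec.output_rate_hz,
        readings.astype(float),
        "mm",
        valid=readings != spec.no_reflection_value,
    )
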