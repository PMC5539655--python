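"""Gyro-peak-synchronized distance extraction.

Data-reduction procedure of the dynamic benchmark: the 50 Hz ToF channel
is linearly interpolated onto the 100 Hz gyro grid; the angular-velocity
peaks (one per half-oscillation, alternating in sign) mark the passes
through the pendulum's lowest point, where the sensor faces the target at
the imposed distance; the distance read at each retained peak yields one
sample ``d_k`` per oscillation, keeping peaks with |omega| in the
1-6 rad/s analysis window.

Sentinel (no-reflection) readings are treated as missing: they are
excluded from the interpolation support and can never be extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .streams import SensorStream

__all__ = [
    "OscillationSample",
    "Peak",
    "resample_linear",
    "static_distance",
    "detect_peaks",
    "extract_oscillations",
]

logger = logging.getLogger(__name__)


class Peak(NamedTuple):
    index: int
    time_s: float
    omega_rad_s: float


@dataclass(frozen=True)
class OscillationSample:
    """One extracted (peak omega, sensor distance, true distance) triple."""

    k: int
    t_peak_s: float
    omega_peak_rad_s: float
    d_irtof_mm: float
    d_true_mm: float


def resample_linear(stream: SensorStream, target_rate_hz: float = 100.0) -> SensorStream:
    """Linearly interpolate a stream onto a faster uniform grid.

    Interpolation uses the valid samples only; target timestamps outside
    the valid support are flagged invalid.  The output grid starts at the
    input's start time and spans its duration, so a 50 Hz ToF stream lands
    sample-for-sample on the 100 Hz grid of the paired gyro stream.
    """
    t_valid, v_valid = stream.valid_points()
    if t_valid.size < 2:
        raise ValueError(
            f"resampling needs at least 2 valid samples, got {t_valid.size}"
        )
    duration = (len(stream) - 1) / stream.rate_hz
    n_out = int(round(duration * target_rate_hz)) + 1
    t_out = stream.start_s + np.arange(n_out) / target_rate_hz
    values = np.interp(t_out, t_valid, v_valid)
    valid = (t_out >= t_valid[0]) & (t_out <= t_valid[-1])
    return SensorStream(
        stream.name, target_rate_hz, values, stream.units, stream.start_s, valid
    )


def static_distance(readings, n: int = 30) -> float:
    """Sensor-target distance of a static acquisition: mean of n readings.

    Sentinel/invalid readings are excluded before counting; the first
    ``n`` valid readings are averaged.  ``readings`` may be a
    :class:`SensorStream` or an array (where 0 marks the sentinel).
    """
    if isinstance(readings, SensorStream):
        vals = readings.values[readings.valid]
    else:
        vals = np.asarray(readings, dtype=float)
        vals = vals[np.isfinite(vals) & (vals != 0)]
    if vals.size < n:
        raise ValueError(
            f"static averaging needs {n} valid readings, got {vals.size}"
        )
    return float(np.mean(vals[:n]))


def detect_peaks(
    gyro: SensorStream, min_abs_omega: float = 1.0
) -> list[Peak]:
    """Signed local extrema of the angular velocity, alternating in sign.

    A three-point test finds local maxima with positive value and local
    minima with negative value (plateaus resolve to their earliest
    sample), keeps those with |omega| >= ``min_abs_omega``, and enforces
    sign alternation by retaining the largest-|omega| extremum of any
    same-sign run.  Each retained peak marks one half-oscillation.
    """
    v = gyro.values
    if v.size < 3:
        return []
    is_max = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > 0)
    is_min = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]) & (v[1:-1] < 0)
    idx = np.nonzero(is_max | is_min)[0] + 1
    idx = idx[np.abs(v[idx]) >= min_abs_omega]

    t = gyro.times
    peaks: list[Peak] = []
    for i in idx:
        cand = Peak(int(i), float(t[i]), float(v[i]))
        if peaks and np.sign(cand.omega_rad_s) == np.sign(peaks[-1].omega_rad_s):
            if abs(cand.omega_rad_s) > abs(peaks[-1].omega_rad_s):
                peaks[-1] = cand  # same-sign run: keep the strongest
        else:
            peaks.append(cand)
    return peaks


def extract_oscillations(
    gyro: SensorStream,
    tof_resampled: SensorStream,
    d_true_mm: float,
    omega_window: tuple[float, float] = (1.0, 6.0),
    jitter_half_width_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[OscillationSample]:
    """One distance sample per half-oscillation inside the omega window.

    For each detected gyro peak with |omega| inside ``omega_window`` the
    resampled ToF value at the identical timestamp index is paired with
    it; peaks whose paired distance is invalid (no reflection, outside the
    interpolation support) are dropped.

    ``jitter_half_width_s`` optionally perturbs each read-out time by a
    uniform +/- shift (the value is then read by interpolation on the
    valid support), emulating a peak-identification timing uncertainty on
    top of the intrinsic half-sample ambiguity; it requires ``rng``.

    Returns an empty list, with a logged warning, when no peak survives.
    """
    if len(gyro) != len(tof_resampled) or gyro.rate_hz != tof_resampled.rate_hz:
        raise ValueError("gyro and resampled ToF streams must share the same grid")
    if jitter_half_width_s < 0:
        raise ValueError("jitter_half_width_s must be non-negative")
    if jitter_half_width_s > 0 and rng is None:
        raise ValueError("peak-time jitter requires an explicit rng")

    lo, hi = omega_window
    peaks = [p for p in detect_peaks(gyro, min_abs_omega=lo)
             if lo <= abs(p.omega_rad_s) <= hi]

    t_valid, v_valid = tof_resampled.valid_points()
    samples: list[OscillationSample] = []
    for p in peaks:
        if jitter_half_width_s > 0:
            t_read = p.time_s + rng.uniform(-jitter_half_width_s, jitter_half_width_s)
            if t_valid.size < 2 or not (t_valid[0] <= t_read <= t_valid[-1]):
                continue
            d = float(np.interp(t_read, t_valid, v_valid))
        else:
            if not tof_resampled.valid[p.index]:
                continue
            d = float(tof_resampled.values[p.index])
        samples.append(
            OscillationSample(
                k=len(samples) + 1,
                t_peak_s=p.time_s,
                omega_peak_rad_s=p.omega_rad_s,
                d_irtof_mm=d,
                d_true_mm=float(d_true_mm),
            )
        )
    if not samples:
        logger.warning(
            "no oscillation with |omega| in [%g, %g] rad/s and a valid distance",
            lo, hi,
        )
    return samples
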