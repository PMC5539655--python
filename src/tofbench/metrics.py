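"""Accuracy statistics and the closed-form timing-error model.

Per dynamic condition (one AoI, one imposed distance d, N retained
oscillations with extracted distances d_k) the benchmark reports

    e    = (1/N) sum (d_k - d)                      mean error, mm
    sd   = sqrt( (1/(N-1)) sum (d_k - d)^2 )        spread, mm
    mae  = (1/N) sum |d_k - d|                      mean absolute error, mm
    mae% = 100 mae / d                              relative error, %

Note sd measures deviations from the TRUE distance d with an N-1 divisor,
exactly as the protocol defines it; it is not the conventional sample
standard deviation (which is exposed separately as ``sd_sample``).  Per
AoI, the per-distance indices are averaged (unweighted) into E, SD, MAE,
MAE%.

The timing-error model quantifies the effect of the peak-identification
ambiguity: the gyro samples at 100 Hz, so the lowest-point instant is
known only to within half a sample period (5 ms); during a time shift
``dt`` the pendulum tip travels an arc ``l * omega * dt``, which maps into
a distance error ``l * omega * dt * tan(AoI)`` on a target yawed by AoI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .extraction import OscillationSample

__all__ = [
    "ConditionError",
    "AoISummary",
    "TimingErrorInputs",
    "error_stats",
    "condition_errors",
    "aggregate_by_aoi",
    "regress_abs_error_vs_omega",
    "timing_error",
    "peak_time_ambiguity",
]


@dataclass(frozen=True)
class ConditionError:
    """e / sd / mae / mae% of one (AoI, d) condition.

    ``sd_mm`` deviates from the true distance (protocol definition);
    ``sd_sample_mm`` is the conventional sample SD about the mean reading,
    exposed for comparison.  ``sd`` fields are NaN when N < 2.
    """

    aoi_deg: float
    d_mm: float
    n: int
    e_mm: float
    sd_mm: float
    mae_mm: float
    mae_pct: float
    sd_sample_mm: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a condition needs at least one sample")


@dataclass(frozen=True)
class AoISummary:
    """Unweighted mean of the per-distance indices for one AoI."""

    aoi_deg: float
    mode: str
    n_conditions: int
    E_mm: float
    SD_mm: float
    MAE_mm: float
    MAE_pct: float


@dataclass(frozen=True)
class TimingErrorInputs:
    """Inputs of the closed-form timing-induced distance error."""

    length_mm: float
    omega_rad_s: float
    time_shift_s: float
    aoi_deg: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.time_shift_s < 0:
            raise ValueError("time_shift_s must be non-negative")


def error_stats(values_mm, d_true_mm: float) -> tuple[float, float, float, float, float]:
    """(e, sd, mae, mae%, conventional sample sd) of readings vs truth."""
    v = np.asarray(values_mm, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one reading")
    if d_true_mm <= 0:
        raise ValueError("true distance must be positive")
    dev = v - d_true_mm
    e = float(np.mean(dev))
    mae = float(np.mean(np.abs(dev)))
    if v.size >= 2:
        sd = float(np.sqrt(np.sum(dev**2) / (v.size - 1)))
        sd_sample = float(np.std(v, ddof=1))
    else:
        sd = sd_sample = float("nan")
    return e, sd, mae, 100.0 * mae / d_true_mm, sd_sample


def condition_errors(
    samples: Sequence[OscillationSample], aoi_deg: float = 0.0
) -> ConditionError:
    """Error indices of one condition from its extracted oscillation samples.

    All samples must share the same true distance (mixed conditions are
    rejected); ``aoi_deg`` labels the condition for aggregation.
    """
    if not samples:
        raise ValueError("no samples to summarize")
    d_set = {s.d_true_mm for s in samples}
    if len(d_set) > 1:
        raise ValueError(f"mixed conditions: true distances {sorted(d_set)}")
    d = d_set.pop()
    vals = [s.d_irtof_mm for s in samples]
    e, sd, mae, mae_pct, sd_sample = error_stats(vals, d)
    return ConditionError(
        aoi_deg=aoi_deg, d_mm=d, n=len(vals),
        e_mm=e, sd_mm=sd, mae_mm=mae, mae_pct=mae_pct, sd_sample_mm=sd_sample,
    )


def aggregate_by_aoi(
    per_condition: Sequence[ConditionError], mode: str = "dynamic"
) -> list[AoISummary]:
    """E/SD/MAE/MAE% per AoI: unweighted means across distances."""
    out: list[AoISummary] = []
    for aoi in sorted({c.aoi_deg for c in per_condition}):
        group = [c for c in per_condition if c.aoi_deg == aoi]
        out.append(
            AoISummary(
                aoi_deg=aoi,
                mode=mode,
                n_conditions=len(group),
                E_mm=float(np.mean([c.e_mm for c in group])),
                SD_mm=float(np.mean([c.sd_mm for c in group])),
                MAE_mm=float(np.mean([c.mae_mm for c in group])),
                MAE_pct=float(np.mean([c.mae_pct for c in group])),
            )
        )
    return out


def regress_abs_error_vs_omega(
    samples: Sequence[OscillationSample],
) -> tuple[float, float]:
    """First-order fit of |error| against peak angular velocity.

    Pools all oscillations of one AoI across distances and returns the
    OLS (slope mm/(rad/s), intercept mm) of |d_k - d| on |omega_k|.
    """
    if len(samples) < 2:
        raise ValueError("regression needs at least two samples")
    w = np.array([abs(s.omega_peak_rad_s) for s in samples])
    ae = np.array([abs(s.d_irtof_mm - s.d_true_mm) for s in samples])
    if np.ptp(w) == 0:
        raise ValueError("degenerate regression: all angular velocities equal")
    slope, intercept = np.polyfit(w, ae, 1)
    return float(slope), float(intercept)


def timing_error(inputs: TimingErrorInputs) -> float:
    """Magnitude (mm) of the distance error caused by a peak-time shift.

    ``l * omega * dt * tan(AoI)``: the arc travelled by the pendulum tip
    during the shift, projected through the target-plane slope.  The real
    error carries either sign depending on the shift direction; the
    magnitude of the bound is returned.
    """
    if abs(inputs.aoi_deg) >= 90:
        raise ValueError("timing error is unbounded at |AoI| >= 90 deg")
    return abs(
        inputs.length_mm
        * inputs.omega_rad_s
        * inputs.time_shift_s
        * math.tan(math.radians(inputs.aoi_deg))
    )


def peak_time_ambiguity(gyro_rate_hz: float = 100.0) -> float:
    """Worst-case peak-identification time error (s): half a sample period."""
    if gyro_rate_hz <= 0:
        raise ValueError("gyro_rate_hz must be positive")
    return 0.5 / gyro_rate_hz
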