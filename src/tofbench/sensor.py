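"""Forward model of the IR time-of-flight proximity sensor.

The device estimates range from the phase shift between an emitted
amplitude-modulated infrared wave ``s(t) = sin(2 pi f_m t)`` and its
reflection ``r(t) = R sin(2 pi f_m t - phi)``: the round trip over a
distance ``d`` delays the reflection by ``phi = 4 pi f_m d / c``, so
``d = c phi / (4 pi f_m)``.  The conversion is scale-invariant end to end,
so the simulator works directly in the distance domain;
:func:`distance_to_phase` / :func:`phase_to_distance` expose the ranging
model itself with the modulation frequency as a free parameter.

On top of the ideal ranging model, :func:`measure` applies the empirical
behavior of the packaged sensor: an additive bias depending on the angle of
incidence (AoI) between the boresight and the target normal, a per-color
reflectance offset, Gaussian electronic noise, quantization to integer
millimetres, range gating to the configured 0-200 mm window, and the
firmware convention of reporting the sentinel 0 when no reflection is seen
(including a hard dropout for black targets beyond ~140 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "NO_HIT",
    "COLORS",
    "DEFAULT_AOI_BIAS_MM",
    "COLOR_BIAS_MM",
    "ToFSensorSpec",
    "CalibrationModel",
    "distance_to_phase",
    "phase_to_distance",
    "measure",
    "fit_calibration",
]

SPEED_OF_LIGHT = 3.0e8
"""Speed of light in m/s (the value the ranging model rounds to)."""

NO_HIT = float("nan")
"""Sentinel for a line of sight that misses the target (any non-finite
value passed to :func:`measure` is treated as no hit)."""

COLORS = ("red", "green", "blue", "yellow", "white", "black")

#: Static mean error (mm) of the sensor versus angle of incidence, white
#: target.  Intermediate angles are linearly interpolated.
DEFAULT_AOI_BIAS_MM: dict[float, float] = {
    -60.0: -7.8,
    -30.0: -3.4,
    0.0: 0.2,
    30.0: 2.4,
    60.0: 0.4,
}

#: Per-color mean-error offset (mm) relative to a white target.  Black
#: additionally stops reflecting beyond ``black_cutoff``.
COLOR_BIAS_MM: dict[str, float] = {
    "red": -0.5,
    "green": -0.1,
    "blue": 0.5,
    "yellow": -0.5,
    "white": 0.0,
    "black": 12.5,
}


def _default_bias_table() -> dict[float, float]:
    return dict(DEFAULT_AOI_BIAS_MM)


@dataclass
class ToFSensorSpec:
    """Ranging physics plus noise/bias/dropout parameters of the sensor.

    Attributes
    ----------
    modulation_frequency_hz
        Modulation frequency ``f_m`` of the emitted IR wave.  Free
        parameter of the phase model; the distance-domain pipeline never
        consumes it.
    reflection_coefficient
        Amplitude ``R`` of the reflected wave.  Documented for completeness
        of the signal model; it does not enter the distance estimate.
    range_min_mm, range_max_mm
        Configured measurement window (0-200 mm for gait use).
    output_rate_hz
        Output data rate of the distance channel (50 Hz maximum).
    quantization_step_mm
        Reported resolution; the device reports integer millimetres.
    noise_sd_mm
        Standard deviation of the additive Gaussian electronic noise.
    bias_table_mm
        Map AoI (degrees) -> additive bias (mm); linearly interpolated.
    color
        Target reflectance profile; one of :data:`COLORS`.
    black_cutoff_mm
        Beyond this true distance a black target returns no reflection.
    no_reflection_value
        The sentinel the firmware reports when no reflection is observed.
    """

    modulation_frequency_hz: float = 10.0e6
    reflection_coefficient: float = 1.0
    range_min_mm: float = 0.0
    range_max_mm: float = 200.0
    output_rate_hz: float = 50.0
    quantization_step_mm: float = 1.0
    noise_sd_mm: float = 1.4
    bias_table_mm: dict[float, float] = field(default_factory=_default_bias_table)
    color: str = "white"
    black_cutoff_mm: float = 140.0
    no_reflection_value: int = 0

    def __post_init__(self) -> None:
        if self.range_min_mm >= self.range_max_mm:
            raise ValueError("range_min_mm must be < range_max_mm")
        if self.output_rate_hz <= 0:
            raise ValueError("output_rate_hz must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")
        if self.quantization_step_mm <= 0:
            raise ValueError("quantization_step_mm must be positive")
        if self.black_cutoff_mm > self.range_max_mm:
            raise ValueError("black_cutoff_mm must be <= range_max_mm")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}; expected one of {COLORS}")
        if not self.bias_table_mm:
            raise ValueError("bias_table_mm must not be empty")

    def bias_mm(self, aoi_deg: float) -> float:
        """Total additive bias at the given angle of incidence.

        Linear interpolation between the tabulated AoI nodes (constant
        extrapolation beyond them) plus the color offset.
        """
        nodes = np.array(sorted(self.bias_table_mm))
        vals = np.array([self.bias_table_mm[a] for a in nodes])
        return float(np.interp(aoi_deg, nodes, vals)) + COLOR_BIAS_MM[self.color]


@dataclass
class CalibrationModel:
    """Linear correction ``corrected = gain * raw + offset`` (mm)."""

    gain: float
    offset: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def apply(self, raw_mm):
        return self.gain * np.asarray(raw_mm, dtype=float) + self.offset


def distance_to_phase(d_mm: float, f_m_hz: float) -> float:
    """Phase shift (rad) accumulated over the round trip to a target.

    ``phi = 4 pi f_m d / c`` with ``d`` in metres internally.
    """
    if d_mm < 0:
        raise ValueError(f"distance must be non-negative, got {d_mm} mm")
    if f_m_hz <= 0:
        raise ValueError(f"modulation frequency must be positive, got {f_m_hz} Hz")
    return 4.0 * math.pi * f_m_hz * (d_mm / 1000.0) / SPEED_OF_LIGHT


def phase_to_distance(phi_rad: float, f_m_hz: float) -> float:
    """Distance (mm) recovered from a measured phase shift."""
    if phi_rad < 0:
        raise ValueError(f"phase must be non-negative, got {phi_rad} rad")
    if f_m_hz <= 0:
        raise ValueError(f"modulation frequency must be positive, got {f_m_hz} Hz")
    return SPEED_OF_LIGHT * phi_rad / (4.0 * math.pi * f_m_hz) * 1000.0


def measure(
    true_los_mm,
    spec: ToFSensorSpec,
    rng: np.random.Generator,
    aoi_deg: float = 0.0,
):
    """One (or a vector of) sensor reading(s) for true line-of-sight distances.

    Rules, in order: a non-finite input (no hit) reports the sentinel; a
    black target beyond the reflectance cutoff reports the sentinel;
    otherwise the reading is the true distance plus AoI/color bias plus
    Gaussian noise, quantized to the device step, and finally gated: a
    quantized value outside ``[range_min, range_max]`` reports the sentinel.

    Parameters
    ----------
    true_los_mm
        Scalar or array of true distances in mm; NaN/inf marks no hit.
    spec
        Sensor parameterization.
    rng
        Explicit random generator (reproducibility contract).
    aoi_deg
        Angle of incidence of the condition, used for the bias lookup.

    Returns
    -------
    float or ndarray
        Readings in mm, quantized to the device step (whole numbers for
        the default 1 mm step); the sentinel (0) for missing returns.
    """
    true = np.atleast_1d(np.asarray(true_los_mm, dtype=float))
    out = np.full(true.shape, float(spec.no_reflection_value))

    hit = np.isfinite(true)
    if spec.color == "black":
        hit &= true <= spec.black_cutoff_mm

    if hit.any():
        raw = true[hit] + spec.bias_mm(aoi_deg)
        if spec.noise_sd_mm > 0:
            raw = raw + rng.normal(0.0, spec.noise_sd_mm, size=raw.shape)
        q = spec.quantization_step_mm
        quant = np.round(raw / q) * q
        in_range = (quant >= spec.range_min_mm) & (quant <= spec.range_max_mm)
        out[hit] = np.where(in_range, quant, spec.no_reflection_value)

    if np.isscalar(true_los_mm) or np.ndim(true_los_mm) == 0:
        return float(out[0])
    return out


def fit_calibration(pairs) -> CalibrationModel:
    """Least-squares linear calibration from (reference, raw) reading pairs.

    Minimizes ``sum((gain * raw + offset - reference)^2)``; at least two
    distinct reference distances are required.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need a sequence of at least two (reference, raw) pairs")
    ref, raw = arr[:, 0], arr[:, 1]
    if np.ptp(ref) == 0:
        raise ValueError("degenerate calibration: all reference distances equal")
    design = np.column_stack([raw, np.ones_like(raw)])
    (gain, offset), *_ = np.linalg.lstsq(design, ref, rcond=None)
    return CalibrationModel(gain=float(gain), offset=float(offset))
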