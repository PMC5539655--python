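"""Uniformly sampled sensor channels.

A :class:`SensorStream` is the common container for the two channels the
platform logs on a shared clock: the gyroscope angular velocity (rad/s,
100 Hz) and the IR-ToF proximity readings (mm, 50 Hz).  ToF samples where
the firmware saw no reflection carry the sentinel value 0 and are flagged
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorStream"]


@dataclass
class SensorStream:
    """A uniformly sampled, timestamped scalar channel.

    Parameters
    ----------
    name
        Channel name, e.g. ``"gyro"`` or ``"tof"``.
    rate_hz
        Sampling rate in Hz; must be positive.
    values
        1-D array of samples (rad/s for the gyro, mm for the ToF channel).
    units
        Unit string, for provenance only.
    start_s
        Timestamp of the first sample on the shared clock (t = 0 at release).
    valid
        Boolean mask of the same shape as ``values``; invalid samples are
        sentinel/no-reflection readings or resampled points outside the
        interpolation support.  Defaults to all-valid.
    """

    name: str
    rate_hz: float
    values: np.ndarray
    units: str = ""
    start_s: float = 0.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask must match values in shape")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds on the shared clock."""
        return self.start_s + np.arange(self.values.size) / self.rate_hz

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) restricted to valid samples."""
        m = self.valid
        return self.times[m], self.values[m]
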