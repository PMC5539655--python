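"""CSV readers and writers for every artifact the pipeline exchanges.

All files are plain CSV with a header row; units are embedded in the
column names (seconds, mm, rad/s).  The shared clock starts at the
pendulum release (or the first capture frame).

Schemas
-------
gyro.csv            t_s, omega_rad_s
tof.csv             t_s, dist_mm, valid_flag
truth.csv           k, t_peak_s, omega_peak_rad_s, d_true_mm
oscillations.csv    k, t_peak_s, omega_peak_rad_s, d_irtof_mm, d_true_mm
summary_*.csv       condition, mode, E_mm, SD_mm, MAE_mm, MAE_pct
markers.csv         frame, time, <name>_X, <name>_Y, <name>_Z
phases.csv          cycle, stance_start, stance_stop, swing_start, swing_stop
ifd_report.csv      cycle, phase, tof_mean_mm, ref_mean_mm, error_mm
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import OscillationSample
from .gait import GaitCyclePhases, GaitPhaseAnnotation, IfdReport, MarkerFrame
from .metrics import AoISummary
from .pendulum import RigGroundTruth
from .streams import SensorStream

__all__ = [
    "write_gyro", "read_gyro",
    "write_tof", "read_tof",
    "write_truth", "read_truth",
    "write_oscillations", "read_oscillations",
    "write_summary",
    "write_markers", "read_markers",
    "write_phases", "read_phases",
    "write_ifd_report",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def _infer_rate(t: np.ndarray, path) -> float:
    dt = np.diff(t)
    if dt.size == 0 or np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: timestamps are not uniformly sampled")
    return 1.0 / float(dt[0])


def write_gyro(stream: SensorStream, path) -> None:
    pd.DataFrame({"t_s": stream.times, "omega_rad_s": stream.values}).to_csv(
        path, index=False
    )


def read_gyro(path) -> SensorStream:
    df = _read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    return SensorStream(
        "gyro", _infer_rate(t, path), df["omega_rad_s"].to_numpy(dtype=float),
        "rad/s", float(t[0]),
    )


def write_tof(stream: SensorStream, path) -> None:
    pd.DataFrame(
        {
            "t_s": stream.times,
            "dist_mm": stream.values,
            "valid_flag": stream.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_tof(path) -> SensorStream:
    df = _read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    return SensorStream(
        "tof", _infer_rate(t, path), df["dist_mm"].to_numpy(dtype=float),
        "mm", float(t[0]), df["valid_flag"].to_numpy(dtype=bool),
    )


def write_truth(truth: RigGroundTruth, path) -> None:
    pd.DataFrame(
        {
            "k": np.arange(1, truth.peak_times_s.size + 1),
            "t_peak_s": truth.peak_times_s,
            "omega_peak_rad_s": truth.peak_omegas_rad_s,
            "d_true_mm": truth.peak_d_true_mm,
        }
    ).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return _read_csv(path)


def write_oscillations(samples: Sequence[OscillationSample], path) -> None:
    pd.DataFrame(
        {
            "k": [s.k for s in samples],
            "t_peak_s": [s.t_peak_s for s in samples],
            "omega_peak_rad_s": [s.omega_peak_rad_s for s in samples],
            "d_irtof_mm": [s.d_irtof_mm for s in samples],
            "d_true_mm": [s.d_true_mm for s in samples],
        }
    ).to_csv(path, index=False)


def read_oscillations(path) -> list[OscillationSample]:
    df = _read_csv(path)
    return [
        OscillationSample(
            k=int(r.k), t_peak_s=float(r.t_peak_s),
            omega_peak_rad_s=float(r.omega_peak_rad_s),
            d_irtof_mm=float(r.d_irtof_mm), d_true_mm=float(r.d_true_mm),
        )
        for r in df.itertuples()
    ]


def write_summary(summaries: Sequence[AoISummary], path) -> None:
    pd.DataFrame(
        {
            "condition": [f"AoI = {s.aoi_deg:+g} deg" for s in summaries],
            "mode": [s.mode for s in summaries],
            "E_mm": [s.E_mm for s in summaries],
            "SD_mm": [s.SD_mm for s in summaries],
            "MAE_mm": [s.MAE_mm for s in summaries],
            "MAE_pct": [s.MAE_pct for s in summaries],
        }
    ).to_csv(path, index=False)


def write_markers(frames: Sequence[MarkerFrame], path) -> None:
    names = sorted(frames[0].positions)
    cols: dict[str, list] = {"frame": [], "time": []}
    for n in names:
        for ax in "XYZ":
            cols[f"{n}_{ax}"] = []
    for f in frames:
        cols["frame"].append(f.index)
        cols["time"].append(f.time_s)
        for n in names:
            p = f.positions.get(n)
            for j, ax in enumerate("XYZ"):
                cols[f"{n}_{ax}"].append(np.nan if p is None else p[j])
    pd.DataFrame(cols).to_csv(path, index=False)


def read_markers(path) -> list[MarkerFrame]:
    df = _read_csv(path)
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_X", "_Y", "_Z"))})
    frames = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        pos, missing = {}, set()
        for n in names:
            p = np.array([row[f"{n}_{ax}"] for ax in "XYZ"], dtype=float)
            if np.isnan(p).any():
                missing.add(n)
            else:
                pos[n] = p
        frames.append(
            MarkerFrame(
                index=int(row["frame"]), time_s=float(row["time"]),
                positions=pos, missing=frozenset(missing),
            )
        )
    return frames


def write_phases(phases: GaitPhaseAnnotation, path) -> None:
    pd.DataFrame(
        {
            "cycle": [c.cycle for c in phases],
            "stance_start": [c.stance[0] for c in phases],
            "stance_stop": [c.stance[1] for c in phases],
            "swing_start": [c.swing[0] for c in phases],
            "swing_stop": [c.swing[1] for c in phases],
        }
    ).to_csv(path, index=False)


def read_phases(path) -> GaitPhaseAnnotation:
    df = _read_csv(path)
    return [
        GaitCyclePhases(
            cycle=int(r.cycle),
            stance=(int(r.stance_start), int(r.stance_stop)),
            swing=(int(r.swing_start), int(r.swing_stop)),
        )
        for r in df.itertuples()
    ]


def write_ifd_report(report: IfdReport, path) -> None:
    pd.DataFrame(
        {
            "cycle": [r.cycle for r in report.records],
            "phase": [r.phase for r in report.records],
            "tof_mean_mm": [r.tof_mean_mm for r in report.records],
            "ref_mean_mm": [r.ref_mean_mm for r in report.records],
            "error_mm": [r.error_mm for r in report.records],
        }
    ).to_csv(path, index=False)
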