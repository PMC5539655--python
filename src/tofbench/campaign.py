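"""Reproducible benchmark campaigns: simulate -> extract -> metrics.

A campaign runs the full pendulum condition matrix (angles of incidence
0, +/-30, +/-60 degrees crossed with the legal imposed distances, 24
dynamic conditions in total) in both static and dynamic mode, reduces
each dynamic acquisition with the gyro-peak extraction pipeline, and
aggregates the error indices per AoI.  Every artifact is re-derivable
from the config plus the base seed: per-condition random generators are
spawned deterministically and a manifest records them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tbio
from .extraction import OscillationSample, extract_oscillations, resample_linear
from .metrics import (
    AoISummary,
    ConditionError,
    aggregate_by_aoi,
    condition_errors,
    error_stats,
)
from .pendulum import DEFAULT_DAMPING, PendulumRig, generate_condition, generate_static
from .sensor import ToFSensorSpec

__all__ = [
    "DEFAULT_CONDITIONS",
    "CampaignConfig",
    "CampaignResult",
    "run_campaign",
    "load_config",
    "save_config",
]

logger = logging.getLogger(__name__)

#: (AoI deg, imposed distance mm): the full benchmark matrix.  Minimum
#: distances grow with |AoI| so the swinging pendulum clears the target.
DEFAULT_CONDITIONS: tuple[tuple[float, float], ...] = tuple(
    [(0.0, d) for d in (40.0, 70.0, 100.0, 130.0, 160.0, 190.0)]
    + [(30.0, d) for d in (70.0, 100.0, 130.0, 160.0, 190.0)]
    + [(-30.0, d) for d in (70.0, 100.0, 130.0, 160.0, 190.0)]
    + [(60.0, d) for d in (100.0, 130.0, 160.0, 190.0)]
    + [(-60.0, d) for d in (100.0, 130.0, 160.0, 190.0)]
)


@dataclass
class CampaignConfig:
    """Condition matrix, sensor/rig parameters and seeds of one campaign."""

    conditions: tuple[tuple[float, float], ...] = DEFAULT_CONDITIONS
    color: str = "white"
    seed: int = 0
    noise_sd_mm: float = 1.4
    length_mm: float = 600.0
    damping_1_s: float = DEFAULT_DAMPING
    duration_s: float = 40.0
    static_n: int = 30
    omega_window: tuple[float, float] = (1.0, 6.0)
    jitter_half_width_s: float = 0.0

    def sensor_spec(self) -> ToFSensorSpec:
        return ToFSensorSpec(noise_sd_mm=self.noise_sd_mm, color=self.color)

    def rig(self, aoi_deg: float, d_mm: float) -> PendulumRig:
        return PendulumRig(
            imposed_distance_mm=d_mm,
            aoi_deg=aoi_deg,
            length_mm=self.length_mm,
            damping_1_s=self.damping_1_s,
        )


@dataclass
class CampaignResult:
    static_conditions: list[ConditionError]
    dynamic_conditions: list[ConditionError]
    static_summary: list[AoISummary]
    dynamic_summary: list[AoISummary]
    samples: dict[tuple[float, float], list[OscillationSample]]
    manifest: dict


def _condition_tag(aoi: float, d: float) -> str:
    return f"aoi{aoi:+03.0f}_d{d:03.0f}"


def run_campaign(config: CampaignConfig, out_dir=None) -> CampaignResult:
    """Run every condition of the matrix; failures are isolated per condition.

    When ``out_dir`` is given, writes per-condition gyro/tof/truth/
    oscillations CSVs, the two AoI summary tables and a JSON manifest of
    seeds and parameters.
    """
    spec = config.sensor_spec()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    static_cond: list[ConditionError] = []
    dynamic_cond: list[ConditionError] = []
    samples_by_cond: dict[tuple[float, float], list[OscillationSample]] = {}
    failures: dict[str, str] = {}

    for i, (aoi, d) in enumerate(config.conditions):
        tag = _condition_tag(aoi, d)
        logger.info("condition %s (%d/%d)", tag, i + 1, len(config.conditions))
        try:
            # static mode: n readings with the target held at d
            static = generate_static(
                d, aoi, spec,
                np.random.SeedSequence(config.seed, spawn_key=(i, 0)),
                n=config.static_n,
            )
            vals = static.values[static.valid][: config.static_n]
            if vals.size < config.static_n:
                raise ValueError(
                    f"static: only {vals.size} valid readings of {config.static_n}"
                )
            e, sd, mae, mae_pct, sd_sample = error_stats(vals, d)
            static_cond.append(
                ConditionError(aoi, d, int(vals.size), e, sd, mae, mae_pct, sd_sample)
            )

            # dynamic mode: pendulum release, peak-synchronized extraction
            rig = config.rig(aoi, d)
            gyro, tof, truth = generate_condition(
                rig, spec,
                np.random.SeedSequence(config.seed, spawn_key=(i, 1)),
                duration_s=config.duration_s,
            )
            tof100 = resample_linear(tof, rig.gyro_rate_hz)
            jitter_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(i, 2))
            )
            samples = extract_oscillations(
                gyro, tof100, d,
                omega_window=config.omega_window,
                jitter_half_width_s=config.jitter_half_width_s,
                rng=jitter_rng if config.jitter_half_width_s > 0 else None,
            )
            samples_by_cond[(aoi, d)] = samples
            dynamic_cond.append(condition_errors(samples, aoi_deg=aoi))

            if out is not None:
                cdir = out / tag
                cdir.mkdir(exist_ok=True)
                tbio.write_gyro(gyro, cdir / "gyro.csv")
                tbio.write_tof(tof, cdir / "tof.csv")
                tbio.write_truth(truth, cdir / "truth.csv")
                tbio.write_oscillations(samples, cdir / "oscillations.csv")
        except Exception as exc:  # isolate per condition
            failures[tag] = str(exc)
            logger.error("condition %s failed: %s", tag, exc)

    static_summary = aggregate_by_aoi(static_cond, mode="static") if static_cond else []
    dynamic_summary = (
        aggregate_by_aoi(dynamic_cond, mode="dynamic") if dynamic_cond else []
    )

    manifest = {
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "conditions"
            },
            "conditions": [list(c) for c in config.conditions],
        },
        "seed_derivation": "SeedSequence(seed, spawn_key=(condition_index, stage)); "
        "stage 0 = static, 1 = dynamic, 2 = peak-time jitter",
        "failures": failures,
    }

    if out is not None:
        if static_summary:
            tbio.write_summary(static_summary, out / "summary_static.csv")
        if dynamic_summary:
            tbio.write_summary(dynamic_summary, out / "summary_dynamic.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return CampaignResult(
        static_conditions=static_cond,
        dynamic_conditions=dynamic_cond,
        static_summary=static_summary,
        dynamic_summary=dynamic_summary,
        samples=samples_by_cond,
        manifest=manifest,
    )


def load_config(path) -> CampaignConfig:
    """Load a campaign config from a YAML key-value file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "conditions" in data:
        data["conditions"] = tuple(tuple(map(float, c)) for c in data["conditions"])
    if "omega_window" in data:
        data["omega_window"] = tuple(map(float, data["omega_window"]))
    return CampaignConfig(**data)


def save_config(config: CampaignConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["conditions"] = [list(c) for c in config.conditions]
    data["omega_window"] = list(config.omega_window)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
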