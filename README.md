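# tofbench

Simulation and benchmarking toolkit for **wearable infrared
time-of-flight (IR-ToF) proximity sensing** in human movement analysis.

Magneto-inertial units alone cannot measure the relative position of
body segments, so quantities that matter for gait stability — step
width, base of support, inter-foot distance (IFD) — are out of their
reach.  Pairing an MIMU with a short-range IR-ToF proximity sensor
closes that gap, but the sensor's accuracy must be characterized under
conditions that resemble gait: varying target color, distance, angle of
incidence (AoI) and relative velocity.  `tofbench` implements that whole
validation as tested, reproducible software:

- **`tofbench.sensor`** — the phase-shift ranging model
  (φ = 4π f_m d / c, d = c φ / 4π f_m) and a forward model of the
  packaged sensor: AoI-dependent bias, per-color offsets, Gaussian
  noise, 1 mm quantization, 0–200 mm range gating, black-target dropout
  beyond 140 mm and the sentinel-0 no-reflection convention.
- **`tofbench.pendulum`** — the dynamic benchmark rig: a damped uniform
  rod (θ̈ = −(3g/2l) sin θ − γθ̇) released from horizontal swings the
  sensor past a finite tilted target, emitting synchronized gyro
  (100 Hz) and ToF (50 Hz) streams plus ground truth.
- **`tofbench.extraction`** — the data reduction: 50→100 Hz linear
  resampling, 30-reading static averaging, alternating-sign gyro-peak
  detection, and per-oscillation distance extraction in the
  1–6 rad/s window.
- **`tofbench.metrics`** — error indices per condition
  (e, sd, mae, mae%), per-AoI aggregates (E, SD, MAE, MAE%), the
  |error|-vs-ω regression, and the closed-form timing-induced error
  l·ω·Δt·tan(AoI).
- **`tofbench.gait`** — the IFD application: marker-cluster coordinate
  systems, sensor/target pose calibration, the boresight-line ∩
  target-plane reference distance, phase-averaged comparison, and a
  synthetic two-foot gait generator.
- **`tofbench.campaign` / CLI** — reproducible full-matrix campaigns
  with per-condition seed derivation and CSV/JSON artifacts.

## Worked example

The worst-case timing error of peak-synchronized extraction: the gyro
samples at 100 Hz, so the lowest-point instant is known to within 5 ms;
at 6 rad/s on a 600 mm pendulum against a 60° target that maps to

```sh
$ tofbench timing-error --length 600 --omega 6 --dt 0.005 --aoi 60
31.2 mm
```

i.e. a ±31 mm worst-case distance error — which is why dynamic errors
grow so sharply with AoI.  Running the full benchmark campaign (24
static + 24 dynamic conditions, white target, ±5 ms peak-time jitter):

```sh
$ tofbench run-campaign --seed 0 --jitter 0.005 --out-dir campaign/
24 static and 24 dynamic conditions -> campaign/
AoI -60 deg dynamic: E = -12.4 mm, SD = 27.0 mm, MAE = 20.5 mm, MAE% = 14.8
AoI -30 deg dynamic: E = -3.6 mm, SD = 9.5 mm, MAE = 7.4 mm, MAE% = 6.6
AoI +0 deg dynamic: E = 0.3 mm, SD = 1.2 mm, MAE = 0.9 mm, MAE% = 1.0
AoI +30 deg dynamic: E = 0.9 mm, SD = 8.3 mm, MAE = 6.7 mm, MAE% = 6.0
AoI +60 deg dynamic: E = -9.8 mm, SD = 25.9 mm, MAE = 20.9 mm, MAE% = 15.0
```

At normal incidence the sensor tracks the imposed distance to ≈1 mm
even in motion; as |AoI| grows, the combination of timing ambiguity and
the moving line-of-sight geometry inflates the dynamic MAE by an order
of magnitude — the behavior the benchmark was designed to expose.
`campaign/` contains per-condition `gyro.csv` / `tof.csv` / `truth.csv`
/ `oscillations.csv`, the two AoI summary tables and a seed manifest;
rerunning with the same seed reproduces every file bit for bit.

The same library drives the gait stage:

```python
from tofbench.gait import (GaitParams, generate_synthetic_gait,
                           calibrate_pose, reference_series,
                           phase_means_and_errors)

gait = generate_synthetic_gait(GaitParams(), seed=2)
pose, plane = calibrate_pose(gait.static_frame, gait.right_cluster, gait.left_cluster)
ref = reference_series(gait.frames, pose, plane, gait.right_cluster, gait.left_cluster)
report = phase_means_and_errors(gait.tof, ref, gait.frame_times_s, gait.phases)
print(f"IFD = {report.ifd_mean_mm:.1f} mm, E = {report.E_mm:.2f} mm, "
      f"MAE = {report.MAE_mm:.2f} mm")
# IFD = 83.8 mm, E = -0.58 mm, MAE = 1.04 mm
```

The marker-based reference recovers the generator's prescribed
inter-foot distance (83.6 mm nominal) and the sensor agrees with it to
about a millimetre under 0.5 mm marker noise.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

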