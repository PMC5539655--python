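# Methods

`tofbench` simulates and analyses the benchmark of a wearable platform
that combines a magneto-inertial measurement unit (MIMU) with an
infrared time-of-flight (IR-ToF) proximity sensor for short-range
distance measurement during human movement (step width, inter-foot
distance).  This note documents the models, the parameter choices, the
numerical decisions, and the limits of what the synthetic experiments
can show.

## Ranging model

The sensor emits an amplitude-modulated IR wave `s(t) = sin(2π f_m t)`
and receives the reflection `r(t) = R sin(2π f_m t − φ)`.  The round
trip over a distance `d` delays the reflection by

    φ = 4π f_m d / c,      d = c φ / (4π f_m),

with `c = 3×10⁸ m/s`.  The conversion is exactly scale-invariant —
composing distance→phase→distance is the identity for any modulation
frequency — so the rest of the simulator works directly in the distance
domain.  `f_m` is kept as a free, documented parameter of
`ToFSensorSpec` (the packaged device does not publish it) and the phase
model is exposed and tested on its own (`distance_to_phase`,
`phase_to_distance`).  The reflection amplitude `R` is likewise carried
as a documented parameter that never enters the distance estimate.

## Sensor forward model

`measure()` maps a true line-of-sight distance to a reading:

1. no hit (non-finite input) → sentinel 0, the firmware convention for
   "no reflection observed";
2. black target beyond the reflectance cutoff (default 140 mm) →
   sentinel 0;
3. otherwise reading = quantize(true + bias(AoI) + color offset +
   N(0, σ)), quantized to the device step (1 mm: the device reports
   integer millimetres; sub-millimetre table resolutions arise only
   after averaging);
4. range gating: a quantized value outside the configured 0–200 mm
   window maps to the sentinel 0 rather than clipping, matching the
   no-reflection convention (whether the real firmware clips or zeroes
   above the ceiling is not documented; zeroing is this package's
   choice).

Defaults: σ = 1.4 mm; AoI bias table {0°: +0.2, +30°: +2.4, −30°: −3.4,
+60°: +0.4, −60°: −7.8} mm with linear interpolation between nodes and
constant extrapolation beyond; per-color offsets relative to white
(red −0.5, green −0.1, blue +0.5, yellow −0.5, black +12.5 mm).  The
bias/noise defaults reproduce the static error statistics reported for
the physical device, which makes parameter-recovery tests meaningful.
The color offsets are re-baselined to white because the AoI table was
measured with a white target; keeping both absolute would double-count
white's own bias.  With the default 0 mm range floor, a legitimate
reading of exactly 0 mm is indistinguishable from the sentinel; at the
bench's ≥40 mm distances this never occurs.

The "ad hoc calibration" of the device is modelled as a linear
gain/offset least-squares fit (`fit_calibration`); the true form is not
documented, and linear is the minimal choice.

## Pendulum rig

The dynamic benchmark swings the platform on a wooden pendulum (length
600 mm) released from horizontal past a stationary rectangular cuboid
target (180×70 mm face).  The pendulum is modelled as a uniform rod
pivoted at one end with viscous damping:

    θ̈ = −(3g / 2l) sin θ − γ θ̇ ,   θ(0) = π/2, θ̇(0) = 0.

Only the length and the peak angular velocity of the physical rig are
known; the uniform-rod assumption fixes the effective inertia and the
undamped closed form `ω_peak = √(3g/l) ≈ 7.00 rad/s` (l = 600 mm),
which the integrator must and does reproduce to <0.1%.  The damping
coefficient defaults to γ = 0.18 s⁻¹, tuned analytically
(γ ≈ 2 ln 6 / t_window) and confirmed numerically so that the peak
angular velocity decays through the 1–6 rad/s analysis window in ≈30
half-oscillations, matching the protocol's description of the
acquisition; γ remains a config parameter.  An "oscillation" is a
half-period — one directed pass through the lowest point, one gyro peak
of alternating sign — since each pass yields one distance sample.

Integration is a fixed-step classical RK4 at 1 ms, 10× oversampling the
gyro so that ground-truth peak times are known far below the 5 ms
ambiguity under study; sensor streams are taken by nearest-node
decimation (the 1 ms grid contains the 100 Hz and 50 Hz nodes exactly).
A mechanical-energy growth check rejects unstable step sizes.
Ground-truth peak times/velocities are refined below the internal step
by parabolic interpolation through the three samples around each
extremum.

Geometry: world X along the swing direction, Y along the boresight,
Z up, origin at the pivot.  The boresight is fixed perpendicular to the
swing plane, so the angle of incidence (AoI) is purely a yaw of the
target normal about the vertical; the plane is positioned so that the
line-of-sight distance at the lowest point equals the imposed distance
`d`.  For a lateral sensor offset `x` the ray–plane solve reduces to
`los = d + x·tan(AoI)`, and hits outside the finite target face return
`NO_HIT` (which the sensor model turns into sentinel readings — the
simulated traces therefore show valid data only around each pass, as
the physical traces do).  Condition pairs where the swing would collide
with the tilted target are rejected (|AoI| = 30° needs d ≥ 70 mm,
|AoI| = 60° needs d ≥ 100 mm).

A physical consequence of the damped model worth flagging: the |θ̇|
extremum does not fall exactly at the lowest point but leads it by
`Δx ≈ l γ ω / ω₀²` (≈26 mm at ω = 6 rad/s with the default γ).  At
AoI ≠ 0 this adds an alternating-sign geometric error of up to
`Δx·tan(AoI)` on top of the sampling-induced timing error, and is the
main reason simulated dynamic MAEs at ±60° reach ≈20 mm.  The bound
`|error| ≤ l·ω·(5 ms)·tan(AoI) + quantization` is therefore exact only
for an undamped rig, and is verified as such.

## Extraction pipeline

Mirrors the bench's data reduction: the 50 Hz ToF stream is linearly
interpolated onto the 100 Hz gyro grid (sentinel readings are treated
as missing — excluded from the interpolation support — because
interpolating through zeros would fabricate large errors; resampled
points outside the valid support are flagged invalid); static
acquisitions are summarized by the mean of the first 30 valid readings;
gyro peaks are detected by a three-point local-extremum test on the
signed signal (plateaus resolve to the earliest sample, determinism),
with sign alternation enforced by keeping the strongest extremum of a
same-sign run; one sample per peak with |ω| in the [1, 6] rad/s window
is extracted by reading the resampled distance at the identical
timestamp index.  Both swing directions contribute (the window tests
|ω|).

An optional uniform ±Δt peak-time jitter (default off, ±5 ms in the
recovery campaign) perturbs each read-out time before interpolation,
emulating peak-identification uncertainty beyond the intrinsic
half-sample (≤5 ms at 100 Hz) discretization that is always present.

## Error statistics and timing-error model

Per condition: `e` (mean error), `sd`, `mae`, `mae%` with the spread
measured about the **true** distance with an N−1 divisor — the
protocol's definition, not the conventional sample SD, which is exposed
separately (`sd_sample_mm`) for transparency.  Per AoI, the
per-distance indices are averaged unweighted (distances have
near-equal N and no weighting is documented).  The |error|-vs-ω
regression pools all oscillations of one AoI across distances, as the
bench analysis does.  Whether the per-AoI SD should be a mean of
per-distance sd's or a pooled SD is not documented; the mean-of-indices
reading is implemented.

The closed-form timing-induced error is `l·ω·Δt·tan(AoI)`: the arc the
tip travels during the time shift, projected through the target-plane
slope.  At l = 600 mm, ω = 6 rad/s, Δt = 5 ms, AoI = 60° this is
31.2 ≈ ±31 mm; it is linear in ω and Δt, strictly increasing in |AoI|,
and undefined at |AoI| = 90°.

## Gait inter-foot distance

The reference for the sensor during walking is marker-based: the
distance from the sensor centre to the intersection of the sensor-plane
normal (through the centre) with the target plane on the opposite foot.
Foot-fixed frames come from three-marker rigid clusters (origin at
marker 1; first axis toward marker 2; plane normal as third axis;
right-handed completion — only the origin rule is documented upstream,
the rest is this package's construction).  Calibration uses a static
frame with seven extra markers: sensor centre from the sensor marker,
boresight as the support-triad plane normal signed toward the
contralateral cluster, target plane from the target triad (centroid,
normal signed toward the sensor, in-plane axes from the first target
edge).  The exact support-plane construction of the physical protocol
is not detailed; this one is a documented choice.  The reference is
invariant under rigid world motions by construction and is verified as
such.

Per gait cycle, sensor and reference means over the right foot's stance
and swing phases are differenced; E, SD, MAE are taken across
cycle-phases and MAE% is normalized by the mean reference distance.
Phases are consumed as annotations (the generator provides them; real
use would import them) — inventing a gait-event detector is out of
scope.

The synthetic generator walks two rigid, non-rotating feet forward at
0.9 m/s (1.1 s cycles, 60% stance, smooth cosine swing advance, half a
cycle out of phase), with the lateral separation following a per-cycle
IFD profile drawn from N(83.6, 11.0) mm — the means reported for a
healthy walker — interpolated between cycle centres and floored at
30 mm so the feet cannot interpenetrate.  Markers carry isotropic
Gaussian noise (default 0.5 mm, typical of optical capture).  What the
generator deliberately omits: foot rotation (internal/external
progression angles), vertical foot lift, soft-tissue marker artefacts,
marker occlusions, and within-phase IFD dynamics beyond the slow
profile.  Passing tests therefore show the geometry/averaging pipeline
is correct and noise-robust, not that a real walker's foot rotations
are handled; AoI between boresight and target stays ≈0° in this
synthetic world.

## Campaign, seeds, problem sizes

`run_campaign` executes the full 24-condition matrix (AoI 0° at
40–190 mm; ±30° at 70–190 mm; ±60° at 100–190 mm) in static (30
readings) and dynamic (40 s release, ≈30 retained oscillations) mode.
Per-condition generators are spawned as
`SeedSequence(seed, spawn_key=(condition_index, stage))`, so any single
condition is re-derivable without running the others; a JSON manifest
records the seed derivation and config.  Failures (e.g. the black
target at 160 mm, where every reading drops out) are isolated per
condition and reported in the manifest.

Default problem sizes — 40 s simulated swing at a 1 ms step, 24
conditions, 10 gait cycles, 20 000-draw Monte-Carlo noise checks — keep
a full campaign under a second on one core while leaving estimator
standard errors well below the effects being measured (e.g. the static
per-AoI bias recovery interval is ≈0.3 mm against biases of 0.2–7.8 mm).

## Known limitations

- The simulator's dynamic errors arise from sampling ambiguity, the
  damped peak-offset geometry, noise and bias; real-device effects such
  as convergence time, ambient light, or reflectance-dependent phase
  distortion are not modelled, so simulated dynamic tables resemble but
  need not match hardware tables.
- The black-target model (hard cutoff + constant offset) compresses a
  reflectance continuum into two parameters.
- The linear calibration stands in for an undocumented procedure.
- The gait generator's simplifications listed above.
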