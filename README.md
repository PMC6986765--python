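# anthroneck

Anthropometrically scaled cervical-spine musculoskeletal models with
voxel-based inertia, static-optimization strength evaluation, and bilevel
calibration of muscle forces.

Neck loading cannot be measured in vivo, so estimates of cervical-spine
forces — for helmet design, head-supported mass limits, or injury-risk
studies — rely on musculoskeletal models. Existing detailed neck models
represent one subject or one percentile, and scaling them to a given
person's anthropometry while keeping the *overall neck strength* realistic
is not trivial. `anthroneck` is a toolkit for researchers in
biomechanics/ergonomics that builds 50th-percentile male and female neck
models (8 cervical joints, 24 DOF, 88 line-segment muscle fascicles),
calibrates their strengths to published targets, and then generates models
for any height / body mass / neck circumference / neck length or any
ANSUR II percentile (1st–99th).

## The model and the math

**Strength evaluation.** The maximum resistible load in a mode (flexion,
extension, lateral bending: a force at a skull landmark; axial rotation: a
pure moment) is found by increasing the load until static muscle
optimization can no longer balance the required joint torques. The inner
problem per load is the convex QP

```
min_f  Σᵢ (fᵢ/fᵢᵐᵃˣ)²  +  w_τ Σⱼ (τⱼˢⁱᵐ − τⱼᵉˣᵖ)²,   0 ≤ fᵢ ≤ fᵢᵐᵃˣ,
```

with tendon-excursion moment arms (τˢⁱᵐ = Rᵀf), w_τ = 100, and failure
declared when the RMS residual torque exceeds 0.1 N·m.

**Bilevel calibration.** A seeded global search over one force multiplier
per muscle group minimizes

```
J_F = Σₖ wₖ Σᵢ (τᵢˢⁱᵐ − τᵢᵉˣᵖ)²  +  J_p ,
```

where τᵉˣᵖ are the torques needed to resist the target strengths
(extension 254 N, flexion 122 N, lateral bending 173 N, axial rotation
11.2 N·m for the 50th-percentile male; female targets at 0.65× the male
values). J_p is a reciprocal over-strength penalty, active per mode when
the model can still hold targets inflated by 2 %. Group volume fractions
are constrained to ±5 % of the published in-vivo distribution, left/right
symmetry and within-group force ratios are exact by construction.

**Anthropometric scaling.** Segments scale with s_x, s_y, s_z from the
four measurements (neck: circumference & length ratios; skull: stature;
torso: volume-consistent); each muscle node carries s_vi = s_x s_y s_z, a
fascicle's volume factor is the weighted mean s_v = Σ (lᵢ/L) s_vi, its
length factor s_L = L/L₀, fiber/tendon lengths scale with s_L and the
maximum isometric force with the PCSA factor s_c = s_v/s_L.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Strengths of the packaged (uncalibrated) 50th-percentile male model:

```
$ anthroneck strength --gender male --mode all --gravity on
extension,flexion,lateral_bending,axial_rotation
180.5,88.5,121.5,7.79
```

Like the original model the method was developed on, the uncalibrated
model is uniformly weak against the literature targets (254 / 122 / 173 N,
11.2 N·m). Calibrating it (≈70 s per seed; here the best of five seeds):

```
$ anthroneck calibrate --gender male --seed 5 --out male50.json --report report.csv
$ cat report.csv
mode,target,optimized,difference_pct
extension,254.0,258.5,1.77
flexion,122.0,124.0,1.64
lateral_bending,173.0,174.5,0.87
axial_rotation,11.2,11.17,-0.27
```

All four modes land within 1.8 % of target (the published calibration's
worst deviation was 9.8 %). The analytic single-hinge fixture reproduces
its closed form f·r/d = 100 N × 0.03 m / 0.15 m:

```
$ anthroneck fixture --name single_hinge --out toy.json
$ anthroneck strength --model toy.json --mode flexion --gravity off --tolerance 0.01
flexion
20.0
```

Percentile sweeps (`anthroneck sweep --gender female --out fig_female.csv`)
emit per-percentile strengths for the 13 packaged percentiles; female
strengths increase monotonically in every mode, male strengths may dip at
individual percentiles because neck length and circumference grow at
different rates (no re-optimization is applied after scaling).

## Model files

Models are single JSON documents (`anthroneck.model.save_model` /
`load_model`): top-level keys `gender`, `segments[]`, `joints[]`,
`fascicles[]`, `landmarks[]`, `reference_anthropometry`, `metadata`;
lengths in metres, masses in kg, forces in N, angles in radians. Loading
validates every structural invariant (tree connectivity, fraction sums,
left/right pairing, orthonormal frames) and names the offending field on
failure. The packaged reference tables (strength targets, muscle-volume
distribution, original forces, percentile anthropometry) ship as CSV under
`src/anthroneck/data/`.

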