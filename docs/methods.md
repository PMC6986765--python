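# Methods

`anthroneck` implements a pipeline for generating anthropometrically scaled
whole-neck musculoskeletal models: a cervical-spine model with line-segment
muscle fascicles, voxel-based segment inertia estimation, strength
evaluation by static muscle optimization under incremental head loads,
bilevel calibration of maximum isometric muscle forces against target neck
strengths, and percentile/measurement-driven scaling of geometry, inertia
and muscle parameters. This note records the model assumptions, the
defaults and why they were chosen, the numerical methods, and the open
design choices that were resolved during implementation.

## The neck model

The skeleton is a tree of rigid segments — torso (root), C7 … C1, skull —
connected by eight joints (C7-T1 up to OC-C1), each with three rotational
degrees of freedom about the global axes at neutral posture (x anterior =
lateral bending, y left-lateral = flexion/extension, z superior = axial
rotation), 24 DOF in total. Intervertebral kinematics are prescribed: each
joint realises a fixed fraction of the overall head-to-T1 angle per
direction, constant over the range of motion. The per-joint fractions of
the source kinematic data are not published, so the default is uniform
(1/8 per joint, overridable in the model file); angle distribution is
linear and the fractions must sum to one per direction.

**Synthetic default geometry.** The original muscle-path coordinates the
method was developed on are not published, so the default 50th-percentile
male model uses a documented synthetic geometry: joint centres stacked on
the z axis at uniform spacing summing to the reference neck length
(10.8 cm), and attachment nodes at anatomically motivated offsets on or
inside the reference neck cylinder (radius = circumference / 2π ≈ 6.3 cm),
with skull and shoulder attachments at plausible skull/torso points. The
muscle inventory (44 base names, mirrored to 88 fascicles) and the original
maximum isometric forces are the published original-model values; the two
added deep flexors (rectus capitis anterior and lateralis) start at 32.5 N.
Three muscles that wrap in reality (the sternocleidomastoid heads and two
posterior extensors) carry one mid-cervical via point so their lower path
segment has a genuine tangential (circumferential) component; everything
else is a straight line, matching the straight-line limitation of the
method this package implements.

Because a straight-line stand-in geometry does not automatically have
realistic relative strengths, the attachment offsets were designed — and
numerically refined against the model's own strength evaluation — so that
the volume-constrained model's extension : flexion : lateral-bending :
axial-rotation capacity ratios are anatomically realistic (close to the
published 50th-percentile male target ratios 254 : 122 : 173 N : 11.2 N·m).
Two structural facts drove that design: (a) capacity in a mode is limited
not by the summed agonist moments but by the joint-by-joint torque profile
— straight torso-to-skull muscles over-torque the upper joints when the
lower-joint demand is met, and the excess must be cancelled by antagonists,
so extensor skull attachments are tapered toward the spine axis; (b) axial
rotation is intrinsically the scarcest capacity, carried by the tangential
path components of sternocleidomastoid, splenius, semispinalis/multifidus
and levator scapulae. Without this design the calibration below cannot
reconcile all four modes, for the same reason the original published model
needed extra flexors.

**Optimal fiber lengths** are not published. Per group, one fiber length is
chosen so the default male model's group volume fractions equal the
published male distribution exactly, with total muscle volume 813.9 cm³ at
the reference specific tension of 35 N/cm² (the lower bound of the
literature span 35–137 N/cm²; volume *fractions* are independent of the
constant). Within a group, all fascicles share the fiber length, so
within-group volume ratios equal the original force ratios. Tendon slack
length is the neutral path length minus the fiber length (floored at 0);
neither tendon nor fiber length affects the isometric neutral-posture
analysis — there are no force–length/velocity curves by design.

The iliocostalis cervicis fascicle is assigned to the longissimus cervicis
group (its nearest erector-spinae group in the published 16-group volume
table). The infrahyoid fascicles are routed to an anterior skull (jaw)
attachment, implementing the assumption that hyoid muscles participate in
maximal efforts through a clenched jaw.

Segment masses default to head 4.20 kg and whole-neck 1.66 kg (split
equally over C1–C7), torso the remaining body mass; only the masses and
COM positions matter for statics (gravity moments), not the inertia
tensors, which are carried for downstream dynamic use.

The female default model is derived from the male model: geometry and
inertia are scaled to the female reference anthropometry (1.63 m, 66.8 kg,
32.8 cm circumference, 10.6 cm neck length), then all maximum isometric
forces are rescaled by one common factor so the total muscle volume equals
the male total times the published female/male volume ratio 510.4/813.9.
Fascicle topology is identical between genders.

## Musculotendon mechanics

Path length is the summed Euclidean length of the posed polyline. Moment
arms use the tendon-excursion definition r = −∂L/∂θ, evaluated by central
finite differences with step 1e-5 rad (the arm then satisfies the virtual
work balance τ = Σ r·f). Finite differences were preferred over geometric
cross products because they are exact for arbitrary polyline paths and
multi-joint fascicles, including the via-point muscles. Halving the step
changes no entry by more than 1e-8 m.

## Voxel inertia

A watertight OBJ/STL surface is voxelized on a regular grid: a voxel is
occupied iff its centre is inside the mesh, decided by the crossing parity
of a vertical ray (vectorized 2-D point-in-triangle tests; a deterministic
sub-voxel jitter keeps rays off edges and vertices, with per-column retry
on odd parity). Ray parity was chosen over a signed-distance query because
it is exact for watertight meshes and costs one pass per column — a
full-body mesh at the default 5 mm voxel has ~10⁶ voxel candidates.
Occupied voxels are labelled by half-space segmentation rules that must
partition them (0 or ≥2 matches is an error listing offending centres).
Default head/neck/torso planes: head–neck through the tragion midpoint,
neck–torso through the 0.7·C7 + 0.3·clavicle point, both with z normals.
A uniform density is calibrated so the reconstructed mass equals the total
body mass exactly; per-segment mass/COM/inertia are accumulated with the
parallel-axis theorem. Each voxel's own cuboid inertia m·a²/6 is included
on the diagonal by default (a pure point-mass summation is available via a
switch); the term vanishes as the voxel size shrinks and improves
small-count accuracy. At characteristic-length/20 voxels, cylinder and
cuboid principal moments are within 2 % of closed forms (typically well
under 1 %).

## Strength evaluation

A loading mode applies an external load to the skull at neutral posture:
in a maximal-effort test the subject pushes anteriorly at the forehead
(flexion), posteriorly at the opisthocranion (extension) and laterally at
the temple (bending), so the external load on the head is the pad's
*reaction* — the opposite direction — and the agonists of the named mode
resist it; axial rotation applies a pure moment about z. The torque the
muscles must generate at every joint DOF is minus the moment of the load
(plus, by default, of the head/neck segment weights) about the joint
centre, projected on the DOF axes.

The muscle-redundancy problem at one instant is the bound-constrained
convex quadratic program

    min  Σ (f_i / f_i^max)²  +  w_τ ‖R᾿f − τ‖²,    0 ≤ f_i ≤ f_i^max,

with w_τ = 100. It is solved by a semismooth Newton method in the
24-dimensional torque space: at the optimum f = clip(w_τ (f^max)² (Rᵀr),
0, f^max) with r the torque residual, a piecewise-linear fixed point whose
merit function is strictly convex and piecewise quadratic; Newton steps
combined with an exact piecewise line search converge in ~10 iterations
(≈2 ms for 88 muscles), verified to 1e-12 against scipy's bounded least
squares on randomized problems, which also serves as the fallback. KKT
stationarity at the solution is ≤1e-8 in scaled units.

The model "fails" a load once the RMS residual torque over the cervical
DOFs exceeds 0.1 N·m (configurable); the maximum resistible load is found
by deterministic bisection to 0.5 N (forces) or 0.01 N·m (moments), after
doubling an upper bracket. The threshold makes the published "can no
longer maintain the static neutral posture" criterion explicit; note that
on toy models with few DOFs the threshold slack is visible (≈1 N on the
single-hinge fixture), so closed-form comparisons use a tighter threshold.

## Bilevel calibration

The outer level searches one force multiplier per muscle group; evaluating
a candidate solves the inner problem for the four modes at the target
loads, accumulating J = Σ_k w_k Σ_i (τ_i^sim − τ_i^exp)² with equal mode
weights. To reject over-strong models the targets are inflated by 2 % and
re-solved; for every mode whose inflated-target residual shows the model
can still hold the higher load, a reciprocal penalty w_k1/(ε + Σ residual²)
is added (ε = 1e-9), growing with reserve capacity; J_F = J + J_p.

The penalty gate deserves a note. Gating on a fixed residual magnitude
(e.g. 1e-3) fails for this model because the inner problem's effort term
leaves a residual floor — dominated by weakly actuated cross-axis DOFs —
that stays above 1e-3 until far beyond realistic over-strength, so the
objective would decrease monotonically toward the multiplier bounds.
The gate therefore asks the question directly: *can the muscles still hold
the 2 %-inflated load*, using the same RMS feasibility threshold that
defines strength failure (sum-of-squares tolerance n_dof · 0.1²). With
this gate the objective along the uniform-multiplier direction has a clear
minimum at the matched strength level and a steep penalty wall beyond it.

Structure is enforced by construction rather than constraints: one
multiplier per group keeps within-group force ratios and left/right
symmetry exact; a clip-renormalize repair projects the implied group
volume fractions into the ±5 % (relative; an absolute mode is available)
band around the published distribution while preserving the candidate's
total muscle volume, so the search effectively explores one overall
strength scale, a ±5 % per-group wiggle, and the separately bounded added
rectus capitis group (32.5–127 N, ≈32.5 × 137/35, reflecting the span of
reported specific tensions; these muscles are absent from the published
volume table and are excluded from its fractions). The global optimizer is
scipy differential evolution (seeded, popsize 7 × 17 dimensions, 25
generations ≈ 3100 evaluations, ≈70 s on one CPU; no polish step — the
penalty gate is discontinuous). Identical seeds give identical results.

Calibrating the default male model against the published male targets
lands all four achieved strengths within ~2 % of target (the published
model's own worst deviation was 9.8 %); recalibrating a uniformly weakened
(0.5×) model back to its original strengths recovers them within 2 % at a
reduced budget (popsize 5, 12 generations, ≈17 s per seed).

## Anthropometric scaling

Scale factors from four measurements: cervical segments take s_x = s_y =
the neck-circumference ratio and s_z = the neck-length ratio (one neck
factor shared by all seven cervical segments — the published method scales
a single neck segment and redistributes; the exact redistribution rule is
unpublished, so equal per-segment factors are used); the skull scales
isotropically with the stature ratio (skull scaling is unstated in the
source method; the head-landmark lever arms must grow with body size for
the percentile strength trends to emerge); the torso takes s_z = stature
ratio and lateral factors √(mass ratio / stature ratio), a
volume-consistent proxy for the out-of-scope statistical body-shape model
that keeps gravity loads and shoulder attachment positions plausible.

Muscle scaling follows the nodal-volume law: each node carries
s_vi = s_x s_y s_z of its segment; s_v = Σ (l_i/L) s_vi with l_i the
characteristic node lengths (half the incident edges) of the reference
geometry; s_L = L/L0; fiber and tendon lengths scale with s_L and the
maximum isometric force with s_c = s_v/s_L. For isotropic s this gives
exactly s_c = s² and fiber length × s.

Scaled models remember their reference model and cumulative per-segment
factors, and re-scaling composes factors and rebuilds from the reference.
This matches the intended workflow (everything is generated from the
50th-percentile model) and makes scale-then-inverse-scale exactly the
identity; re-applying the arithmetic-mean s_v law to an already-scaled
model would not be exactly reciprocal for fascicles spanning segments with
different factors (~1e-3 relative error at percentile-scale anisotropy).

Percentile models resolve the packaged male/female percentile tables
(1st–99th), apply the factors, and recalibrate the uniform density so the
total mass matches the percentile body mass. No muscle re-optimization is
performed after scaling — deliberately, since the non-monotone strength
progression reported for male percentiles arises exactly when no further
optimization is applied. A symmetrization utility averages left/right
quantities (idempotent), for models derived from asymmetric surface data.

## Synthetic body surfaces

`make_body_mesh` builds a watertight generalized cylinder (stacked
elliptical cross-sections with polar caps): a stylized torso, a prismatic
circular neck whose polygon perimeter equals the requested circumference
(slice-measured to <0.5 %), and an ellipsoidal head, with the landmarks
the pipeline needs (tragions, C7, clavicle, Adam's apple, forehead,
opisthocranion, temple). It stands in for non-redistributable statistical
body-scan surfaces: circumference/length/mass relationships are honoured;
skin-shape realism, limb geometry and inter-feature correlations are not.
Consequently the voxel pipeline's absolute head/neck masses from this
surface are demonstrations, not population estimates — passing tests show
the machinery is correct (conservation, convergence, plane partitioning),
not that the stylized surface reproduces published cadaver-based inertia
values, which would require the original scan data.

## Known limitations

* Straight-line muscle paths (plus three documented via points): bending
  moment arms are larger than wrapped paths would give; the calibration
  absorbs this into the force scales.
* No ligaments, discs, facet contact, passive torques, or activation
  dynamics; isometric neutral-posture analysis only.
* Uniform body density; single-subject-free synthetic geometry; the exact
  published optimized forces are not reproducible without the unpublished
  source geometry — the calibration machinery, scaling laws and trends
  are what this package reproduces.
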