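# Methods

This note records the modelling choices behind `gplkit`: what each
component computes, the parameters that matter, what the synthetic data do
and do not emulate, and the numerical decisions taken where the underlying
protocols leave the design open.

## Rigid transforms and the six accuracy components

All deviations are rigid by construction (a prosthesis and a mandible do
not scale or shear between plan and outcome), so the central object is a
4×4 homogeneous roto-translational matrix with an orthonormal, det = +1
rotation block (enforced to 1e-9; composition re-projects the rotation via
SVD when drift exceeds 1e-12).

The six components use the **extrinsic X-Y-Z Euler convention**,
`R = Rz(rot_z) · Ry(rot_y) · Rx(rot_x)`, angles reported in degrees and
translations in millimetres. Different conventions redistribute the same
matrix over the three angles differently; the convention is therefore
stated here and fixed throughout. `decompose` returns `rot_y ∈ [−90°, 90°]`
and is the exact inverse of `compose_from_components` away from gimbal
lock; at `|rot_y| = 90°` the residual one-parameter family is resolved by
`rot_x := 0` (folded into `rot_z`) with a warning. Clinically relevant
deviations are of order 1°, far from the singular set.

## GPL reference system

The GPL-RS is built from the reference mandible alone: the centroid is the
origin and the principal axes of the vertex cloud are the coordinate axes
(largest variance → X, then Y, then Z). Signs are fixed deterministically:
each axis is oriented so that the vertex with the largest absolute
projection lies on its positive side (ties broken by lowest vertex index),
and the third axis is flipped if needed for a right-handed frame. The
vertex cloud is unweighted, which makes the frame mildly sensitive to mesh
density; density is controlled by the synthetic generator here, and
resampling would be advisable before applying the frame to meshes of very
uneven tessellation. Component values are expressed in this frame; the
rigid-recovery property (injected deviation in, same deviation out) is
frame-independent.

The preoperative/planned mandible serves as the reference mandible — it is
the only intact whole-mandible geometry in a case bundle — and this is
configurable.

## Registration

Closed-form superposition is the Kabsch/Umeyama SVD solution with a
reflection guard. Collinear source points leave a rotation about the line
unconstrained and are rejected; coplanar points are well-posed and only
flagged, since four seed points picked on a surface patch are frequently
near-coplanar.

ICP uses point-to-triangle matching against the fixed surface with a
point-to-point (Kabsch) update — the floating and fixed models are
near-identical surfaces in every use here, where this simple variant
converges well and is exactly reproducible. Parameters: `tol = 1e-6` mm
change in RMS residual, `max_iter = 100`, optional match-distance cap
(default off; 10 mm for mandible-to-mandible alignment, where the
resection site guarantees partial mismatch), and a deterministic
index-stride subsample above 20 000 floating vertices. The matched-pair
residual history is monotonically non-increasing: each iteration's
candidate set always contains the previous iteration's matched triangle,
so the pre-update match distance never exceeds the previous post-update
distance, and the closed-form update can only lower it further.

Closest-point queries run against a KD-tree of triangle centroids with a
certified-exact two-stage search (a triangle can only beat the incumbent
if its centroid lies within best-distance + max circumscribing radius;
oversized triangles are midpoint-subdivided for query purposes so the
bound stays tight). Hausdorff statistics use this exact path; inside the
ICP loop a warm-started k-nearest-candidate variant is used instead, which
preserves monotonicity exactly (above) and whose rare mismatches only
perturb intermediate correspondences, not the fixed point.

Step 2 of the GPL chain needs a global initialization because the
postoperative scan pose is arbitrary. The two prosthesis models are
superposed by their principal-axes frames; since a body-spanning
prosthesis is nearly an end-symmetric arc tube, all four proper axis-flip
candidates are evaluated and the one with the smallest summed squared
surface distance is kept (deterministic tie-break by candidate order).
Step 3 starts from identity: after prosthesis anchoring the postoperative
mandible is already within the small-deviation regime.

## Method A

Accuracy per landmark pair is the difference of mean inter-landmark
distances (postoperative minus planned), each mean over three replicates.
Replicates are modelled as independent landmark-picking sessions — if the
three measurements reused one picked point set they would be degenerate
copies of each other, which cannot reproduce the intra-operator spread the
protocol is known for. A pair missing in any session is reported MISSING
for that case (complete-case behaviour mirrors the clinical protocol,
where the lingula pair is never evaluable on CT-derived models and the
notch/coronoid pairs only rarely).

## Method B

The directed (one-way) measure samples the postoperative model's vertices
against the planned surface; min/max/mean and RMS
(`sqrt(mean of squared distances)`) are reported, with a symmetric variant
pooling both directed sample sets (sorted before summarising so the
statistics are exactly swap-invariant). Sampling density equals vertex
density; the generator's meshes are uniform enough that no surface
oversampling is applied by default.

Seeded alignment mirrors the semi-automatic protocol: the operator's ≥ 4
point pairs give the closed-form initial registration, ICP refines it. In
the *measurement* simulation (`measure_case`) the refinement is bounded
(`tol = 1e-4`, 15 iterations): semi-automatic alignment tools improve on
the manual seeding but do not iterate to a unique optimum, and a fully
converged ICP would make the simulated Method B exactly as
operator-independent as GPL — the reliability contrast between the
protocols would be structurally impossible rather than empirically small.
With bounded refinement, between-operator variance grows monotonically
with seed noise and Hmax is more variable than Hmean, the qualitative
signature expected of this protocol family.

## Mixed-effects reliability model

Per metric: fixed effects for operator, occasion and their interaction,
and a random intercept per patient, fitted by REML (the standard choice
for variance components). Estimated marginal means are the fixed-effect
cell predictions on the operator × occasion grid; intra-operator contrasts
are occasion-2 minus occasion-1 within operator, inter-operator contrasts
are operator-pair differences within occasion. No multiplicity adjustment
is applied — reporting is CI-based.

Confidence intervals use a t reference with **df = n_patients − 1** (a
conservative between-within rule), recorded in the report as `df_method`.
A Satterthwaite or Kenward-Roger approximation would be marginally less
conservative at n = 17; the implementation platform provides neither, and
simulation under the generating model shows empirical 95% CI coverage of
94–96% with this rule. An all-constant response is handled as the exact
degenerate fit (all cell means equal, both variance components zero) with
a singular-fit warning; a zero patient-variance estimate likewise warns
but retains the fit.

## Synthetic data

The generator emulates only what the three protocols consume: geometry
with well-defined extremal landmarks, a prosthesis spanning a defect, a
known rigid deviation, and noise.

- **Mandible**: a horseshoe-shaped swept tube (default width 100 mm, depth
  70 mm, ramus height 60 mm) with condyle-like end caps, coronoid-like
  superior protrusions, gonial-angle dips, a chin-to-angle radius taper
  and a small (3%) left/right ramus asymmetry. The twelve Wilde landmarks
  are defined as extremal vertices in fixed parameter windows. This is
  deliberately minimal anatomy — a stand-in for clinical meshes, not a
  statistical shape model.
- **Defect classes**: arc-fraction spans of the body (three classes, drawn
  60/20/20 with random side), confined so the ramus landmarks stay
  measurable; in the clinical setting landmark loss is anatomy-driven,
  which is modelled by a per-case flag making the notch/coronoid pairs
  pickable in roughly 2 of 17 patients, while the lingula pair is never
  pickable.
- **Injected deviation**: the six true components are defined in the
  GPL-RS; the designed prosthesis is mapped by that displacement
  (conjugated into world coordinates) to give the postoperative
  prosthesis, while the postoperative mandible keeps the planned pose —
  so the prosthesis carries the placement error relative to the bone and
  the chain must recover exactly the injected components in the
  noise-free limit. Cohort draws: rotations N(0, 1°), translations
  N(0, 0.5 mm), clipped to ±3° / ±2 mm — the magnitude regime of reported
  clinical reconstructions.
- **Noise**: segmentation error is isotropic Gaussian vertex jitter
  (default 0.05 mm) on the postoperative models; operators have a fixed
  landmark bias vector plus isotropic picking noise (defaults 0.25, 0.30,
  0.35 mm for O1–O3), Gaussian seed-point noise (0.5–0.7 mm), and a
  systematic postoperative-distance widening bias (0, +0.1, −0.3 mm) —
  the simplest mechanism that produces reproducible between-operator
  disagreement of the magnitude reported for landmark protocols, since a
  constant bias vector cancels in pair distances.
- **Determinism**: one seeded generator, with named sub-streams spawned
  per case; identical parameters regenerate bit-identical meshes, landmark
  sessions, seeds and tables.

What passing tests on these data show: the pipeline recovers known rigid
deviations, is exactly reproducible, and propagates injected noise with
the expected structure. What they do not show: behaviour on real
segmentations (non-rigid anatomy change between scans, segmentation
topology defects, metal artefacts) or the anatomical validity of the
landmark definitions.

## Problem sizes and tolerances used in the shipped checks

Recovery checks run 50 noise-free cases (components uniform in ±3° / ±2 mm;
every component recovered within 0.05° / 0.02 mm — observed errors are
two orders of magnitude smaller) and 20 jittered cases at 0.1 mm (mean
absolute error bounds 0.3° / 0.2 mm). Hausdorff statistics are compared to
brute-force all-pairs minimisation on 20 random 50-vertex mesh pairs at
1e-9 mm. Mixed-model calibration uses 500 simulated balanced 17-patient
cohorts (patient sd 1.0, residual sd 0.3) for bias and coverage and 200
cohorts at residual sd 0.15 for detecting a −0.307 mm operator offset.
The standalone `scripts/acceptance.py` recomputes the same quantities at
moderately reduced replicate counts (30/10 recovery cases, 200/100
mixed-model cohorts).

## Known limitations

- Binary STL stores float32; the 1e-5 mm round-trip guarantee holds for
  coordinates below ~80 mm magnitude (true of centred anatomical models).
- The PCA reference frame is a documented stand-in for the original
  geometric GPL-RS construction; a different frame redistributes the same
  deviation over the six components, though the recovery property is
  unaffected.
- Step-3 alignment uses the full mandible meshes under a 10 mm distance
  cap rather than excluding the prosthesis region explicitly.
- ICC-style reliability indices and non-rigid registration are out of
  scope.
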