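# Methods

This note records the models, conventions and numerical choices behind
`cbctraj`, and what the synthetic studies do and do not demonstrate.

## C-arm geometry

The imaging system is isocentric with two rotation families. A pose is
parameterized by a primary sweep angle and a fixed oblique tilt:
RAO/LAO sweeps by θ₁ about the patient axis Z after a tilt ψ about X;
CRA/CAU sweeps by θ₂ about X after a tilt φ about Z. The composition order
is *tilt first, then sweep* (extrinsic rotations, `R = R_sweep · R_tilt`),
so a fixed oblique defines the plane in which an arc sweeps. Signs follow
the clinical convention: negative = right/caudal, positive = left/cranial.
The reference pose puts the source posterior at (0, −SAD, 0), the detector
u-axis along +X and v-axis along +Z; any consistent choice works because
every quality comparison is relative.

The metric geometry of a real C-arm is not part of the search problem, only
a carrier for it. Defaults are SAD = 810 mm, SDD = 1195 mm, configurable
detector size/pitch (`fit_detector` chooses a pitch that covers a given
volume diagonal with 10% margin). Angles are degrees everywhere; radians
appear only inside trigonometric calls.

## Arc space and collision handling

Arcs are capped at an 80° sweep. The default splits span each family's
range with 80-station arcs (79° inclusive spans), so a 4°-stride simulation
uses exactly 20 views per arc and 20/40/60 views for 1/2/3-arc states.
Forbidden regions are rectangles in (primary, oblique) coordinates; a
region can apply to one family or both. The 10% removal rule and the
cropping rule are evaluated on the 1°-sampled station set rather than as a
continuous measure — at 1° sampling the difference is negligible and the
discrete rule is exactly testable. Cropping keeps the single longest
collision-free run (first one on ties), preserving the one-arc-per-candidate
structure the greedy search assumes. Sparsification keeps obliques ≡ 0
(mod 6°), anchored at 0°; the anchor is arbitrary and configurable.
Neighbor moves shift the *oblique* by ±1°, because the oblique is the
dimension that sparsification thinned; the primary splits are never
sparsified, so re-densifying them locally has nothing to recover.

## Projector

The forward model computes cone-beam line integrals with a midpoint-rule
ray sampler: each ray is clipped against the volume bounding box and
sampled with trilinear interpolation at a 0.5-voxel step (per-ray step
adapted so the clipped span divides evenly). The backprojector scatters
with exactly the same sample positions and weights, so forward and adjoint
operators form a matched pair — the inner-product (dot) test holds to
floating-point precision, which the SART normalization relies on. Sample
coordinates are stored in float32 when cached (sub-1e-5-voxel rounding);
accumulation is float64. Accuracy against closed-form ray–ellipsoid chord
lengths is ~1% for rays well inside the silhouette at 64³/128²; near-tangent
rays see the voxelization's partial-volume band and are excluded from
accuracy checks (chord > half the maximum chord).

Volumes are stored in Hounsfield units and converted to linear attenuation
with μ = 0.02 mm⁻¹ · (1 + HU/1000), clipped at zero, before projection.

## ASD-POCS reconstruction

Each outer iteration (default 5) runs (a) one ordered-subsets SART sweep
(subset size 10, trajectory angle order, no randomization) with the
standard row-sum/column-sum normalization and a nonnegativity clamp, then
(b) total-variation steepest descent (default 20 steps) with a normalized
gradient. The first TV step length is `tv_step_ratio` (0.2) times the first
data-update magnitude; it shrinks by 0.95 whenever the TV stage moves the
image more than 0.95× the data stage, and the SART relaxation anneals by
0.995 per iteration. Two numerical guards are added to the classic
schedule:

* per-step backtracking in the TV stage (halve the step up to 5 times if TV
  would increase) — at linear-attenuation scale the nominal step otherwise
  overshoots and the stage would stall;
* the nonnegativity clamp is re-applied after the TV stage, so the output
  volume is truly nonnegative; clipping is 1-Lipschitz per voxel pair and
  therefore cannot increase TV.

Initialization is the zero volume; the whole reconstruction is
deterministic. The isotropic TV uses forward differences with ε = 1e-8
smoothing.

## Image metrics

FSIM follows the standard formulation: phase-congruency maps from a
4-scale × 4-orientation log-Gabor bank (smallest wavelength 6 px, scale
factor 2, σ_onf = 0.55, angular spread π/4/1.2, noise threshold k = 2 with
the usual response-median noise estimate), Scharr gradient magnitudes,
similarity constants T₁ = 0.85 and T₂ = 160 (for a 0–255 range), pooled
with the maximum phase congruency as weight. When the total
phase-congruency weight is negligible (flat images) the unweighted mean of
the similarity product is used, so identical constant images score 1
instead of 0/0. UQI is the windowed product of correlation, luminance and
contrast similarity (8×8 windows, stride 1, unbiased moments); degenerate
factors take their limiting value 1, variances are clipped at zero, and
moments below a scale-relative tolerance are treated as zero so sliding-sum
roundoff cannot fabricate correlations.

3D scoring is slice-wise along the axial axis (configurable), averaged over
the VOI, after jointly min-max normalizing the two cropped volumes to
[0, 255] with one shared affine map — scores are symmetric and independent
of any display window. The relative-deviation protocol compares a
candidate's score against the circular reference's score, both measured
against the prior.

## Greedy optimizer

Selection rounds alternate families starting with RAO/LAO. Every sparse arc
of the round's family is evaluated; the best `seed_count` (3) arcs seed
sequential ±1° hill climbs with a shared memo table (each oblique evaluated
at most once per round); lineages expand while a neighbor improves on its
parent. Ties break deterministically by smaller |oblique|, then smaller
start angle, then family order. A selected arc's stride-thinned projections
join the accumulated set used by all later evaluations. Per-orientation
projections of the prior are cached across candidates, since neighbors
share most of their stations.

## Synthetic phantom and study conditions

The phantom emulates a thorax/neck prior CT: a soft-tissue (40 HU)
ellipsoid body (semi-axes 28/22/30 mm) in air (−1000 HU) with three
1000 HU, 4 mm-radius vertebra-like inserts along the long axis — two
"thoracic", one "cervical" — voxelized with 2× supersampling so boundaries
carry partial-volume fractions. One VOI per insert; by default the prior is
noiseless (it plays the ground-truth digital-phantom role), and seeded
Gaussian noise in HU is available. Two kinematic scenarios are bundled: one
collision zone (primary −120…−60°, oblique −60…0°) and a second opposing
zone (primary 30…110°, oblique 0…50°), both applying to both families.

What the phantom does *not* emulate: realistic anatomy and texture,
polychromatic physics (beam hardening, scatter), detector blur and noise,
and gantry flex. Passing studies therefore demonstrate the correctness and
internal consistency of the search/reconstruction/scoring machinery, not
clinical image quality.

## Problem sizes used in the shipped studies

The full-scale configuration (256³ volume, 512² detector, obliques to
±60/±90°) is expressible in the configs but the shipped tests and the
acceptance study run a desk-scale version chosen as the package's standard
reference conditions: 32³ phantom (2 mm voxels, same 64 mm physical
extent), 32² detector, oblique range ±12°, 6° sparsification, 4° simulation
stride, 5 ASD-POCS iterations, scenario "one", the first (thoracic-analog)
VOI at 16³ voxels, and a 313-view/210° circular reference. The
greedy-vs-exhaustive check runs at 24³ with 13 obliques per split.

A consequence of the noiseless, simulation-only protocol is worth noting:
the VOI-targeted multi-arc trajectories can *exceed* the in-plane circular
reference inside the VOI (the simulation both generates and reconstructs
with the same operator, and the VOI rewards the oblique coverage the
optimizer selects). The absolute relative deviation |ref − meas|/ref then
*grows* as quality improves past the reference, so "deviation shrinks with
more arcs" — which holds when the reference is a strictly better real-world
scan — can invert at desk scale even though FSIM/UQI strictly improve from
2 to 3 arcs. The acceptance suite asserts both the literal deviation
ordering and the quality ordering separately rather than conflating them.

## Known limitations

* Single-threaded numpy implementation; the full 256³/512² preset is
  expressible but slow without acceleration.
* Forbidden regions are axis-aligned angular rectangles; arbitrary shapes
  (e.g. from a depth sensor) would need a rasterized region type.
* Only isocentric trajectories; no virtual-isocenter or variable
  magnification poses.
* FSIM is defined for 2D images; the slice-wise 3D extension is a
  convention (it affects all candidates identically, which is what the
  relative search needs).
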