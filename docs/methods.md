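# Methods

## Coordinate frame

All coordinates are millimetres. The standard frame is: +x toward the
patient's right, +y anterior, +z superior. It is constructed from seven
skull-base landmarks placed in anatomy unaffected by surgery or the
syndromes — the lateral and posterior points of both lateral semicircular
canals, both glenoid fossae, and the crista galli:

1. A total-least-squares plane is fitted to the six vestibular/glenoid
   points (smallest singular-vector of the centred points), and the six
   points are projected onto it.
2. The line through the projected lateral-canal points is mapped to the
   x-axis (right canal to +x) with its midpoint at the origin, and the
   plane normal to +z.
3. A final rotation about z brings the crista galli onto the anterior
   y–z half-plane (x = 0, y > 0).

Because the z-rotation follows the x-axis alignment, the canal line is
only *approximately* on the x-axis in the final frame. The guaranteed,
property-tested postconditions are: the projected canal midpoint is at
the origin; the best-fit plane coincides with x–y; crista galli has
x = 0, y > 0. (For noisy landmarks the *raw* canal midpoint retains the
mean off-plane residual of the two canal points in z; its x and y are
exactly zero.) Axis polarity is not intrinsic to the landmarks: the
superior side is chosen so that the static bone landmarks' centroid (or,
absent those, the crista galli) ends with z ≥ 0; `--flip-z` forces the
opposite.

Pre- and post-operative stages are aligned independently from their own
reference landmarks. Since those landmarks are static, both stages land
in a common frame; the residual pre/post RMS at static landmarks is
reported as a congruence diagnostic — with 1 mm placement noise it is
typically 2–3 mm because frame errors are amplified at distant landmarks
by the lever arm relative to the ~40 mm canal spread.

## The weighted RBF warp

Both the surgical and normalisation warps are vector-valued polyharmonic
splines `s(x) = c0 + Cx + Σ λᵢ φ(‖x − xᵢ‖)` fitted by the augmented
symmetric system shown in the README. Choices that matter:

- **Basis.** φ(r) = r (3D biharmonic) by default — the minimiser of the
  thin-plate bending energy among interpolants, i.e. the least-oscillatory
  field through the data. φ(r) = r³ (triharmonic, C² smooth) is selectable
  as `triharmonic_r3`.
- **Smoothing.** Per-centre diagonal augmentation `A_ii += α σᵢ²`
  (heteroscedastic spline smoothing). The residual at centre i is exactly
  `−α σᵢ² λᵢ`: zero-variance centres are interpolated exactly for any α,
  and the weighted residual `Σ rᵢ²/σᵢ²` is non-decreasing in α
  (property-tested). Default α = 1.
- **Variance estimator.** "Variance of the averaged landmark" is the trace
  of the sample covariance of the per-patient contributions divided by the
  contribution count (the variance of the mean — the fidelity target is
  the *average* vector). A `sample` option uses the raw trace instead.
- **One joint field.** Skin, facial-bone, static calvarial and reference
  landmarks all enter one fit as centres of a single 3D displacement
  field (three scalar solves sharing one factorisation), so bone and skin
  movements are never decoupled.
- **Numerics.** Dense direct solve (N ≲ a few hundred centres) with
  symmetric equilibration to remove the block-scale mismatch between
  φ-entries and the unit polynomial column; condition numbers above 1e13
  raise a diagnostic error. Duplicate centres (< 1e-6 mm apart) and
  coplanar centre sets (affine term unidentifiable) are rejected.
  Serialised warps round-trip bit-exactly through JSON (repr-based
  doubles).

## Cohort models and prediction

The surgical model averages pre→post change vectors per landmark over the
contributing datasets (sorted by patient id, hence order-independent) and
fits the weighted RBF at the averaged pre-operative landmarks. Static
landmarks contribute their (near-zero) change vectors as anchors.
Contributor lists are explicit: a model may be built from any subset, and
predicting a patient who contributed raises a data-leakage error unless
overridden. A single contributor is allowed (the degenerate "cohort of
two" case, where the model is simply the other patient's change vectors).

Normalisation fits the forward warp at the individual's 36 craniometric
positions with targets (cohort mean − individual) weighted by the cohort
craniometric variances, then fits the *reverse* warp at the
forward-warped positions with zero smoothing — an exact interpolant, so
forward-then-reverse restores every craniometric landmark to machine
precision. Reversal by exact re-interpolation was chosen over numerical
inversion of the forward field, which has no closed form once smoothed.

Prediction composes the three warps sequentially (pointwise function
composition, not displacement addition) and transports mesh vertices and
landmarks through the identical composite field. Provenance (contributing
ids, basis, α, config hash, package version) is recorded with every
output; identical inputs give bit-identical predictions.

## Evaluation

Closest-point queries are exact per-triangle scans (vectorised Voronoi
region classification), with ties resolved to the lowest face index.
Signed distance is positive when the predicted vertex lies outside the
actual surface — "the brow was over-predicted" reads as positive values —
with the side decided by the barycentrically interpolated vertex-normal
field of the actual mesh (robust at edges/vertices). If the actual mesh
is not consistently oriented the map falls back to unsigned values and
says so. Reliability SD is the 3D root-mean-square deviation from the
repeat-mean position (per-axis SDs also reported), banded on half-open
intervals [0,1), [1,2), [2,3), [3,∞) mm. Colour export uses a diverging
blue–green–red map, green at zero, clipped at user-set limits.

## Synthetic data: what it emulates, and what it does not

The generator produces bone surfaces as an analytic radial function on
the unit sphere — an anisotropic ellipsoid (turricephaly stretches z,
brachycephaly shortens y) with a facial protrusion flattened by mid-face
retrusion, a nasal ridge, and a seeded smooth asymmetry term odd in x —
and skin surfaces offset outward by a smoothly varying soft-tissue
thickness (thicker cheeks, thinner scalp). Landmark positions are exact
evaluations of the same functions at the dictionary's canonical
directions, so there is no mesh-snapping error and scale changes rescale
all distances exactly. Reference landmarks are interior skull-base points
that scale anisotropically but carry no asymmetry (the premise of the
reference frame is that this anatomy is unaffected).

The surgical field is analytic: a Gaussian advancement+descent bump at
the mid-face apex (default 15 mm forward, 5 mm descent, 32 mm falloff),
optional bipartition terms (para-midline maxillary divergence, orbital
medialisation) and an optional mandibular auto-rotation about the
condylar axis — all multiplied by a smoothstep gate that is exactly zero
on an ellipsoidal neighbourhood of the skull base. Placement noise
(default σ = 1 mm, matching typical manual reliability) perturbs
post-operative landmark placements only; surfaces are transported
noise-free.

What passing tests therefore show: the pipeline recovers a known smooth
surgical field from noisy landmark data under realistic size/shape
variation, with exact behaviour in the noise-free limit. What they do not
show: performance on real CT iso-surfaces with segmentation artefacts,
bespoke surgical remodelling (forehead, nasal grafts), growth between
scans, or landmarking by different operators — the stylised heads have no
such structure. With 1 mm placement noise and full shape variation, the
held-out mid-face landmark recovery sits around 1.6–2.2 mm RMS across
seeds: placement noise amplified through the reference frame plus
small-cohort averaging error, consistent with mid-face surface
differences of a couple of millimetres.

## Problem sizes and defaults

Synthetic cohorts default to icosphere subdivision 2 (162 vertices per
surface) — landmark-level accuracy is independent of mesh density, so
test cohorts stay small; evaluation tests use subdivision 4 spheres
(5120 faces) where surface sampling matters. Default cohort variation:
scale 68–84 mm, turricephaly 0.95–1.25, brachycephaly 0.80–1.00,
asymmetry 0–3 mm, retrusion 4–10 mm — spanning the tall, short, wide,
narrow and asymmetric phenotypes the normalisation must remove.

## Known limitations

- The reverse normalisation is exact at the craniometric centres but only
  approximate elsewhere; far from the head both warps revert to their
  affine parts.
- The biharmonic basis is C⁰ at the centres; fields are smooth elsewhere.
- Signed distance near thin or highly concave regions inherits the usual
  ambiguity of normal-based side tests; region-wise reporting (e.g. the
  mandible after auto-rotation) is the intended mitigation, not a
  geometric correction.
- The frame guarantees nothing about the canal line's final x-alignment
  (see above); no re-enforcement pass is applied.
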