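# craniowarp

Landmark-based prediction of post-operative head and face shape after
**monobloc** or **facial bipartition** distraction in children with syndromic
craniosynostosis (Apert, Crouzon).

Both operations free the forehead, orbits and mid-face from the skull base
and advance them gradually with an external distractor. Predicting the
resulting composite bone-and-skin shape change is hard: faces in these
cohorts vary enormously in size, proportion and asymmetry, and bone and
soft-tissue movements are coupled. `craniowarp` implements a pipeline that
addresses this with variance-weighted radial basis function (RBF) warps
fitted to manually placed anatomical landmarks:

1. **Alignment** — every patient dataset (pre- and post-operative skin and
   bone iso-surfaces plus landmarks) is placed in a standardised skull-base
   frame built from seven landmarks in unoperated anatomy: the lateral
   semicircular canals, the glenoid fossae and the crista galli. The
   vestibular/glenoid best-fit plane defines the horizontal, the canal line
   the transverse axis, and the crista galli the anterior midline.
2. **Shape–size normalisation** — an RBF warp moves the individual's 36
   craniometric bone landmarks toward the cohort average, removing size,
   proportion and asymmetry differences; its exact reverse is kept.
3. **Surgical warp** — pre→post change vectors at all 78 skin + 78 facial
   bone landmarks (plus static calvarial/skull-base constraints) are
   averaged over the *other* n − 1 patients of the cohort, and a
   variance-weighted RBF is fitted to the averaged vectors.
4. **Prediction** — normalise → surgical warp → reverse normalisation,
   applied identically to every mesh vertex and landmark.
5. **Evaluation** — signed-distance maps (positive = over-predicted,
   i.e. outside the actual surface) and per-region summaries; landmark
   placement reliability with <1 / 1–2 / 2–3 mm accuracy bands.

## The model

The displacement field is a vector-valued polyharmonic spline

```
s(x) = c0 + C x + Σᵢ λᵢ φ(‖x − xᵢ‖),   φ(r) = r   (biharmonic, default; r³ optional)
```

fitted per component by solving the symmetric augmented system

```
[ A + α·diag(σ²)   P ] [λ]   [f]
[ Pᵀ               0 ] [c] = [0]
```

with `A_ij = φ(‖xᵢ − xⱼ‖)`, `P = [1 x y z]` at the centres, `f` the target
change vectors and `σᵢ²` the per-landmark variance of the cohort average.
A zero-variance landmark is interpolated exactly for any smoothing
parameter α; high-variance landmarks trade fidelity for smoothness, keeping
the warp surgically plausible rather than "wiggly". The affine term lies
in the penalty null space, so translations and any affine field are always
reproduced exactly.

Since clinical CT data cannot be shipped, the package includes a
first-class synthetic generator (`craniowarp.synthetic`): head-like
skin/bone surface pairs carrying the full landmark schema, per-patient
variation in size, turricephaly, brachycephaly, asymmetry and mid-face
retrusion, and an analytic "surgical" field (advancement + descent,
optional bipartition divergence/medialisation) that is exactly zero at the
skull base and queryable anywhere — so every pipeline stage can be tested
against known ground truth.

## Worked example

```sh
craniowarp simulate --n 6 --seed 7 --out cohort
printf 'cohort_dir: cohort\noutput_dir: out\nseed: 7\n' > run.yaml
craniowarp run --config run.yaml
```

This simulates six varied patients (1 mm landmark placement noise), aligns
them, builds a leave-one-out surgical model and a normalisation warp for
each, predicts, and evaluates against the simulated outcomes:

```
INFO:craniowarp:aligned p000: 170 landmarks, static pre/post RMS 3.293 mm
...
pipeline complete: 6 patients predicted

p000  n-1 = 5 | skin mean signed dist  0.33 mm | landmark RMS 5.65 mm
p001  n-1 = 5 | skin mean signed dist -0.38 mm | landmark RMS 3.32 mm
p002  n-1 = 5 | skin mean signed dist -0.68 mm | landmark RMS 3.43 mm
p003  n-1 = 5 | skin mean signed dist -0.13 mm | landmark RMS 3.70 mm
p004  n-1 = 5 | skin mean signed dist  0.21 mm | landmark RMS 3.05 mm
p005  n-1 = 5 | skin mean signed dist  0.37 mm | landmark RMS 3.10 mm
```

Each line is one held-out patient: `n-1` is the number of datasets that
contributed to their surgical model (leave-one-out is machine-enforced),
the mean signed distance is the bias of the predicted skin surface against
the actual post-operative surface (fractions of a millimetre here), and the
landmark RMS compares predicted landmarks with the noisy "manually placed"
post-operative landmarks — at a cohort of six it is dominated by placement
noise and small-cohort averaging error. `out/<patient>/` contains the
predicted meshes (PLY), landmarks (CSV), the per-vertex signed-distance
sidecar and a provenance record (config hash, contributing patient ids,
basis, smoothing).

Other subcommands: `align`, `build-model`, `build-norm`, `predict`,
`evaluate` (see `craniowarp <cmd> --help`). Everything is also available as
a library; see `docs/methods.md` for the scientific details.

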