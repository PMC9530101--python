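# Methods

`meniscusmotion` quantifies how the medial (MM) and lateral (LM) menisci
move on the tibial plateau between knee positions imaged in 3D MRI —
typically a neutral reference and internally/externally rotated
positions under tibial torque. This note records the model, the numerical
choices, the synthetic data the package is validated on, and the limits
of what that validation shows.

## Coordinate conventions

All geometry lives in the world frame of the NIfTI affine (RAS+: +x
right, +y anterior, +z superior), in millimetres. Voxel indices are
0-based and refer to voxel centers; the index-to-world map is
`x = origin + direction @ (spacing * i)` with an orthogonal direction
matrix and strictly positive (possibly anisotropic) spacing.
Displacements, distances and all reported motions are world millimetres.

## Stage 1 — tibia-anchored rigid alignment

Meniscal motion is only meaningful relative to the tibia, so every
moving position is first aligned to the template by a 6-DOF rigid
transform `phi(x) = R(x - c) + c + t` (Euler angles `R = Rz Ry Rx`,
rotation center `c` = tibia-mask centroid) minimising the
sum-of-squared-differences restricted to the template tibia mask:

    f(p) = (N / N_valid) * v * sum_{x in tibia, valid} (T(x) - M(phi(x)))^2

with `v` the voxel volume. Voxels whose warped position leaves the
moving field of view carry no information and are excluded, with the sum
renormalised so that pushing voxels out of view can never lower the
objective (without this, large through-plane translations bias the fit
by up to ~0.8 mm). The minimisation uses L-BFGS-B with the analytic
gradient (sampled image gradient chained through the rigid map) on a
3-level Gaussian pyramid, coarse to fine. The solution is guarded: if it
scores worse than the identity it is replaced by the identity.

On the default 96×96×64 phantom (0.6×0.6×0.5 mm), random perturbations
up to 10° / 5 mm are recovered with a mean tibia-voxel error of ~0.01 mm
(clean trials) and < 0.25 mm in 20/20 seeded trials.

## Stage 2 — deformable registration of the menisci

Both menisci are registered in a single solve on the joint (MM ∪ LM)
mask pair; per-meniscus motion is extracted afterwards by cropping. The
displacement field `u` (mm, dense on the template grid, trilinearly
interpolated between voxels) minimises

    J[u] = SSD(T_s, M_s, u) + alpha * S[u] + beta * P[u]

* **Data term.** `T_s`, `M_s` are the template/moving mask indicators
  smoothed with a Gaussian of sigma = 1 voxel;
  `SSD = v/2 * sum_x (T_s(x) - M_s(x + u(x)))^2`. Smoothing gives SSD a
  capture range of a few voxels; raw MR intensities are deliberately not
  used (the menisci are thin, low-contrast structures and the
  segmentations are the trusted signal).
* **Curvature regulariser.** `S[u] = v * sum_l sum_x (lap u_l)^2`, the
  squared Laplacian of each component, discretised with spacing-aware
  central differences on interior nodes (boundary planes contribute
  zero, so constant and affine fields — global shifts and rotations —
  are penalty-free, and the discrete operator pair (L, L^T) is an exact
  adjoint pair). The conventional 1/2 prefactor of the variational form
  is absorbed into `alpha`. On a 10 mm cube at 64³ the discretised
  functional reproduces the closed form for a sinusoidal field
  (pi^4/20 ≈ 4.8705) within ~3%.
* **Distance (shape) penalty.** `P[u] = v/2 * sum_{x in template mask}
  D_M(x + u(x))^2`, where `D_M` is the Euclidean distance transform (mm)
  of the moving meniscus mask. Each template-meniscus voxel's warped
  position is pulled down the distance map onto the moving shape — the
  same direction the SSD term drives `u`, so the two terms share their
  minimiser. Because the distance map has global support, this term
  provides capture across arbitrary gaps: two crescents with zero
  overlap and a 7 mm gap register to Dice ≈ 1.0, while with `beta = 0`
  SSD alone achieves no overlap (its only descent directions for
  disjoint shapes erode the indicators in place). An alternative
  formulation that weights the warped moving indicator by the template
  distance map was implemented and rejected: its forces only shrink,
  never translate (Dice 0.0 on the same case).

**Optimisation.** Gauss–Newton, matrix-free: the normal equations
`(J^T J) delta = -grad J` are solved by conjugate gradients using only
operator applications (pointwise gradient outer products plus
`L^T L`), ≤ 45 CG iterations or relative residual 1e-2, followed by
Armijo backtracking (factor 0.5, c = 1e-4). Accepted iterates are
strictly non-increasing in `J`; line-search stagnation terminates the
level. A 3-level coarse-to-fine pyramid (factor-2, Gaussian
anti-aliased; coarsest ≥ 8 voxels/axis) avoids local minima; the coarse
field is prolonged by trilinear interpolation. At each level the
distance map and its mask weight are recomputed from re-binarised
downsampled masks, so identical masks incur an exactly-zero penalty at
every level (a blurred weight×distance product would not, and was
measured to inject a spurious ~0.2 mm field into the identity case).
The solver is deterministic; the `seed` argument exists for API
uniformity only.

**Defaults and units.** `alpha = 0.1` (curvature weight; S has units of
mm after the volume factor), `beta = 0.05` (mm⁻²-scaled shape weight),
12 Gauss–Newton iterations per level, `tol_rel = 1e-4`. These were set
by recovery experiments on phantoms with known fields: with `alpha = 1`
the regulariser biases a 4.3 mm translation by ~0.8 mm (under-recovery);
the defaults give mean endpoint errors of 0.1–0.3 mm for translations
and smooth bumps up to ~6 mm while keeping the zero-overlap capture
property. Larger `beta` (≥ 0.3) degrades accuracy: the nearest-point
pull locks in slightly wrong correspondences before SSD can refine them.

## Segment readout

* **Anatomical axes.** PCA of the combined MM+LM voxel cloud (world
  coordinates): the top-2 eigenvectors span the plateau plane. The
  in-plane axis with the larger projection of the MM-to-LM centroid
  difference is ML, oriented medial→lateral (the centroids encode
  laterality, so left and right knees come out consistently); the
  orthogonal in-plane axis is AP, oriented toward patient-posterior.
  Near-isotropic clouds (relative eigengap < 1e-6) are rejected.
* **Arch partition.** Meniscus voxels are projected into the plateau
  plane and parameterised by the polar angle about the crescent's
  *center of curvature*, obtained by a least-squares (Kåsa) circle fit
  that is then refitted on the extracted centerline (the one-pass fit on
  a thick half-annulus is biased ~1 mm toward the open side, enough to
  move a third-cut by ~7°). The arch must be connected with an angular
  gap ≥ 10° (a closed annulus has no endpoints). Arc length is
  accumulated along the centerline polyline (mean radius per ~2° bin,
  3-bin moving average) and cut at 1/3 and 2/3; the end whose voxels
  are more anterior becomes the anterior horn (AH), the other the
  posterior horn (PH), the middle the intermediate horn (IH). On
  circular-arc oracles the cuts land within ~2° of the exact thirds.
* **Per-segment motion.** For each segment (and the whole meniscus) the
  mean displacement vector ū over member template voxels is reported as
  `avg = |ū|`, `ml = ū·ml_axis` (+ = lateral), `ap = ū·ap_axis`
  (+ = posterior). `avg` is the norm of the mean vector, not the mean of
  per-voxel norms: each segment is summarised by one direction, matching
  how a single arrow per segment is interpreted; the alternative (mean
  of norms) would not distinguish coherent translation from incoherent
  jitter.

## Cohort statistics

Per-cell summaries are mean and sample SD (n−1). Paired comparisons use
the Wilcoxon signed-rank test, two-sided, with the classic treatment:
zero differences discarded, mid-ranks for tied magnitudes. The exact
null distribution is computed by dynamic programming over doubled
(integral) mid-ranks for n_eff ≤ 25 without ties, otherwise a normal
approximation with continuity and tie correction (agrees with the exact
p within 0.01 at n = 25). The comparison grid — internal vs external
per meniscus, MM vs LM per condition, each × {whole, AH, IH, PH} ×
{avg, ml, ap} — is exploratory and deliberately unadjusted for
multiplicity. Confidence intervals for the paired differences are not
emitted (the interval construction used alongside such tables is
method-dependent; only p-values are reported).

## Synthetic knees

No public in-vivo dataset exists for this protocol, so validation rests
on digital phantoms: a half-cylindrical tibial plateau (flat anterior
cut, smooth trabecular-like internal texture — the texture is what makes
an in-plane rotation of an otherwise nearly cylindrical bone observable)
and two annulus-sector crescents resting on the plateau plane, the MM
with a larger radius and wider arc (200°) than the more circular LM
(160°), at 0.6×0.6×0.5 mm resolution, with Gaussian intensity noise
(SD = 2% of tissue contrast; the masks, not the intensities, drive
stage 2, so noise mainly exercises stage 1).

Two motion paths are generated:

* **Smooth-field path** (`apply_motion`): a C¹, contraction-checked
  composition of global rigid repositioning, in-plane tibial rotation
  about the plateau center, per-meniscus plateau-weighted translations
  and an optional Gaussian bump (≤ 8 mm). Moving images are the template
  resampled through the exact inverse (rigid parts analytic, smooth part
  by fixed-point iteration), so the forward field on the template grid
  is known exactly. Used for deformable-recovery validation.
* **Sliding-render path** (`render_moving_position`, used by
  `simulate_cohort`): real menisci *slide on* the plateau — the
  interface motion is discontinuous and the tibia does not deform. A
  globally smooth field cannot represent that: in a compact field of
  view the translation weights drag the tibia by >1 mm and corrupt the
  rigid anchor. The renderer therefore re-evaluates the procedural
  anatomy with the rigid part applied to everything and each meniscus
  additionally translated in the tibia frame, with fresh acquisition
  noise per position. The tibia-relative ground truth is then exactly
  the per-meniscus translation.

Cohort simulations draw per-condition whole-meniscus translations from
Gaussians whose means/SDs emulate healthy knees under ~5 Nm tibial
torque at 20° flexion — internal rotation: MM (ML +0.14 ± 0.45,
AP −1.66 ± 0.99) mm, LM (−1.19 ± 0.71, +4.32 ± 1.15) mm; external
rotation: MM (+1.91 ± 0.89, +5.70 ± 1.49) mm, LM (−0.22 ± 0.58,
−3.51 ± 1.83) mm — plus a small superior–inferior component
(SD 0.2 mm), tibial rotation of ±8° ± 2°, and rigid repositioning
(1.5° / 1.5 mm SD). Drawn translations are capped at 8 mm magnitude
(physiologic range; also keeps the smooth-path warp invertible).
Laterality alternates right/left with mirrored anatomy.

## Problem sizes

The package's own validation sizes, chosen to keep the full test suite
and the acceptance script desk-scale: rigid recovery on the full
96×96×64 phantom; deformable recovery at 64×64×32 / 1 mm; cohort runs on
a compact 80×80×40 field of view at the clinical 0.6×0.6×0.5 mm
resolution with proportionally smaller menisci (outer radii 9–10.5 mm);
a 10-subject cohort end-to-end in the tests and a 6-subject cohort in
the acceptance script. Registration accuracy on the compact cohort
phantom is ~0.2–0.4 mm per subject-condition, against generating SDs of
0.45–1.8 mm.

## What passing tests do and do not show

The phantoms validate the *machinery*: geometric fidelity of the
registration and readout under known motion, correctness of the
statistics, and end-to-end reproducibility. They do not validate the
biology: real menisci deform non-rigidly in ways the translation + bump
model does not span; real segmentations carry boundary errors that the
clean procedural masks do not; MR intensity artifacts never enter.
Conclusions about in-vivo meniscal mechanics require real cohorts; what
the tests establish is that motions of the simulated kind and size are
recovered to a few tenths of a millimetre, well below the 1–6 mm
effects of interest.

## Known limitations

* Mask-driven stage 2: garbage segmentations yield garbage fields; no
  intensity fallback exists.
* The deformation field is regularised but not guaranteed
  diffeomorphic; extreme inputs could fold it.
* The arch partition assumes crescent topology; fragmented or annular
  masks are rejected rather than repaired.
* The exact Wilcoxon null assumes exchangeability under the null; the
  grid of tests is exploratory (no multiplicity adjustment by design).
* `avg` cohort means are means of per-subject vector norms, so the
  cohort `avg` need not equal the norm of the cohort (ML, AP) mean.
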