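# meniscusmotion

Quantifies how the menisci move on the tibial plateau between knee
positions imaged with 3D MRI — for example between internal and external
tibial rotation under load. It is aimed at musculoskeletal imaging
groups who have, per subject and position, a T1-weighted knee volume and
segmentation masks (tibia, medial meniscus MM, lateral meniscus LM), and
who want per-segment motion vectors and cohort statistics out the other
end.

## Method in brief

1. **Tibia-anchored rigid alignment.** Each position is aligned to a
   template position with a 6-DOF transform minimising the SSD
   restricted to the tibia mask, so all subsequent motion is relative to
   the tibial plateau.
2. **Deformable meniscus registration.** A dense displacement field
   u (mm, on the template grid) minimises

       J[u] = SSD(T_s, M_s, u) + α·∑_ℓ∫(Δu_ℓ)² + β·½∑_{x∈T} D_M(x+u(x))²

   where T_s/M_s are smoothed meniscus-mask indicators, the curvature
   term penalises the squared Laplacian of each component (affine fields
   are free), and the distance term scores each template-meniscus
   voxel's warped position against the Euclidean distance transform D_M
   of the moving meniscus — giving the solver a capture range even when
   the masks do not overlap at all. The optimiser is a matrix-free
   Gauss–Newton method (conjugate-gradient normal equations, Armijo line
   search) on a coarse-to-fine multilevel pyramid.
3. **Segment readout.** The field is cropped with the template meniscus
   masks; each crescent is split into anterior/intermediate/posterior
   horns (AH/IH/PH) by equal arc length along its arch; mean segment
   displacements are projected on PCA-derived anatomical axes
   (ML: + = lateral, AP: + = posterior).
4. **Cohort statistics.** Mean ± SD tables and paired two-sided Wilcoxon
   signed-rank tests (exact null for small samples, zeros dropped,
   mid-ranks for ties; no multiplicity adjustment) across rotation
   conditions and between menisci.

Because no public dataset exists for this protocol, the package ships a
synthetic-knee module (`meniscusmotion.phantom`) that generates phantom
cohorts with analytically known ground-truth motion; the entire test
suite runs on those. See `docs/methods.md` for the model details,
parameter defaults and validation scope.

## Worked example

```bash
meniscusmotion simulate --out cohort --subjects 2 --seed 7
meniscusmotion run-cohort --input cohort --out results --seed 1
```

(the same is available as library calls: `simulate_cohort(CohortSpec(...))`,
`run_cohort(RunConfig(...))`). `results/report.md` then contains, for
this seed:

```
| condition | meniscus | segment | Avg | ML | AP |
|---|---|---|---|---|---|
| external | MM | whole | 6.36 (0.95) | 1.18 (0.81) | 6.22 (0.82) |
...
| external | LM | whole | 4.62 (3.47) | -0.72 (0.53) | -4.47 (3.67) |
| internal | MM | whole | 1.64 (0.34) | 0.09 (0.22) | -1.61 (0.36) |
| internal | LM | whole | 3.47 (0.00) | -1.44 (0.05) | 3.15 (0.02) |
```

Reading the `whole` rows: in external rotation the medial meniscus of
these two simulated subjects moved on average 6.36 mm, decomposed into
1.18 mm lateral (positive ML) and 6.22 mm posterior (positive AP), while
the lateral meniscus moved 4.62 mm anterior-medially (negative AP and
ML); in internal rotation both directions reverse — the
opposite-direction pattern the cohort was generated with. The
parenthesised values are across-subject SDs, and `results/` also holds
the per-subject tidy CSV (`motions.csv`), the Wilcoxon comparison grid
(`comparisons.csv`), per-segment vector plots, and every intermediate
artifact (rigid parameters, deformation fields, segment label maps,
objective traces).

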