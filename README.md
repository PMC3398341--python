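# heartnc

Reconstruction of patient-specific 3D heart volumes from 2D planar
radiographs by **navigator-channel (NC) adaptation** of a population
deformation model.

The package implements the full chain on synthetic thorax/heart phantoms
with known ground truth:

1. **Population model** — logical-OR union of several subjects' binary
   heart masks, converted to a closed triangulated surface
   (`geometry_core`, `pipeline.run_build_population`).
2. **Population → reference registration** — iterated closest-point
   surface morphing with smoothed displacement updates, yielding a
   per-vertex deformation field with logged residuals (`registration`).
   This is a documented stand-in for a biomechanical FEM registration
   engine; only the surface displacement field is needed downstream.
3. **Reference/test matching** — thorax measurements (W1, W2, L) read off
   anterior radiographs and a root-sum-of-squares difference score, with
   lowest-score matching inside each group (`matching`).
4. **Radiograph normalization** — parallel-projection radiograph
   synthesis from CT attenuation volumes, graticule re-scaling of the test
   image, and translation-only rigid alignment on midline bony landmarks
   (`projection`).
5. **Navigator channels** — six rectangular channels (4 horizontal at the
   chamber circumflexes, 2 vertical at the superior/inferior edges)
   turn local organ-edge displacements into 1D intensity-profile shifts
   via the inflection point of the smoothed profile (`navigator`).
6. **Adaptation** — the core: per-node linear (upper/lower regions,
   superior–inferior) and bilinear (middle region) blending of the
   channel ratios `(ΔNC + ∂NC) / ΔNC` converts the population→reference
   field into a population→test field; anterior–posterior components pass
   through unchanged (`adaptation`).
7. **Evaluation** — Dice volume overlap (optionally center-of-mass
   aligned), cohort summaries, paired t-test (`evaluation`).
8. **Phantoms** — seeded generators for superellipsoid-with-lobes hearts,
   thorax CT volumes with ribs/spine at prescribed W1/W2/L, and
   ground-truth deformations (`phantom`).

## CLI

```bash
heartnc fixtures --out fixtures/ --seed 1 --n 3     # small phantom cohort
heartnc build-population --masks a.nii.gz --masks b.nii.gz --out pop.vtk
heartnc match --refs refs.csv --tests tests.csv --out out/
heartnc reconstruct --seed 1 --out out/             # seeded phantom cohort
heartnc evaluate --seed 1 --out out/                # + Dice summary, paired t
heartnc shifts --seed 1                             # per-channel edge shifts
```

All commands accept `--config run.yaml` (see `heartnc.pipeline.RunConfig`
for the keys). Exit codes: 0 success, 2 validation error, 1 stage failure.

## File formats

Masks and CT volumes: NIfTI (header in mm, converted to cm). Meshes:
legacy ASCII VTK PolyData and PLY. Deformation fields: CSV
(`vertex_index,dx,dy,dz`) or VTK point data. Radiographs: 16-bit PNG with
a JSON sidecar (spacing, landmarks, contour, calibration).

## Conventions

Patient frame: +x patient left, +y patient inferior, +z patient
posterior, units cm. Voxel `(i, j, k)` has its center at
`origin + (i + ½, j + ½, k + ½) · spacing`. Channel roles: NC1/NC2
right/left lower circumflexes, NC3/NC4 right/left upper, NC5 superior and
NC6 inferior edge by default (configurable via `superior_role`).
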