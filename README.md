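# pbnrr — physics-based non-rigid registration for intra-operative brain shift

After the skull is opened during neurosurgery, the brain deforms by
several millimetres ("brain shift"), invalidating the rigid alignment
between the pre-operative MRI and the patient. `pbnrr` implements
physics-based non-rigid registration (PBNRR): sparse displacements are
measured by block matching and regularized by a linear-elastic
tetrahedral finite-element model of the brain, with iterative rejection
of outlier matches. It adds the geometric resection-aware and
incremental adaptive extensions (removal of mesh elements that fall
into the resection cavity; re-mesh → register → compose loops for large
deformations), registration-point-driven mesh-sizing metrics, and a
synthetic phantom generator with known ground truth. It is aimed at
researchers in medical image registration and image-guided-therapy
pipelines; it is not a clinical product.

## Method

Feature points are selected in the floating (pre-operative) image where
the local intensity variance is high. For each point, every integer
voxel displacement `d` with `|d| ≤ W` is scored against the fixed
(intra-operative) image by normalized cross-correlation of the
`(2B+1)`-voxel block, giving a sparse displacement vector `D` with
confidence weights `S` (per-match weight `max(c,0)² I₃`). The mesh
displacement `U` solves the regularized interpolation system

    [K + HᵀSH] U = HᵀSD + F,      F ← K·U   (updated each iteration)

where `K` is the global stiffness matrix of 4-node linear tetrahedra
with isotropic Hookean materials per tissue label, and `H` interpolates
nodal displacements to the match points by barycentric weights. The
external force `F` progressively relaxes the internal mesh stress, so
the iteration converges toward the approximation problem
`argmin_U (HU−D)ᵀS(HU−D)`; along the way, a total fraction `f_R` of the
matches is discarded over `n_R` iterations, ranked by the per-block
error `ξ_k = (H_k U − D_k)ᵀ S_k (H_k U − D_k)`. The nodal solution is
rasterized to a dense displacement field and the floating image is
backward-warped into the intra-operative frame.

Resection is handled geometrically: tetrahedra whose displaced samples
fall below an intensity threshold in the intra-operative image and form
a maximal face-connected submesh are removed from the model. The
adaptive loop re-meshes the incrementally warped label image on a
body-centered-cubic (BCC) lattice each iteration and composes the
incremental fields, so large deformations never invert elements within
a single solve. Registration accuracy is evaluated with the untrimmed
Hausdorff distance between Canny-edge point sets — a relative
comparison instrument, not a clinical measure.

## Worked example

```python
import numpy as np
from pbnrr import (PhantomSpec, make_phantom, BlockSpec, SolverConfig,
                   bcc_mesh, register_images, evaluate_registration)
from pbnrr.robust_solver import sample_field

ph = make_phantom(PhantomSpec(size=(64, 64, 64), seed=42, deform_max=4.0))
mesh = bcc_mesh(ph.labels, cell_size=8.0)
res = register_images(ph.preop, ph.intraop, mesh,
                      block_spec=BlockSpec(B=(3, 3, 3), W=(5, 5, 5)),
                      solver_cfg=SolverConfig(n_R=5, f_R=0.25),
                      mask=ph.labels)
truth = sample_field(ph.truth, mesh.vertices)
err = np.linalg.norm(res.U - truth, axis=1)
base = np.linalg.norm(truth, axis=1)
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_tets} tets")
print(f"matches: {len(res.matches)} found, {len(res.kept)} inside the mesh, "
      f"{len(res.log['rejected_ids'])} rejected as outliers")
print(f"mean nodal error: {err.mean():.2f} mm "
      f"(zero-displacement baseline {base.mean():.2f} mm)")
report = evaluate_registration(ph.preop, ph.intraop, res.field)
print(f"Canny/Hausdorff: {report['hausdorff_mm']:.2f} mm")
```

prints

```
mesh: 302 vertices, 1080 tets
matches: 432 found, 297 inside the mesh, 74 rejected as outliers
mean nodal error: 0.77 mm (zero-displacement baseline 2.27 mm)
Canny/Hausdorff: 2.45 mm
```

i.e. on a 64³ phantom with a smooth 4 mm peak deformation, the solve
reduces the mean nodal misalignment from 2.27 mm to 0.77 mm — close to
the ~0.6 mm floor set by the integer-voxel matching quantization at
1 mm voxels. The same pipeline is available from the shell:

```bash
pbnrr phantom --seed 42 --out-dir work/
pbnrr mesh --labels work/labels.nii.gz --cell-size 8 --out work/brain.vtk
pbnrr register --fixed work/intraop.nii.gz --floating work/preop.nii.gz \
    --mesh work/brain.vtk --mask work/labels.nii.gz \
    --out-field work/field.nii.gz --out-warped work/warped.nii.gz
pbnrr evaluate --preop work/preop.nii.gz --intraop work/intraop.nii.gz \
    --field work/field.nii.gz --out work/report.json
```

`pbnrr adapt` runs the incremental adaptive loop and `pbnrr metric`
exports isotropic or anisotropic mesh-sizing fields.

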