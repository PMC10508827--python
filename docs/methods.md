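# Methods

## Model and assumptions

The registration treats the brain as an isotropic, linear-elastic
(small-strain) solid discretized with 4-node constant-strain
tetrahedra. Each element carries a tissue label mapped to a Young's
modulus `E` (Pa) and Poisson ratio `ν`; the defaults — parenchyma
`E = 3000 Pa, ν = 0.45`, tumor `E = 9000 Pa, ν = 0.45` — are this
package's configurable defaults, chosen in the range commonly used for
brain biomechanics (soft, nearly incompressible tissue with a stiffer
tumor). No Dirichlet boundary conditions are imposed: the data term
`HᵀSH` itself renders the system positive definite as long as the
matches constrain all six rigid modes, which a handful of
non-collinear matches always does. The solver verifies the residual of
every linear solve and raises a conditioning error (with a
smallest-eigenvalue estimate) otherwise.

Only the *relative* magnitude of the elastic term against the match
term matters to the solution. The stiffness is therefore multiplied by
an explicit scale, by default chosen so `trace(K)/trace(HᵀSH) ≈ 10`;
the resolved value is reported in the run log. Heavier smoothing slows
the stress-relaxation loop's convergence toward the approximation
problem but does not change its limit.

Block matching searches integer voxel displacements only, with ties
broken toward the smaller displacement norm and then lexicographically
on `(dz, dy, dx)` — deterministic and biased toward no motion. Feature
selection ranks candidate block centers by intra-block sample variance
and keeps the top fraction, greedily thinned to a minimum spacing
(highest variance wins). An optional absolute variance threshold is
exposed for users who prefer a fixed cutoff.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `B` | (3, 3, 3) | voxels | block half-extent for NCC |
| `W` | (5, 5, 5) | voxels | displacement search half-range |
| `fraction` | 0.05 | — | share of candidate blocks kept as features |
| `min_spacing` | 2.0 | voxels | minimum distance between features |
| `min_confidence` | 0.5 | — | NCC below which a match is dropped |
| `f_R` / `n_R` | 0.25 / 5 | — | total rejected fraction / iterations |
| `relax_tol` / `relax_max_iter` | 1e-3 / 50 | — | relaxation stop rule |
| `linear_tol` | 1e-8 | — | relative residual of each solve |
| `target_trace_ratio` | 10 | — | trace(K)/trace(HᵀSH) balance |
| `cell_size` | 8.0 | mm | BCC lattice cell |
| `bg_fraction` | 0.8 | — | background samples needed to flag a tet |
| `N_iter` | 5 | — | adaptive increments |
| `k` / `a` | 5 / 1.2 | — | sizing neighbors / ellipsoid inflation |

Per-match weights are `max(c, 0)² I₃` with `c` the NCC value, so
negative-correlation matches carry no weight; the 3×3 tensor slot
keeps the door open for anisotropic (structure-tensor) weighting.

## Numerical choices

**Relaxation restart.** The stress-relaxation iteration
`U ← [K+HᵀSH]⁻¹[HᵀSD + KU]` has eigenvalue exactly 1 on the null space
of `HᵀSH`: displacement components without match support never forget
their history, including the influence of matches later rejected as
outliers. After the last rejection the relaxation therefore restarts
from the interpolation solve (`F = 0`) of the cleaned system, which
pins unsupported degrees of freedom to the elastic solution. When
nothing is rejected this coincides with the plain first iteration. The
relaxation residual `(HU−D)ᵀS(HU−D)` is provably non-increasing from
any starting point, and is recorded per iteration in the run log.

**Rejection schedule.** `⌊f_R·n/n_R⌋` blocks per iteration with the
remainder in the last rejection iteration, i.e. exactly `⌊f_R·n⌋`
total; ξ ties break toward lower confidence, then lower match id.

**Point location.** Containing tetrahedra are found through a k-NN
search on element centroids with barycentric verification at tolerance
1e-9, widening the candidate set until resolved; points outside every
element are dropped (with their index reported), not an error.

**Degenerate inputs.** Elements below 1e-12 mm³ volume raise a
degenerate-element error naming the element. NCC of a zero-variance
block is the flagged 0 sentinel and such candidates are excluded from
the argmax. The Khachiyan minimum-volume-ellipsoid ascent runs to
tolerance 1e-6 (capped at 2·10⁴ iterations) and then rescales the
tensor so containment of the inputs holds regardless of where the
ascent stopped; coplanar clouds are regularized with a bounding-box-
scaled jitter and flagged.

**Background threshold.** When no resection threshold is given, Otsu's
threshold on the intra-operative intensities within the mesh bounding
box is used. A tetrahedron is flagged as background when at least
`bg_fraction` of its five samples (four displaced vertices plus the
displaced centroid) fall below threshold; samples outside the image
count as background. Connectivity for the maximal-submesh growth is
face-adjacency, which does not leak through pinch vertices.

**Adaptive meshing margin.** Each adaptive iteration meshes the warped
label image dilated by 3 voxels (nearest-label fill). Without the
margin, the composed field's zero-displacement region just outside the
mesh hull progressively erodes the warped mask (≈1% of its voxels per
iteration in phantom runs) and the loop destabilizes; with it, the
tissue always lies strictly inside the hull and increments shrink to
zero once aligned. Re-meshing uses the internal BCC mesher; the
adaptive loop's contract — a fresh valid mesh of the warped labels at
every iteration — is what matters, not the specific mesher.

**Canny thresholds.** The 3-D Canny extractor (Gaussian smoothing at
`sigma` mm, gradient magnitude, non-maximum suppression along the
gradient, 26-connected hysteresis) uses hysteresis thresholds relative
to the maximum gradient magnitude, default 0.2/0.4. Lower settings
admit weak texture edges that have no counterpart across a deformed
image pair, and the untrimmed Hausdorff distance — a max statistic —
then saturates on unmatched points rather than tracking alignment; at
0.2/0.4 the ground-truth field of the phantom evaluates to ≈1 voxel.

## The phantom

The generator emulates the geometry of a brain-shift study: an
ellipsoidal "brain" (semi-axes 0.35 of the field of view, so the brain
surface stays outside the `B+W` matching margin), an embedded
spherical "tumor", correlated Gaussian texture (correlation length
3 mm, amplitude 15) that gives NCC a well-conditioned landscape, a
smooth ground-truth field (Gaussian radial bumps, cosine-tapered to
zero away from the brain, normalized to an exact peak magnitude), an
intra-operative image produced by backward-warping, and an optional
carved zero-intensity resection cavity. The default deformation is a
single 19-mm-radius bump, peak 4 mm — a broad, smooth shift of the
kind seen after dura opening.

What the phantom does **not** emulate: anatomical structure, MR noise
and bias fields, partial-volume effects, tissue-dependent contrast
changes between acquisitions, and discontinuous deformation at the
resection margin. Passing the phantom experiments therefore
demonstrates the correctness of the machinery (matching, assembly,
robust solve, composition, evaluation) under known ground truth, not
clinical accuracy.

## Problem sizes

The test-suite and acceptance experiments run on 64³ phantoms at 1 mm
spacing with ~300-vertex meshes (8 mm cells), a few hundred matches,
and 2 mm cells (~70k elements) for resection detection — sizes chosen
so each experiment completes in seconds on a single core while keeping
every length scale (block, window, cell, cavity) in the same ratio a
full-resolution study would use.

## Known limitations

- **Quantization floor.** Integer-voxel matching carries a
  deterministic rounding error `round(u) − u` (mean ≈ 0.57 mm at 1 mm
  voxels) whose spatial correlation length (voxel size divided by the
  field gradient, ≈7 mm for the default phantom) matches the mesh cell,
  so the FEM fit cannot average it away. Mean nodal recovery error
  plateaus at ≈0.8 mm under these conditions regardless of match
  density or regularization; sub-voxel accuracy requires sub-voxel
  matching, which this implementation intentionally omits.
- **Outlier absorption.** The stress-relaxation makes the solution fit
  the data progressively, so an outlier in a sparsely-matched region
  can see its error rank decay across the rejection iterations and
  escape a tight rejection budget; one escaped 10 mm outlier measurably
  inflates the nodal error. Increasing `f_R` or `n_R` mitigates this.
- **Dense-field support.** Voxels outside the mesh hull receive zero
  displacement; the mesh is expected to cover the region of interest
  (the adaptive loop's dilation margin exists for this reason).
- **Evaluation instrument.** The Canny/Hausdorff score is a relative
  comparison between runs; it saturates when edge sets lose
  correspondence and must not be read as a clinical error measure.
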