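# Methods

`aawall` estimates abdominal-aortic-aneurysm (AAA) wall stress from the
segmented outer-wall geometry alone, and provides the surrounding
toolchain: segmentation (a desk-scale dilated patch U-Net), NURBS-based
contour refinement, contour-stack lofting, segmentation metrics and a
reproducible end-to-end pipeline. This note records the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Membrane equilibrium wall-stress estimation

### Model

A pressurized thin-walled vessel imaged in its deformed configuration is
statically determinate: the in-plane Cauchy stress follows from
equilibrium and the applied load, with no constitutive model. On a
surface parameterized by coordinates ξ¹, ξ² with covariant basis
g_α = ∂x/∂ξ^α, metric determinant g and outward unit normal n, membrane
equilibrium reads

    (1/√g) ∂_β ( √g · h · σ^{αβ} g_α ) + p n = 0,

with uniform thickness h, intraluminal pressure p applied outwards along
n, and σ^{αβ} the in-plane Cauchy components in the local contravariant
basis. Bending and transmural gradients are neglected (membrane
assumption); the mesh is treated as the deformed mid-surface geometry.

Reference load state: h = 1.5 mm and p = 93.3 mmHg (mean arterial
pressure), proximal and distal end rings fixed. Geometry is in mm,
pressure input in mmHg (1 mmHg = 133.322 Pa = 1.33322·10⁻² N/cm²), all
reported stresses in N/cm².

### Discretization

Stress unknowns live at the vertices — three components per vertex —
and are interpolated linearly over each flat triangle. Nodal
contravariant components shared between elements would be ill-defined
(each element carries its own covariant basis), so the nodal unknowns
are expressed in a vertex-local orthonormal tangent frame and promoted
to Cartesian 3×3 tensors before interpolation; per element this is
exactly σ^{αβ} g_α ⊗ g_β in that element's basis. Galerkin testing with
the hat function of each free vertex in each Cartesian direction gives,
per element with area A and face normal n,

    Σ_e h A_e  T̄_e ∇N_i  =  Σ_e (p A_e / 3) n_e ,

where T̄_e is the mean of the three corner tensors and ∇N_i the (constant)
surface gradient of the hat function. Equations at the fixed rings are
removed: their reaction tractions are unknowns we do not solve for.
Element-centroid stress is the mean of the corner tensors; principal
stresses come from eigendecomposition of the 2×2 physical tensor in an
element orthonormal frame, and contravariant components are recovered
through the dual basis.

For a fixed deformed geometry the system is linear in the stress
unknowns. It is solved inside a Newton loop (kept for any future
geometrically nonlinear extension); the first step reaches the optimum
and subsequent iterations act as iterative refinement on the factorized
normal matrix, stopping when the projected gradient stagnates at machine
level. Non-convergence above a 10⁻⁸ relative gradient raises an error
carrying the final residual.

### Regularization — selecting the smooth equilibrium solution

Removing the boundary equations leaves the discrete system
underdetermined: it admits self-equilibrated stress fields (on a
cylinder, e.g., any axial stress constant along the axis), and the
equal-order nodal interpolation additionally supports oscillatory
near-null "checkerboard" modes. A plain minimum-norm solution is
contaminated by these modes (on a jagged-boundary icosphere band the
principal-stress error reaches ~10% with strong spurious anisotropy).

The solver therefore minimizes

    |A s − b|²  +  λ |R s|²  +  ε |s|²_F

where R compares, for every mesh edge (u, v), the two nodal stress
tensors after parallel transport: T_u is rotated by the minimal rotation
taking the vertex normal n_u onto n_v, and the Frobenius norm of the
difference is penalized. Fields that are covariantly constant — the
isotropic tension c(I − n nᵀ) of a pressurized sphere, the hoop tension
of a cylinder — have near-zero penalty, so the regularization selects
among equilibrium solutions while leaving Laplace-type fields unbiased;
a naive penalty on raw Cartesian component differences would bias
exactly those fields. λ is set to 1 on the natural scale
(diag-mean of AᵀA over diag-mean of RᵀR); results on the analytic
benchmarks are insensitive to λ over two orders of magnitude on
structured meshes, and the cylinder benchmark (which has a clean
boundary) is unaffected by it. The tiny Tikhonov term
(ε = 10⁻¹⁰ relative) uses the Frobenius norm of the nodal tensors —
shear counted twice — because a plain dof norm is not frame-invariant
and would make the solution depend on the arbitrary orientation of the
vertex tangent frames.

Verified behaviour (all recomputed by the test suite and
`scripts/acceptance.py`): sphere band R = 25 mm recovers σ₁ ≈ σ₂ ≈ pR/2h
within 1.3% max in the interior (≥3 vertex rings from the fixed
boundary, ~12k faces); cylinder R = 10 mm recovers hoop pR/h within 0.2%
at mid-length; interior error decreases monotonically over three
refinement levels; solutions are exactly linear in p and 1/h and
rigid-motion invariant to ~10⁻¹²; near the fixed rings stresses are
reported but flagged (`near_boundary`).

### Biomechanical summary parameters

From the element field of first principal stress σ₁: peak wall stress
(element maximum), 99th and 75th percentiles, mean, and SAWS (spatially
averaged wall stress), the area-weighted mean Σ σ₁ A / Σ A. Percentiles
and mean are unweighted over elements by default — only SAWS is defined
as area-weighted — but an area-weighted mode is available
(`area_weighted_percentiles=True`).

## Geometry: contours, lofting, diameters

Pixel (r, c) centres map to x = (c+0.5)·dx, y = (r+0.5)·dy; this
half-pixel-centre convention survives round trips without drift.
Contours are extracted per connected component as the 0.5 iso-level of
the Gaussian-smoothed (σ = 1 px) binary indicator: marching squares on
raw binary data yields a staircase whose perimeter overestimates a
smooth boundary by ~5–6%, while the smoothed level set localizes the
boundary to sub-pixel accuracy (disk-perimeter error < 1%, hydraulic
diameter of a voxelized vessel within half a pixel of truth).
Rasterization marks a pixel foreground when its centre lies inside the
polygon.

Lofting resamples every contour to a common circumferential count by arc
length, with the start point fixed at the vertex farthest in +x from the
centroid; each subsequent ring is additionally rotated to minimize
summed inter-ring chord length, preventing strip twist on tortuous
centerlines. Adjacent rings are joined by 2·n_circ triangles (quads
split along the shorter diagonal, which conditions the stress solve
better). The result is verified to be an open tube: manifold, exactly
two boundary loops, Euler characteristic 0, no degenerate faces, and
outward orientation (positive signed volume after capping the rings;
flipped automatically if needed).

Maximum AAA diameter uses the hydraulic diameter D_h = 4A/P per
cross-section (exact diameter for a circle, side length for a square).
Both entry points exist: D_h on raw mask contours and on
lofted-mesh cross-sections.

## NURBS refinement

Curves follow the standard rational B-spline form with Cox–de Boor basis
functions on clamped knot vectors. Closed contours are fitted by
least squares with chord-length parameterization, unit weights, and the
seam point repeated and pinned as both end control points — seam
repetition rather than a fully periodic knot vector, because its seam
behaviour is directly testable and the refinement workflow only needs C⁰
closure. Defaults: degree 3, n_ctrl = max(8, n_points/10). Edits
(move a control point, change its weight) are pure and batch-applied;
by local support the curve changes only on the p+1 affected knot spans,
so a reviewer can correct an artifact-corrupted boundary segment without
touching the rest — and reverting to the automatic result is simply not
applying the edit. In the pipeline, refinement touches only slices named
in the edits file; an empty edit set is bit-identical to refinement
disabled. The interactive GUI workflow is replaced by this file-based
edit protocol.

## Dilated patch U-Net

Encoder–decoder with skip connections; encoder levels follow the
dilation schedule 1, 2, 3, 1 (k = 3), so a single kernel's receptive
field (k−1)·d+1 grows without extra parameters. Defaults: 4 levels,
base 16 channels doubling per level, 64-px patches, batch 8, Adam 10⁻³,
Dice+BCE loss weighted 1:1 (soft-Dice smoothing ε = 1), augmentation by
flips, ±15° rotation, 0.9–1.1 zoom and intensity scaling (geometry
shared between image and mask; intensity applied to the image only).
These sizes are the smallest that pass the synthetic learnability
experiment quickly on one CPU; layer widths and optimizer settings are
package defaults, not literature-fixed values. Layers are implemented
directly in numpy (im2col convolutions with explicit backward passes),
which keeps the dilation arithmetic transparent and the dependency
footprint minimal. Training early-stops once held-out Dice reaches
0.98; with fixed seeds runs are reproducible bit-for-bit on one machine.

Patch processing extracts a row-major grid (stride ≤ patch size,
zero-padded edges) and stitches predictions back by averaging overlaps;
the round trip is exact at stride = patch size and exact on constants at
any stride.

## Synthetic phantoms — what they do and do not show

The fusiform phantom is a tube whose radius follows a Gaussian bulge,
r(z) = R0 + ΔR·exp(−(z−z0)²/2s²), optionally with a laterally offset
centerline; defaults R0 = 10 mm, ΔR = 15 mm (a 5 cm maximum-diameter
aneurysm), L = 100 mm, 1 mm pixels, 2 mm slices, noise σ = 0.05 on a
[0, 1] intensity scale — a surveillance-sized AAA at CTA-like sampling.
Cross-sections are circular by design so every geometric quantity has a
closed form. Metal artifacts are modeled as blurred bright line
segments crossing the wall, enough to break naive thresholding. The
training set mixes boundary-centred and off-wall patches roughly 50/50.

Passing these tests demonstrates architectural and numerical
correctness — equilibrium solved to the Laplace law, exact metric and
NURBS identities, learnability of a clean vessel-vs-background
boundary. It does not demonstrate clinical segmentation performance:
real CTA exams have lobulated non-circular walls, thrombus and
calcification, neighbouring organs at similar intensity, and scanner
noise that is not additive Gaussian. Clinical-scale training and
clinical accuracy claims are out of scope.

## Metrics

Accuracy, sensitivity, precision, specificity, DSC, IoU and MCC come
from voxel confusion counts, pooled over the volume by default (a
per-slice-averaged mode is selectable, since published values are
sometimes reported either way). Undefined ratios (zero denominators)
are NaN with a warning, never silently 0. HD95 uses boundary voxels
(foreground with a background face-neighbour), centre-to-centre
distances under anisotropic spacing, and the linearly interpolated 95th
percentile of the pooled directed-distance multiset from both
directions — symmetric by construction and bounded by the exact maximum
Hausdorff distance.

## Problem sizes and determinism

Validation problem sizes: sphere band at icosphere subdivisions 3–5
(up to ~12k faces), cylinder 64×50 rings, phantom pipeline ~6.4k faces,
U-Net experiment 240 training / 60 held-out patches. All generators and
training are deterministic under fixed seeds; the pipeline writes a
provenance manifest (config digest, versions, seed, per-stage timings)
with every run.

## Known limitations

- Membrane-only stress: no bending, no transmural variation, no
  intraluminal thrombus; load acts directly on the outer-wall mesh.
- Stress near the fixed end rings is influenced by the unknown reactions
  and should be read with the `near_boundary` flag.
- Single conduit per slice (largest component); bifurcations, holes and
  nested contours are out of scope.
- The smoothness regularization assumes the true stress field varies
  slowly on the mesh-edge scale; extremely coarse meshes over sharp
  geometric features will smear local concentrations.
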