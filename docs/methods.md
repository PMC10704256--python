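# Methods

## Model

Registration is posed variationally: find the map y from reference
coordinates to template coordinates minimizing an image distance, plus —
for the deformable step — a smoothness penalty. The registered template
is always produced by backward warping, out(x) = T(y(x)) with bilinear
sampling and fill value 0 outside the template (images are converted to
an inverted grayscale convention on loading, so 0 *is* background).
Landmarks in the reference are pushed through y and compared with their
template partners; this direction is used consistently for warping,
evaluation, and the synthetic ground truth.

### Distance: normalized gradient fields

NGF compares gradient directions under the ε-regularized inner product
(see README for the formula). Properties that matter in practice:

- Each per-pixel summand lies in [0, 1]; the distance is bounded by
  N·h²/2 and is 0 exactly when every regularized gradient ratio is 1.
- ε is in the units of the discrete gradients (intensity per μm).
  Below ε, gradients read as noise and contribute ≈ 0 response. The
  response is *not* monotone in ε pixel-by-pixel on noise (the ε² term
  in the numerator makes the penalty peak near |∇I| ≈ ε), but the edge
  weight |∇I|²/(|∇I|²+ε²) is, and the distance on pure noise vanishes
  for large ε.
- Because ‖·‖_ε never vanishes, NGF also weakly prefers gradient
  *magnitudes* to match. On multimodal pairs whose structures have
  genuinely different per-object contrast this produces a small,
  data-inherent bias of the optimum away from the geometric truth
  (measured ≈ 0.1–0.25 px on the synthetic fixtures); it is a property
  of the distance, not of the optimizer.

### Discretization and derivatives

Images are 2-D grids with uniform spacing h and tracked origin; the
physical position of pixel (i, j) is origin + (j·h, i·h). Gradients use
central differences in the interior and one-sided differences at the
boundary, scaled by 1/h. The template is warped first; the gradient of
the warped values is taken on the reference grid with the same stencil.
All analytic derivatives follow that exact computational path — through
the linear stencil (adjoint scatter) and the spatial derivative of the
bilinear interpolant at the mapped points — so they agree with central
finite differences of the implemented objective to rounding error
(verified to <1e-4 relative for rigid/affine/deformable parameters,
<1e-6 for the regularizer).

### Regularizer

CURV penalizes the five-point Laplacian of each displacement component
under Neumann boundary conditions realized by mirrored ghost nodes.
Two discretizations are exposed:

- `curvature_energy(grid)`: on the control grid itself, h = node
  spacing. This is the standalone, grid-intrinsic form (null space:
  constant displacements exactly; affine displacements up to the
  boundary mirroring).
- `curvature_energy_sampled(grid, image)`: u interpolated to the pixel
  centers of a given image, h = pixel spacing. The deformable objective
  uses this form: it shares grid and units with the data term, so
  α weighs like against like, and it also feels the bilinear kinks
  between control cells. With the grid-intrinsic form, α = 0.1 is
  numerically negligible next to a per-pixel data term and folds appear
  inside tissue; with the pixel-sampled form the default α keeps the
  restained solutions fold-free.

The dominant-α limit suppresses what curvature can see: the solution's
curvature energy collapses by orders of magnitude, while the grid may
still move within the penalty's (near-)null space of affine and very
smooth fields. A regularizer of this family cannot pin the map to its
initialization, only its shape.

### Optimization

- Rigid and affine steps: Gauss–Newton with the per-pixel alignment
  ratios q_i as residuals, model Hessian h²JᵀJ (plus a ~1e-10·trace
  Tikhonov term), and Armijo backtracking (factor 0.5, slope 1e-4).
- Deformable step: L-BFGS (scipy, memory 10) over the node
  displacements with the analytic gradient. A line-search breakdown is
  recorded as a warning diagnostic and the best iterate kept.
- Stopping, per level: 100 (affine) / 200 (deformable) iterations, or
  gradient max-norm below 1e-6 of its initial value, or relative
  objective decrease below 1e-6.
- Multilevel scheme: pyramids are built by 2×2 block averaging
  (spacing doubles; origin shifts by h/2 per level so physical
  coordinates stay consistent; a trailing odd row/column is averaged
  over the pixels present and its half-pixel center offset is accepted
  on the uniform grid). Levels are chosen by log-scale proximity to the
  configured spacing; each level's solution initializes the next. The
  control grid is capped so nodes are never finer than 2 pixels at the
  current level and is prolonged by bilinear resampling.
- The pipeline contains no randomness: reruns are bit-identical.

### Prealignment details

The rotation center is the reference image's center of mass (the method
matches centers of mass but no rotation center is canonical; this choice
makes the rotation and translation parameters nearly decoupled). Every
candidate angle 2πk/N_rot seeds a full multilevel rigid optimization;
the winner is the candidate with the smallest final distance at the
prealignment resolution, and by construction never scores worse than the
raw center-of-mass alignment. The angle schedule places N_rot distinct
angles strictly inside [0, 2π) — a schedule with a duplicated endpoint
would waste one of the local solves.

### Fold detection

A deformation is anatomically implausible where its Jacobian determinant
is negative. The detector rasterizes the grid's domain at a sampling
step (default half the node spacing) and takes central differences of
the interpolated map at the raster cell centers. The raster is finer
than the node cells on purpose: a single node pushed past its neighbor
reverses orientation only in a narrow band along the node lines, which
the node-cell centers themselves never sample.

## Synthetic fixtures

`synthfix` emulates the two acquisition regimes:

- **Sections** are sums of Gaussian "nucleus" blobs (default 60 blobs,
  mean radius 6 px) placed by seeded dart-throwing with a minimum
  center distance — nuclei are disjoint objects, and disjointness also
  guarantees the two stain renderings are *structurally* identical.
- **Stains**: both renderings share the section's per-object uptake;
  each applies its own global monotone response (γ = 0.8 vs 1.4 on blob
  peak intensity) plus ~15% per-object variability. The response acts on
  the peak intensities, not pointwise on the image: a pointwise γ-map
  would rescale every Gaussian's width by 1/√γ and thereby change the
  geometry, which restaining does not do. Aligned renderings hence have
  a large intensity difference but a small NGF distance — the
  multimodal contract.
- **Consecutive-like pairs** drop a fraction (default 30%) of blobs from
  the second rendering and add unrelated replacements; only shared blobs
  become landmarks.
- **Deformations**: rigid, affine, or a smooth analytic field (sum of 3
  Gaussian bumps per run, amplitude < 0.3·σ so it cannot fold; default
  recovery fixture: amplitude 5 px, σ = 40 px so the field covers the
  landmark region). The template is the second rendering resampled at
  y⁻¹ (analytic inverse, or fixed-point inversion for the smooth field),
  so t_k = y(r_k) holds to machine precision.

Desk-scale study conditions: 256×256 px at 4 μm/px, prealignment at
~32 μm/px (8× downsampled), 17×17 control nodes (~64 μm spacing). The
node spacing is deliberately much coarser than the blobs, matching the
proportion of a 257×257 grid on a centimeter-scale slide; denser desk
grids let the data term chase per-structure contrast differences and
fold.

What passing these fixtures does *not* show about real slides: no
scanner or stitching artifacts, no stain chemistry or color (the
generator works in the inverted gray convention directly), no tissue
tears or large structural remodeling, nuclei are circularly symmetric,
and landmark placement is exact rather than observer-limited (real
annotation noise is ~0.5 μm). Consecutive-like fixtures can fold at the
default α — consistent with fold-freeness being a restained-section
observation — so fold-freeness is only asserted for restained fixtures.

## Numerical choices and degenerate inputs

- Grayscale conversion: ITU-R 601 luma, then inversion (255 − gray);
  already-gray arrays are rejected rather than silently passed through.
- Bilinear sampling outside the pixel-center hull returns 0 with zero
  gradient; deformation grids extrapolate by clamping to the boundary
  cell's bilinear extension.
- Intensities stay in [0, 255] floating point; no histogram
  normalization (NGF is contrast-invariant by construction).
- All-zero images make the center of mass undefined and are rejected;
  images below 2×2, non-positive spacings, non-finite intensities,
  empty landmark sets, and fold-prone smooth-field amplitudes are
  rejected at construction.
- Serialization: transforms round-trip through tagged JSON exactly
  (bit-identical reruns produce bit-identical files).

## Known limitations

- The supported working range is images that fit in memory at the
  registration resolution (≥ ~1 μm/px levels); there is no tile
  streaming for full-resolution 25k×55k scans.
- NGF's ε-coupled magnitude preference biases optima slightly on pairs
  with strong per-structure contrast differences (see above); on
  consecutive-like data with missing structures the deformable step can
  fold at the default α.
- The Gauss–Newton residual linearization uses the alignment ratio q
  directly; other residual factorizations of NGF exist and would change
  step sizes, though not the minimizers.
- No 3-D stack reconstruction, diffeomorphic parameterizations, GPU
  path, or learned registration.
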