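# Methods

This note records the mathematical model, the parameter choices and the
numerical conventions behind `brainsmapi`, plus the scope of the synthetic
data used to validate it.

## Problem setting

Terabyte-scale brain volumes cannot be deformably registered at native
resolution. The strategy implemented here:

1. **Register at a coarse, feature-driven level.** Both brains are reduced
   to regional-feature label volumes (segmented outlines and internal
   regions) at a working resolution of tens of micrometres. Labels are
   encoded as feature channels and registered by an affine stage followed
   by a symmetric diffeomorphic stage. Intensity artefacts (staining
   variation, streaks, tears) never enter the similarity metric because
   only the region geometry is matched.
2. **Amplify the transform to native resolution analytically.** The
   low-resolution affine `M` and displacement field `φ` define a
   high-resolution map without ever materialising a high-resolution field.
3. **Apply block-wise.** The output volume is partitioned into blocks; for
   each block the six surfaces of its bounding box are mapped through the
   transform to find the source region of interest (ROI), only that ROI is
   read, and the block is resampled independently. Memory stays bounded by
   the block + ROI size regardless of volume size.

## Coordinate conventions

- Arrays are indexed `(x, y, z)`; 2D TIFF slices on disk are `(y, x)` and
  transposed at the I/O boundary.
- Affines use row-vector convention: a point maps as `[x y z 1] @ M`, the
  last column is `(0,0,0,1)ᵀ`, translation sits in the last row. 2D uses
  the analogous 3×3 form.
- Physical coordinate = index × voxel size (µm). Displacement fields are
  stored in voxel units of their own lattice.
- Image resampling is a *pull-back*: `out(q) = v(map(q))`, so the map
  points from output (fixed) space into source (moving) space. Point sets
  push *forward* through the inverse map (`point_transform`).

## High-resolution mapping

With amplification `s` (scalar or per-axis) between the working lattice and
the native lattice:

- `scale_affine` rescales `M` to `M′ = S⁻¹ M S` with `S = diag(s, 1)`, so
  that `[s·p] @ M′ = s·([p] @ M)` exactly. The commutation error is zero in
  floating point up to ~1e-6 over typical coordinate ranges (tested).
- `interp_field` evaluates `φ` at fractional low-resolution positions by
  hand-written trilinear interpolation (the 8-corner expansion is the
  tested reference), with clamping at the lattice border.
- `map_point` composes them: `P″ = [P] @ M′ + s·φ(P/s)`. The field is
  evaluated at the pre-affine position and added after the affine, matching
  how the registration's output field is folded with the affine.

## Block-wise warping

For each output block the ROI is found by mapping a point lattice on the
six faces of the block's bounding box (stride 2 on sides longer than 64)
and taking the axis-aligned hull plus a safety margin. The default margin
is `ceil(2·max(s))`, covering interpolation support and the curvature of
the map between face samples; any voxel whose source falls outside its ROI
is *counted* (`containment_violations`), never silently clamped. Blocks
outside an optional brain mask are skipped. Blocks are processed by a
thread pool; workers write disjoint output blocks and share no mutable
state, so the result is identical for any worker count.

Equivalence with a dense oracle (`transform_volume_dense`, same samplers
applied to the whole volume in memory) is bit-exact for nearest-neighbour
and within 1e-5 of the value range for trilinear; both paths share the
hand-written samplers, and ROI offsets are exact integers so the
subtraction introduces no rounding.

Numerical choices worth recording:

- Nearest-neighbour uses `floor(c + 0.5)` (half-up). Unlike banker's
  rounding (`rint`), half-up commutes with integer offsets, which is what
  makes block-wise nearest bit-identical to the dense path.
- Trilinear sampling is a manual 8-corner gather in float64 with `constant`
  (fill) and `clamp` edge modes; it is exact at grid nodes.

## Registration

- **Features.** Regions are encoded one-hot with optional Gaussian
  smoothing (σ = 1.5 working voxels) or as signed distance maps capped at
  ±10 voxels. Channel order follows the user's region list.
- **Affine.** Coarse-to-fine (levels 4×, 2×, 1×) minimisation of
  channel-wise SSD with analytic gradients (L-BFGS-B), or Powell on mutual
  information for cross-modality features.
- **Diffeomorphic.** Log-domain symmetric demons: a stationary velocity
  field `v` is updated from two-sided forces, smoothed (update σ = 2.0,
  field σ = 0.5), with step halving on energy increase; the exponentials
  `φ₂ = exp(v)` (pull-back) and `φ₁ = exp(−v)` (forward) are computed by
  scaling-and-squaring, guaranteeing invertibility. `φ₂` is folded with the
  affine so its output feeds `map_point` directly. Defaults: levels
  (4, 2, 1), iterations (100, 80, 50), step 2.0, patience 8.
- Inverse consistency `‖φ₁ ∘ (φ₂ A⁻¹)‖` is monitored; on the synthetic
  recovery harness the median is ≪ 0.5 voxel.

## Evaluation

- **Region level.** Per-region 2D Dice over up to 50 evenly spaced slices
  through the region's span in the reference volume.
- **Nucleus level.** STAPLE fuses rater masks by EM in the log domain
  (init `p = q = 0.99`, scalar prior = mean foreground fraction, threshold
  0.5 with ties → foreground); per-rater Dice vs the consensus gives human
  performance, atlas-vs-consensus gives registration performance, compared
  with a Mann-Whitney U test. For pooled sizes ≤ 12 the p-value is
  exhaustive and tie-aware (two-sided = 2·min(tails), capped at 1); larger
  samples use the normal approximation with tie and 0.5 continuity
  corrections.
- **Landmarks.** Euclidean distances and their median.

## Synthetic data and its scope

Desk-scale stand-ins are generated, never shipped:

- A 400² cartoon face with four disjoint region masks and a chain of
  degradations: (1) a smooth "crying" deformation, (2) region-wise texture
  resampling from surrogate histograms, (3) multiplicative sinusoidal
  streaks `v·(A−1+sin(πc/w))/A`, (4) a zeroed tear triangle. Each stage
  preserves the previous stage's region masks, so one registration of the
  stage-1 geometry serves all four models.
- 3D "brains": an ellipsoidal outline with nested blob regions plus
  textured gray values (minimum side 32).
- Random smooth displacement fields: Gaussian-smoothed white noise scaled
  to a prescribed maximum norm, with *wrap-mode* smoothing. Edge-replicating
  modes inflate boundary variance ~10× and the max-normalisation then
  crushes the interior field toward zero; wrap keeps the statistics
  stationary. Fields are rejected (and reseeded) unless the Jacobian
  determinant stays positive, so the "truth" warps are invertible.

These generators are deliberately simple: they exercise the geometry,
bookkeeping and statistics of the pipeline at desk scale (seconds to a
minute per registration at 64³ or 400²), not the biological realism of the
underlying problem.

## Limitations

- The registration is driven entirely by region geometry; with few or
  poorly segmented regions the interior deformation is interpolated, not
  measured.
- The demons optimiser is first-order and can stall in coarse levels for
  very large rotations; initialise with the affine stage.
- Trilinear block equivalence is tolerance-based (≤ 1e-5 of range), not
  bit-exact, because summation order differs between the dense and blocked
  paths.
- SWC radii are scaled by the affine's isotropic factor only; the field's
  local Jacobian is ignored.
- Practical desk-scale sizes: registration up to ~128³ label volumes in
  minutes; block-wise warping tested to 160³ against the dense oracle
  (the algorithm itself is bounded by block size, not volume size).
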