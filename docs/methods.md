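# Methods

This note documents the models, numerical choices, and limitations behind
`plantrecon`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, and what the synthetic fixtures do and do not show about
real data.

## Registration

**Initialization.** A similarity transform (scale `s`, rotation `R`,
translation `t`) is estimated from ≥3 picked correspondence pairs by the
closed-form least-squares (Umeyama) solution. The solution is exact for
noise-free pairs. Collinear or coincident configurations are rejected
(rank test on the centered source matrix, tolerance `1e-10` relative to the
coordinate magnitude); planar configurations are fine because the
reflection-correcting SVD sign fix already selects the proper rotation.
Four pairs — the convention for manual picking — is the default workflow but
not a requirement.

**ICP refinement.** Rigid point-to-point ICP on voxel-downsampled clouds
(one centroid per occupied voxel, ordered by first occurrence, so the whole
procedure is deterministic). Scale is estimated only during initialization
and frozen through ICP: the refinement citations in this literature are all
rigid methods, and letting scale float during nearest-neighbor iteration is
a well-known collapse mode. Two schedules:

- `three_stage`: (voxel, threshold) → (voxel/2, threshold) → (voxel,
  threshold·0.5). The final-stage threshold factor 0.5 is our choice; the
  protocol this mirrors describes "adjusting the threshold" without a
  number.
- `single` (default): one stage of `base_iterations × iteration_multiplier`
  iterations (30 × 10 by default). On thin, self-similar plant geometry the
  stage hand-offs of the multiscale schedule can latch onto wrong
  correspondences; spending the same budget inside one stage avoids that.

Point-to-point residuals are used throughout (point-to-plane would need
normals the pipeline never computes). Convergence: stop when the relative
change of both fitness and inlier RMSE falls below `1e-7`. Correspondences
beyond `distance_threshold` are ignored; if none exist at the initial pose
the refinement aborts and surfaces the initial transform.

A practical caveat: when the voxel size is large enough to merge neighboring
points, the source and target downsamplings merge *different* subsets (the
grids are axis-aligned in each cloud's own frame), so the two centroid sets
are not congruent and ICP converges to a small but nonzero floor (~voxel/20
in our measurements). For transform-recovery work use a voxel below the
cloud's point spacing; the tests use 0.5 mm against ~7–14 mm spacing.

## Geometry metrics

Precision / recall / F-score at threshold `d` use strict inequality
(`nn_distance < d`), matching the definitions literally. Nearest-neighbor
distances come from a k-d tree, but the distance to the returned neighbor is
recomputed with the same elementwise arithmetic an exhaustive scan uses, so
results are *bit-identical* to the O(N·M) brute force — the tests assert
exact equality, not approximate.

PR curves compute the two nn-distance lists once and re-threshold them per
step; this is algebraically identical to per-threshold recomputation.

**Labels.** Per tested point: *correct* if `nn < d`; *outlier* if
`nn > 3σ`, where σ is the population (ddof=0) standard deviation of the
tested cloud's own nn-distance list; *missing* otherwise. σ is computed per
evaluation direction (the precision pass labels the reconstruction, the
recall pass labels the ground truth), not pooled — the source protocol says
only "3 standard deviations", so this is a documented interpretation, and σ
is surfaced in the result for auditability. Edge rule: when `3σ ≤ d` the
missing band is empty and every point at or beyond `d` is an outlier.

**Scale calibration.** `rescale_by_reference` multiplies all coordinates by
`true_length / measured_length` about the origin — the workflow where an
object of known size (e.g. a printed sphere) is placed in the scene to
recover absolute scale when no reference scan exists. `measure_extent`
(max − min along one axis) then yields plant height.

## Image metrics

- MSE over all pixels and channels; PSNR = `10·log10(MAX²/MSE)` with a +∞
  sentinel (serialized as null) for identical images, which averages exclude
  with a reported count.
- SSIM defaults to the *global* form — one application of the formula over
  the whole image with `C1=(0.01·MAX)²`, `C2=(0.03·MAX)²` — because that is
  how the defining equation is written; a windowed mode (11×11 uniform
  window, reflect padding, mean over the map) is available. Color images are
  converted by channel mean for SSIM only.
- LPIPS follows the layer-feature distance exactly: per layer, features are
  unit-normalized along channels at each spatial location (ε=1e-10 guards
  zero vectors), differenced, weighted channel-wise by `w_l` (default
  `1/C_l`, the cosine-distance setting), squared-ℓ2-summed over channels,
  averaged over `H_l×W_l`, summed over layers. The backbone is a pluggable
  contract. The default `ConvBankBackbone` is a fixed-seed bank of random
  3×3 convolutions with ReLU and 2× average pooling — deterministic, no
  trained weights. It satisfies every structural property of the distance
  (identity, symmetry, normalization invariance) and is what the tests use;
  its *magnitudes* are not comparable to any published pretrained-network
  LPIPS figure, and no claim of perceptual alignment is made.

## Early stopping

The monitor consumes an (iteration, average-LPIPS) series, linearly
interpolates it onto a uniform grid of `granularity` points spanning
`[first checkpoint, total_iterations]` (holding the last value constant past
the final checkpoint so no slope is fabricated), and scans for the first
index `i` such that all `C` successive absolute differences in
`[i, i+C−1]` stay below `θ`. The recommended stop is the grid iteration at
`i + C` — the first moment an online monitor could have *confirmed* the
plateau. Defaults: θ=0.005, C=6, granularity 1,000, total 60,000.

The plateau criterion is formalized as *C consecutive absolute successive
differences below θ*; whether the change test should be signed or
window-anchored differently is not pinned down by the prose this follows,
so the interpretation is explicit and configurable.

One consequence worth understanding: on a smooth decay with LPIPS-scale
amplitude (≈0.5) sampled on a ~60-iteration grid, the *average* per-step
change is ≈0.0016 — already below θ=0.005 — so confirmation can occur long
before the curve's nominal flattening point. The detector is faithful to
its definition (the tests verify it against an exhaustive window scan);
where confirmation lands is a property of θ relative to the curve's slope
per grid step, not of the algorithm. Practitioners wanting later stops
should shrink θ or coarsen the grid.

Pearson correlations (e.g. LPIPS vs F1 across runs) use the sample
(ddof=1) formula; zero-variance columns raise rather than returning NaN.

## Synthetic fixtures

The generators emulate the benchmark's data sources at desk scale:

- **Plant cloud**: a vertical cylinder (stem, default 1.2 m × 1 cm radius)
  with parabolic ribbon leaves at evenly spaced nodes, sampled uniformly by
  area at 2·10⁴ points/m² (~7 mm spacing — the TLS-like resolution).
  Poisson point counts; everything is a pure function of the seed.
- **Degraded copy**: optional similarity transform, then Gaussian jitter,
  uniform dropout, and uniform outliers in an inflated bounding box —
  the failure modes of radiance-field exports (surface noise, missing
  coverage, floaters, unknown frame).
- **Training curve**: exponential decay that closes 99 % of the
  start-to-floor gap at the requested plateau iteration, plus seeded noise.
- **Image pairs**: a deterministic sinusoid-plus-noise texture and a
  degraded copy (noise / blur / intensity shift).

What passing tests show: the metrics, registration, and detector are
mathematically correct and statistically calibrated (dropout *f* recovers
recall ≈ 100·(1−f) within binomial error; jitter σ with d=4σ gives
precision ≈ 99.9 % by the χ₃ tail). What they do not show: performance on
real TLS/NeRF data, with its anisotropic noise, view-dependent dropout,
non-rigid plant motion, and registration ambiguity from repeated foliage
structure. The defaults here are study conditions, not claims about any
particular sensor.

### Problem sizes

Tests and the acceptance script run plants of ~1,000–3,600 points, image
grids of 16–64 px, and 1,000-point interpolation grids — sizes at which the
brute-force oracles (O(N²) distance matrices, exhaustive window scans) are
exact and cheap. All operations scale to the ~10⁶-point clouds real exports
produce; only the oracles do not.

## Known limitations

- No LAS/LAZ/E57 input, no mesh metrics, no normals → no point-to-plane ICP.
- Global registration is out of scope: a coarse initial alignment
  (correspondences or an already-near-identity pose) is assumed.
- The statistical-outlier-removal cutoff (`mean + ratio·std` of mean-kNN
  distance, k=20, ratio=2 by default) and the duplicate-removal ε (1 µm)
  are sensible engineering defaults, not fitted to any instrument.
- The PLY writer emits float32 coordinates (the common dialect), bounding
  round-trip precision at ~1e-7 relative; in-memory math is float64.
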