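# Methods

## Registration model

A session-to-session FOV change is modeled as a planar affine map
`(x, y) → (ax + by + e, cx + dy + f)` acting on (x=column, y=row)
coordinates with the origin at the top-left pixel center. The linear part,
when its determinant is positive, is decomposed as
`A = λ R(ψ) diag(t, 1) R(ϕ)` with zoom λ > 0, spin ψ, tilt t ≥ 1 and
longitude ϕ; the latitude is θ = arccos(1/t). The decomposition is computed
by SVD: t is the ratio of the singular values, λ the smaller one, and the
two orthogonal factors are forced to proper rotations. ϕ is normalized into
[0, π) using the symmetry (ψ, ϕ) → (ψ+π, ϕ+π); ψ therefore lives in
[0, 2π) (a pure rotation by 3π/2 has no representation with ψ ≤ π). When the
two singular values coincide (t = 1) ϕ is undefined and is set to 0.
Recomposition reproduces random positive-determinant matrices to < 1e−8.

## View simulation

The grid varies only (t, ϕ): tilts `t_k = √2^k` for k = 0..`max_tilt_index`
(default 5, max tilt 4√2, θ ≈ 79.8°), longitudes `m · 72°/t` for
`m·72°/t < 180°`, and the single frontal pose (1, 0). Spin and zoom are not
simulated; the descriptor backends are rotation- and scale-invariant, which
covers them. For tilt index 5 the grid holds 43 views.

Each view is produced by rotating the image by ϕ with bounding-box expansion
(bilinear, zeros outside), blurring along the to-be-compressed row axis with
a 1-D Gaussian of σ = 0.8·√(t²−1) — the anti-alias kernel of the optical
model; 0.8 is the established constant for this simulation scheme — and
subsampling that axis by t. The exact pixel maps (including the bounding-box
translation) are stored as an inverse pair (`to_view`, `from_view`), so
keypoints detected on a view are mapped back into the original frame
analytically; keypoints whose backprojection leaves the original frame are
dropped. The frontal pose bypasses warping entirely, so it is bit-identical
to the input.

## Backends, matching, estimation

Three detector/descriptor backends are registered, covering both descriptor
metric families: SIFT (float descriptors, Euclidean), ORB (256-bit binary,
Hamming, capped at 500 keypoints per view) and FAST+BRIEF (binary, Hamming).
The registry is pluggable; additional backends can be registered where their
implementations are available. Pooled keypoints closer than 1 px with
identical descriptors are collapsed to one (overlapping near-frontal views
duplicate keypoints, which would bias RANSAC sampling).

Matching is one-way A→B NNDR: for each A-descriptor the two nearest
B-descriptors are found under the set's metric and the pair is kept iff
d₁/d₂ < 0.75. The implementation is exhaustive (chunked matrix distances),
and is tested for exact agreement with an independent brute-force oracle.

RANSAC draws minimal 3-correspondence samples (vectorized in chunks of 512),
solves each exactly, counts inliers at reprojection error ≤ 3 px (default;
neuron radii are ≈ 4–8 px at 512², so 3 px separates true from spurious
correspondences), and stops early once the standard (1−w³)ⁿ confidence bound
reaches 99.9 % or the iteration budget (default 150 000) is exhausted. The
best model is refit by least squares on its inlier set. All sampling flows
from a seeded Generator, so results are reproducible; ties on inlier count
break toward the smaller residual sum, then the earlier sample.

## Repeated estimation and L1 selection

`align_fov` computes features once per pair, matches once (NNDR is
deterministic — re-running it repeatedly would reproduce the same matches,
so the repetition is honored by re-seeding only the stochastic estimation
stage), then runs RANSAC `n_repeats` times with seeds `seed+i`. Each
candidate transform warps the raw moving ROI mask (nearest-neighbor, so
values stay binary) and is scored by the whole-frame sum of absolute
differences against the raw template mask; for 0/255 masks this equals
255 × the symmetric-difference count, which is supported exactly where a
neuron appears in one mask but not the other. The arg-min repeat wins; ties
go to the earliest repeat for determinism. Failed repeats score +inf; if all
repeats fail the alignment raises with the feature/match counts in the
diagnostic.

## Metrics

- **Mask correlation**: Pearson r of the flattened masks; invariant to 0/1
  vs 0/255 coding; a constant mask is an error (undefined), never silently 0.
- **Sharpness**: fraction of centered-spectrum bins of the image whose raw
  modulus exceeds M/1000, M being the maximum of the template's centered
  spectrum. Raw modulus, no log or normalization: the rule is scale-free
  because image and template scale together. Closed forms: a constant image
  scores 1/(H·W), an impulse scores 1.
- **ROI filter**: 8-connected components (matching typical segmentation
  exports); components with ≥ 60 px survive, smaller ones (spine-sized) are
  dropped. Label inputs keep their label identities.
- **Common neurons**: greedy nearest-first one-to-one pairing of transformed
  centroids within 5 px (configurable). This is an algorithmic
  operationalization of what is otherwise a manual curation step, and is
  labeled as such.
- **CLAHE**: 8×8 tile grid, per-tile 256-bin histogram clipped at
  `clip_limit ×` mean bin height with uniform redistribution of the excess,
  CDF lookup tables blended bilinearly between tiles. Used as optional
  preprocessing; the affine-simulated pipeline defaults to CLAHE off, since
  descriptor matching does not need it.

## Synthetic scenes

The generator emulates the failure modes the method targets. A scene is a
set of anisotropic Gaussian blobs (axes 2.8–4.5 px, amplitudes 150–250,
centers ≥ 18 px apart with a 24 px margin) plus a smooth scene-anchored
texture field (white noise smoothed with σ = 2 px, amplitude 12 intensity
units) standing in for the structured neuropil/dendrite background of real
mean images. The texture matters: with bare blobs every neuron is a
near-clone of every other, the distance-ratio test rejects almost all true
matches, and robust estimation locks onto spurious consensus — a failure
real FOVs do not exhibit because their background is distinctive.

A session render warps blob centers and covariances analytically (no
resampling error in the ground truth), restricts to an active neuron subset,
multiplies in 2–4 low-frequency cosine gradients (total amplitude up to
±40 %), then applies Gaussian blur, additive Gaussian noise and 8-bit
quantization. The ROI mask is the amplitude/5 support of each blob
(guaranteeing ≥ 60 px per ROI at the chosen axes), rendered noiselessly and
passed through the standard size filter; per-ROI neuron identities are
recorded so shared-neuron masks can be built exactly. Poisson shot noise is
not modeled.

The benchmark suite renders 10 "easy" pairs (tilt 5–15°, 80 % shared
neurons, no blur, mild background) and 10 "stress" pairs (tilt 35–45°, 30 %
shared, blur σ = 2–3, ±40 % background, noise σ = 6) at 256×256 with 25
neurons. Benchmark poses conjugate the tilt axis (ψ = spin − ϕ) so the net
in-plane rotation equals the sampled spin, as for a physical tilt about an
axis at longitude ϕ. The template session always uses the identity pose, so
the ground-truth moving→template transform is the inverse of the moving
pose. Alignment quality is scored on the shared-neuron masks (Pearson r
after warping) and by the mean frame-corner displacement between recovered
and true transforms.

## Problem sizes and numerical choices

The benchmark and acceptance runs use 256×256 frames, pose-grid tilt index 2
(10 views per image — both images are simulated, so relative tilts up to ~4
are covered, ample for ≤ 45° session tilts), 20 RANSAC repeats and a 10 000
iteration budget; these are the package's default study conditions at desk
scale, with the 150 000-iteration default exercised once in the recovery
test. Degenerate cases are explicit errors, not silent results: non-positive
determinants in decomposition, < 3 matches, all-collinear samples, singular
winning transforms, constant masks in correlation, simulated views smaller
than 8 px.

## What passing tests show — and don't

The synthetic benchmark demonstrates the method's discriminating behavior —
affine-simulated matching keeps registering where single-view matching
collapses, and the L1 selection makes randomized estimation reproducible —
under controlled degradations with exact ground truth. It does not certify
performance on real two-photon data, whose background statistics, vascular
landmarks, non-rigid tissue deformation and session-to-session photometric
drift the generator does not model. Within-session motion correction and
neuron segmentation are upstream of this package and are assumed done.
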