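# Methods

## Problem and approach

The caudate nucleus is a small subcortical gray-matter structure whose
automatic delineation in T1 MRI is limited by weak contrast against
surrounding gray matter and by per-subject shape variation that atlas
pipelines cannot fully capture. `caudatecut` treats segmentation as exact
binary energy minimization seeded by an approximate prior mask: the prior
only locates the structure and pins down hard constraints; the image
evidence decides the boundary.

For each slice, a two-terminal graph is built whose min cut globally
minimizes

    E(L) = Σ_p U_p(L_p) + δ Σ_{p,q∈N} B_{p,q} [L_p ≠ L_q]

over labelings L that respect the seeds. All pairwise weights are
non-negative, so the construction is submodular and the optimum is exact.
Volumes are segmented slice-by-slice (the descriptors, Gaussian scale
analysis and neighborhoods are 2-D) and restacked; left and right caudate
are independent runs, with left-hemisphere slices mirrored into a canonical
(right) orientation because the correlogram's angular sectors are
orientation-specific and the two caudates are mirror images.

## Pipeline stages

1. **Preprocessing.** Perona–Malik anisotropic diffusion (exponential
   conductance, 4-neighbor flux form, reflecting borders) followed by
   linear normalization to integer graylevels 0–255. The same
   preprocessing is applied at training and inference.
2. **Seeds.** C = Erode_ke(R0), B = complement of Dilate_kd(R0), Euclidean
   disk structuring elements. If erosion empties C (thin tail slices), the
   radius is reduced stepwise and, as a last resort, the prior's innermost
   pixel (distance-transform argmax) seeds the slice; such slices are
   flagged degenerate.
3. **Unsupervised unary.** P_u(cau | g) is the relative frequency of
   graylevel g among caudate seeds, pooled over all usable slices of the
   volume, optionally Parzen-smoothed; P_u(back | g) = 1 − P_u(cau | g);
   potentials are −ln probabilities clipped to [ε, 1−ε], hence bounded by
   −ln ε.
4. **Supervised unary.** Each pixel is described by the signed differences
   of mean graylevel between all pairs of the n = c·r correlogram bins
   (c concentric rings of width r pixels, each split into r angular
   sectors; reflection padding at image borders). A linear SVM
   (squared-hinge, L2, standardized features) is trained on all
   ground-truth caudate pixels plus an equal number of block-stratified
   background pixels per slice; its margin is calibrated to a probability
   by a logistic (Platt) map fitted on the training margins. The classifier
   applied to a subject is trained on all other subjects (leave-one-out).
5. **Boundary term.** N_{p,q} = exp(−(ΔI)²/2σ²)/dist and
   O_{p,q} = exp(−θ²/2β²)/dist, θ ∈ [0, π/2] the sign-free angle between
   the Hessian minimum-eigenvalue directions of p and q. Derivatives are
   Gaussian-scale-space responses at a per-pixel scale chosen by
   maximizing the local window entropy over a discrete grid (smallest
   qualifying scale on ties or when no interior maximum exists), with the
   optional Lindeberg factor s^ℓ (ℓ = 0 by default). The edgeness map J
   averages binary Canny maps over a grid of hysteresis thresholds
   (expressed as fractions of the per-scale maximum gradient magnitude,
   low = 0.4·high), takes the minimum across smoothing scales, and is
   Gaussian-smoothed; the pair weight is damped by (1 − J̄) so probable
   boundaries are cheap to cut. A literal J-multiplying variant and an
   edgeness-off variant are selectable.
6. **Min cut.** t-links carry the unary costs (K = 1 + δ·max_p Σ_q B_{p,q}
   for seeds — provably larger than any alternative cut through the
   pixel), n-links carry δ·B_{p,q}. Max-flow is delegated to scipy's Dinic
   implementation, which requires int32 capacities: floats are scaled by
   (2³¹−1)/bound, where bound is an a-priori upper bound on the cut value,
   and the reported energy is recomputed in exact float arithmetic from
   the returned labeling. A brute-force enumerator (≤ 20 free pixels,
   ties broken toward fewer caudate pixels then lexicographically) serves
   as an independent oracle in the tests.

## Parameters

| name | meaning | default | phantom preset |
|---|---|---|---|
| ke, kd | seed erosion / dilation radii (px) | 4, 10 | 2, 4 |
| c, r | correlogram rings × sectors (bins n = c·r) | 3, 5 | 3, 3 |
| α | N vs O mixing weight | 0.5 | 0.5 |
| δ | unary/boundary trade-off | 50 | 100 |
| S_p | entropy scale grid | 1…6 step 0.5 | same |
| γ_k | Canny threshold grid | 0.02…0.30 step 0.01 | same |
| s_j | Canny scale grid | 0.5…5 step 0.5 | 0.5…2 step 0.5 |
| ℓ | Lindeberg exponent | 0 | 0 |
| ε | probability floor | 1e-3 | 1e-3 |
| histogram kernel | Parzen sd (graylevels) | 0 (raw) | 4 |
| σ estimator | adaptive intensity scale | RMS of ΔI | robust (1.4826·median abs ΔI) |
| diffusion | iterations / κ / step | 10 / 30 / 0.2 | 10 / 12 / 0.2 |

The clinical defaults assume 256×256 slices; the phantom preset rescales
the spatial extents to the 32×32 phantom geometry (structure radius ≈ 5 px
instead of ≈ 15–20 px). Design choices behind the preset:

* **κ = 12**: Perona–Malik's contrast scale must sit between the noise
  level (sd 8) and the structure's edge contrast (20 graylevels), or the
  diffusion erases the very boundary the cut must find. κ = 30 is
  appropriate for the 0–255 clinical scale, not for the phantom's raw
  units.
* **δ = 100**: the trade-off coefficient requires per-dataset calibration;
  it was cross-validated once on a development phantom cohort (disjoint
  from every seed used in the tests) and frozen.
* **Parzen sd 4** for the seed histogram: a 32×32 slice yields only ~30
  caudate seeds, far too few to populate 256 raw bins — without smoothing,
  most true caudate graylevels would be "unseen" and floored at ε.
* **robust σ**: the RMS of neighbor differences (the default estimator) is
  inflated several-fold by the strong CSF and WM edges on a small slice,
  flattening the N term; the median-based estimator recovers the noise
  scale. Both are available; the default follows the classical RMS rule.

## The phantom generator

Each synthetic subject is a 32×32×8 volume at 2 mm isotropic voxels
holding two bean-shaped "caudates" (a spherical head tapering into an
elongated, slightly curved body across slices — the head/body transition
being the classically fragile region), with per-side volumes drawn from
N(4800, 600²) mm³. The background is a piecewise-smooth two-level GM/WM
texture (GM 100, WM 150, foreground 120: low contrast by design), a dark
CSF band (40) medial to each bean emulating the lateral ventricle — the
contextual neighbor that makes correlogram supervision informative —
multiplied by a low-frequency ±10% bias field, plus additive Gaussian
noise (sd 8). The prior mask emulates atlas output: the truth translated
by a random in-plane offset (≤ 2 px) with 20% boundary-voxel flips,
guaranteed nonempty and overlapping. Cohorts give case subjects a
configurable right-volume deficit and half that deficit on the left
(a deliberately sub-threshold effect). All generation is deterministic:
one RNG stream per subject derived from (master seed, subject index).

What the phantom does **not** emulate: Rician noise statistics, partial
volume fractions beyond boundary discretization, whole-brain anatomy,
through-plane anisotropy of real 2-mm-thick acquisitions, and realistic
atlas failure modes (systematic, spatially correlated errors rather than
i.i.d. boundary flips). Passing tests therefore demonstrate the machinery
— exact optimization, calibrated probabilities, metric correctness,
reproducibility, and refinement of a perturbed prior under low contrast —
not clinical-grade accuracy on real MRI.

## Numerical choices and degenerate inputs

* Constant slices normalize to all-zero; window entropy is zero at every
  scale and selection falls back to the smallest grid scale.
* σ and β are floored at 1 graylevel and π/36 rad so flat slices cannot
  blow up the exponentials.
* Hessian eigenvectors are unit-normalized, canonicalized to the upper
  half-plane; isotropic Hessians (no preferred direction) default to +x.
  Orientation angles are taken mod π.
* Ties in the brute-force oracle break toward fewer caudate pixels, then
  lexicographically; the min-cut solver is deterministic for fixed input.
* Empty priors, empty seed sets, single-class training data and
  oversized brute-force instances raise descriptive errors rather than
  returning silent zeros.
* Masks are uint8 {0,1}; volumes and masks are written as NIfTI-1 with
  spacing from the header (matrix order row, column, slice).

## Known limitations

* Exact recovery of 2-px-thin tail slices is not guaranteed: any
  contour-penalized energy trades thin protrusions against boundary cost,
  and maximum-surface-distance errors concentrate there.
* The linear margin saturates near AUC 0.82 on the phantom descriptor
  distribution (a nonlinear classifier reaches ~0.95 on the same
  features); linearity is kept because it is the model's design.
* The edgeness map's minimum across scales is conservative: a weak edge
  missed at any one scale is discounted everywhere. The per-pixel entropy
  scale selection and the edgeness scale grid partly compensate.
* Segmentation is per-slice 2-D; no 3-D regularization across slices.
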