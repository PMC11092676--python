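# Methods

This note records the models implemented by `phantombench`, the parameters
that matter, the numerical choices made where a published description was
silent, and the limits of what the synthetic data can demonstrate.

## 1. Synthetic slice generator (`phantom`)

### Tissue layout

Real challenge-style training data are 2-D slices of a procedurally
generated 3-D anthropomorphic breast phantom.  `phantombench` does not
reproduce the 3-D phantom; it generates 2-D layouts directly, designed to
reproduce the *statistical* structure the downstream evaluation consumes:
four mutually exclusive tissue labels, a thin peripheral skin band, a
1-px-wide interior ligament network partitioning the interior into
compartments, and a class-dependent glandular fraction.

Construction, per image:

1. **Outline** — a superellipse (exponent uniform in [2, 3], semi-axes
   0.33–0.40 and 0.37–0.44 of the frame) modulated by a low-order random
   radial perturbation (harmonics 2–5, amplitudes ≤ ~2%) and a slight
   vertical taper, giving a star-convex, egg-like, centered region.
2. **Skin** — the pixels within 2–3 px (random per image) of the outline,
   from the Euclidean distance transform.
3. **Ligaments** — Voronoi edges of Poisson-sampled interior seeds,
   skeletonized to 1-px width and kept more than `skin_width + 4` px from
   the outline so the segmentation's peripheral/central rule is
   unambiguous.  The seed density (default 7·10⁻⁴ per pixel) is defined at
   the 512-px reference frame and rescaled by (512/size)² so that the
   number of compartments — the granularity of glandular allocation — does
   not depend on the rendering resolution.
4. **Glandular tissue** — whole Voronoi compartments are assigned glandular
   until the class target fraction g = G/(G+F) is reached, then individual
   compartments are flipped greedily until |g − target| ≤ 0.05 (bounded
   retries, explicit failure otherwise).  Heterogeneous-class layouts
   additionally receive 3–6 spiculated star-shaped glandular "bursts"
   (radius 2–4% of the frame, 5–8 rays), mimicking the sharp burst
   patterns characteristic of that class.

Class bands for g are fatty < 0.20, scattered [0.20, 0.40),
heterogeneous [0.40, 0.65), dense ≥ 0.65 (left-closed), with per-class
targets 0.10 / 0.30 / 0.52 / 0.75.  These bands are configuration, not
constants: published sources do not fix them numerically.

### Intensities

Each tissue has an affine-scaled Beta law (see README).  Per tissue, a
full-frame i.i.d. field is drawn, smoothed with a Gaussian filter
(σ = 0.8 px) to impose short-range texture, and then **rank-matched** back
to the prescribed marginal: the sorted field values are replaced by the
law's quantiles on a 2¹⁶-point grid.  Rank matching was chosen because the
data design only states that histograms "were transformed" after
smoothing; it restores the marginal essentially exactly while preserving
the spatial ordering (hence the correlation) of the smoothed field.  The
four masked fields are summed; background is exactly zero; quantization to
8 bits happens once, after summation, by round-half-to-even with clipping.

Because tissue supports are disjoint from the segmentation ranges
(fat [52, 112] ⊂ [30, 120), glandular [128, 224] ⊂ [120, 226), skin/ligament
[228, 248] ⊂ [226, 255]), threshold segmentation recovers the generating
label map exactly up to the skin/ligament positional rule.

### Ensembles

Class counts follow largest-remainder rounding of the prevalence (default
1:4:4:1), ties broken in class order; the class sequence is then shuffled
deterministically so any prefix is approximately on-mix.  Per-image RNGs
are spawned from the ensemble seed (`SeedSequence(seed, spawn_key=(i,))`),
making ensembles byte-reproducible; each image's child seed is recorded in
the manifest CSV (`filename,class,glandular_fraction,seed`).

### What the generator does *not* emulate

X-ray physics, lesions, 3-D continuity between slices, the replacement
geometry of vessels/ducts, and the long-tailed variation of real phantom
outlines.  Tests passing on this data show that the *pipeline* measures
what it claims on data with known structure — not that any DGM conclusion
transfers to clinical images.

## 2. Segmentation

Global thresholds partition [0, 255] half-open: background < 30,
fat [30, 120), glandular [120, 226), high [226, 255].  The printed source
ranges share endpoints ("[30, 120]", "[120, 226]"); the half-open
convention resolves them deterministically (120 → glandular, 226 → high).
High pixels within 4 px of the foreground boundary are skin, the rest
ligament.  The foreground is the largest connected component of
above-background pixels; smaller specks are relabeled background.  An
image with no foreground yields an all-background map with a warning
(strict callers can request an explicit error).

The fat–glandular boundary mask is the 8-adjacency morphological gradient
between the two tissues, dilated by 2 px; the dilation absorbs small
positional jitter in the memorization correlation.

## 3. Feature registry

Six families, ~1150 named features, fixed order, versioned by a hash of
the name list.  Multi-valued features are summarized by a fixed scheme:
count, mean, population sd, min, max, and quartiles with numpy's
linear-interpolation convention.

* **Texture (B, plus per-tissue first-order)** — symmetric normalized
  gray-level co-occurrence matrices on the breast region only (pairs with
  both ends in the foreground), intensities binned to 64 levels, distances
  {1, 2, 4, 8} × angles {0°, 45°, 90°, 135°}; the 14 classical Haralick
  statistics per (d, θ) plus per-distance angular means.  First-order
  statistics (the 8-statistic scheme plus skewness, kurtosis, histogram
  energy and entropy) and 64-bin intensity histograms are computed per
  scope F, G, S, L, B; these carry the per-tissue areas and mean
  intensities the public metric needs.
* **Morphology (F, G components; B directly)** — area, perimeter,
  convex-hull area/perimeter, solidity, convexity-perimeter ratio,
  eccentricity, axis lengths, orientation, extent, equivalent diameter,
  circularity 4πA/P², Euler number.  Hull quantities come from the convex
  hull of pixel corner points (boundary pixels only for regions > 400 px),
  which is robust for 1-px regions and cheap for large ones.
* **Skeleton (L)** — number of connected skeletons (8-connectivity) after
  defensive re-skeletonization; per-skeleton endpoints (exactly one
  8-neighbor), branch points (8-connected clusters of pixels with ≥ 3
  neighbors count once), pixel lengths; branch-segment lengths; areas of
  ligament-bounded regions (4-connected components of foreground minus
  ligament).
* **Fractal (F, G, L)** — box dimension as the least-squares slope of
  log N(r) vs log(1/r) over r ∈ {2, 4, …, 64}, grid anchored at the
  origin, no offset averaging; gliding-box lacunarity
  Λ(r) = 1 + var(m)/mean(m)² with unit-stride boxes inside the mask's
  bounding box (so a filled rectangle has Λ ≡ 1), per size plus the mean.
* **Moments (F, G, B)** — raw m_pq (p+q ≤ 3) in frame coordinates, central
  μ_pq (2 ≤ p+q ≤ 3), normalized η_pq, 7 Hu invariants; each on the binary
  mask and intensity-weighted (raw 8-bit values).  Orders above 3 are
  omitted (standard Hu construction).
* **F/G ratio (B)** — fat over glandular pixel count.

Missing values (empty tissue, degenerate statistic) are NaN; they are
mean-imputed with *training-side* statistics just before PCA, never
fabricated at extraction time.

## 4. Two-stage evaluation

**Memorization.**  For each generated image, the maximum over training
images of the zero-lag Pearson correlation between flattened dilated
boundary masks.  Full translational cross-correlation over ~10⁸ pairs is
unnecessary because both ensembles are centered by construction; the
dilation tolerates small shifts.  A 4×-max-pooled prefilter keeps the top
50 candidates per query before full-resolution rescoring; it is exact on
every instance we test against brute force.  The flag threshold defaults
to 0.9; the calibration rule (threshold = max + 1 sd of held-out
training-vs-remainder measures, default holdout 3000, scalable down) is
provided as `calibrate_memorization_threshold`.

**Fréchet distance.**  ‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½) with covariances
regularized by 10⁻⁶·I; an imaginary residue of the matrix square root above
10⁻³ is an error.  Embeddings are pluggable: the feature registry, a
weight-free seeded random projection of mean-pooled pixels (default), or
externally computed vectors.  The screening threshold of 30 is advisory
output, not an abort.

**KS ranking metric.**  PCA (after z-scoring with training mean/sd;
zero-variance columns dropped) is fitted on training features only.  Per
bootstrap replicate, images are resampled with replacement on both sides;
a baseline sample of cosine distances between two distinct random training
points and a cross sample between a random training and a random generated
point (n_pairs = 10 000 each) are drawn in the top-10 PC space and compared
with the two-sample KS statistic; mean ± sd over 1000 replicates is
reported.  Defaults follow the study design; the tests and acceptance runs
use reduced n_pairs/n_boot (stated inline) chosen so the suite completes in
minutes — the metric's seeded values are deterministic at any size.
Per-family sub-metrics refit the PC space on one family's columns.  The
public metric is the same pipeline restricted to nine features: areas and
mean intensities of F, G, S, L, and the F/G ratio.

Known behavior: because standardization centers the training cloud, a
*translation* of the generated feature cloud raises the mean KS
monotonically but saturates well below 1 (cosine distances preserve much
angular structure under translation).  KS near 1 requires genuinely
disjoint distance distributions.

## 5. Diagnostics

* **Class rule** — glandular fraction against the generator's bands
  (left-closed).  This is a documented stand-in for a learned breast-type
  classifier; no trained weights are in scope.  On generator data it
  agrees with the manifest for ≥ 95% of images (boundary-of-band images
  account for the rest).
* **Density / coverage** — with NND_k(x) the k-th nearest-neighbor
  distance among training points (k = 5, the metric's customary
  neighborhood in the absence of a published value):
  density = (kM)⁻¹ ΣᵢΣⱼ 1[‖yⱼ−xᵢ‖ ≤ NND_k(xᵢ)],
  coverage = N⁻¹ Σᵢ 1[∃j ‖yⱼ−xᵢ‖ ≤ NND_k(xᵢ)], overall and per class,
  computed in the training top-2 PC space; classes with fewer than k+1
  training points are reported missing.  Identical point sets give
  coverage 1 and density (k+1)/k exactly.
* **Semivariogram** — γ(h) = ½·E[(z_p−z_q)²] over sampled pixel pairs of
  the ensemble-mean image with both ends in the support (mean above a
  small threshold, default 1) and |p−q| ∈ [h−0.5, h+0.5); the sill is the
  mean of γ over the last quartile of lags.  A low, flat sill indicates an
  ergodic ensemble (pixel position carries no tissue identity).  For
  flatness checks on modest ensembles the support is better restricted to
  pixels whose mean exceeds the background threshold (30): the low-mean
  fringe reflects outline variation across images, which dominates the
  tail otherwise.  The sill magnitude — not the tail slope — is the
  discriminator between diverse and positionally biased ensembles.
* **Artifacts** — per image: convexity-perimeter ratio of the breast mask
  (convex-hull perimeter over the marching-squares contour length, the
  contour lightly smoothed with a 7-point circular moving average to
  remove staircase inflation; discretization keeps a disk within ~2% of
  1), flagged below 0.9; disconnected-skeleton count; median
  ligament-bounded region area; nonzero-background fraction/mean/sd.  Per
  ensemble: ligament-sticking score (mean pairwise zero-lag correlation of
  ligament masks, 1000 sampled pairs or exact all-pairs when smaller —
  near 1 means a frozen ligament layout), referenced to the training
  score; and the glandular-mask lacunarity distribution over images
  classified heterogeneous, with the training distribution attached.
  Flip-artifact detection is out of scope.

## 6. Problem sizes in the shipped checks

The test suite uses seeded ensembles of 24 images at 128 px, 100 at 256 px
(intensity-marginal checks), and 240 at 192 px (ranking null, corruption
ladder, density/coverage, ergodicity); the acceptance script uses 1200
images at 256 px.  These sizes were chosen so each check carries adequate
statistical power while the whole suite runs in minutes on a single CPU;
every quantity involved is scale-stable by construction (per-pixel laws,
resolution-normalized compartment counts, relative lag ranges).

## 7. Known limitations

* The layout family is simpler than real phantom slices (no ducts/vessels
  replacement geometry, no out-of-plane effects); morphology and skeleton
  statistics on real challenge data will occupy different numeric ranges,
  though the pipeline is unchanged.
* The feature registry reaches ~1150 entries, not the several-thousand
  scale of a full radiomics battery; the registry is versioned so the
  count is explicit rather than claimed.
* The memorization measure is zero-lag; a generator that memorizes *and*
  translates its copies would need the (not implemented) translational
  search.
* The glandularity class rule inherits segmentation errors near band
  edges; a learned classifier would draw slightly different class subsets
  for the class-conditional diagnostics.
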