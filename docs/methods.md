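# Methods

This note records the models, parameter choices and numerical conventions
behind `plast`, and what the synthetic-data tests do and do not establish
about behaviour on real microscopy data.

## Image preprocessing

**Fluorescence background.** Rolling-ball background subtraction is
realised as a grayscale opening (erosion then dilation) with a flat disk
footprint. The default radius of 50 px exceeds a budding-yeast cell's
diameter, so whole cells ride on the estimated background surface and only
smooth gradients are removed. For radii above 12 px the image is shrunk by
block-minimum, opened at reduced scale, and the background bilinearly
re-enlarged — the classic large-radius shortcut; unit tests pin the exact
small-radius path against a brute-force min/max oracle, and a synthetic
field with an added linear gradient confirms per-cell totals change by
less than 1%.

**DIC flattening.** Transmitted-light images are divided elementwise by a
Gaussian-smoothed copy of themselves (default sigma 25 px, comparable in
scale to the rolling ball; the value is a package choice since only the
procedure, not the kernel, is fixed upstream). Flat regions map to ~1 and
the bright/dark edge shading that carries cell outlines is preserved.

**Channel alignment.** The instrument offset between the DIC and
fluorescence cameras is estimated in three steps: Otsu-threshold the DIC
deviation image, clean with six dilations and eight erosions (3x3
diamond, with hole-filling after dilation so flat cell interiors count as
foreground), then find the integer shift maximising the Fourier-domain
cross-correlation between the binary mask and the fluorescence
intensities within a +/-20 px window. Ties break toward the smallest
|dy|+|dx|, then lexicographically, so the estimate is deterministic. One
practical caveat, visible in the synthetic tests: the correlation surface
is only sharply peaked when the fluorescence extends to the cell outline
(cytoplasmic-like patterns); signal confined deep inside the mask
(nuclear dots) leaves a plateau and a correspondingly loose estimate.
Otsu's threshold is halved before masking because on sparse-edge images
the raw Otsu level separates only the strongest rim peaks and misses the
weakly shaded flanks.

## Segmentation

**Nuclei.** The DNA channel is smoothed with a 9x9 Gaussian lowpass
(sigma 1.5) and adaptively thresholded with window w = 35 px and bias
−60. The bias follows the OpenCV `adaptiveThreshold` sign convention
(threshold = local mean − bias): −60 selects pixels at least 60 counts
*above* their local mean, which is the only reading under which bright
nuclei on a dark background are detected at all. The generic
`local_structures` primitive keeps the plain additive convention
(threshold = mean + C, strict inequality, reflected borders); the two are
reconciled inside `detect_nuclei`. Components under 20 px are discarded
as specks.

**Cells.** A watershed floods the Sobel gradient magnitude of the
flattened DIC from the nucleus labels plus one background seed (the
complement of the cleaned DIC mask), so no label can flood the whole
image and each nucleus ends up in exactly one cell. Because the DIC edge
shading is the derivative of the cell indicator, the gradient of the DIC
has a local *valley* exactly at the true edge and crests about one
shading half-width inside and outside it; the flood line settles on the
inner crest. Labels are therefore expanded 2 px into background after
the watershed (`boundary_expand`, configurable) to compensate for that
systematic bias. On default synthetic fields this chain yields mean
boundary error ~0.9 px and Rand error ~0.02 against ground truth
(regression thresholds in the suite: 3 px and 0.05).

**Mother–bud combination.** Two touching labels merge when their combined
area is at most θ_A (default 2000 px — also the QC maximum cell area) and
their total-DNA difference is at least θ_D (default 1000 intensity
units): a bud carries little DNA relative to its mother. Merging repeats
to a fixed point in deterministic order (ascending combined area, then
label ids) and never increases the label count.

**Evaluation metrics.** The boundary error index is the symmetric mean of
directed nearest-neighbour Euclidean distances between boundary pixel
sets (internal label-label edges included); the Rand error index is the
fraction of pixel pairs the two labelings co-assign differently, with
background counted as a region. The production Rand implementation uses
the label-pair contingency table (O(N)); the tests check both metrics
against O(N²) brute-force oracles to 1e-12.

## Regions, normalization, features

Five regions partition each cell: cellular, nuclear (intersection with
the cell), cytoplasmic (cell minus nucleus), cytoplasmic boundary (the
rim removed by eroding the cytoplasm with a radius-3 disk), and inner
cytoplasmic (the rest). A nucleus covering the whole cell is a degenerate
cell; a missing nucleus is allowed (nuclear statistics are 0, flagged).
GFP is normalized to unit total inside the cellular region before *any*
feature is computed, making every feature invariant to expression level.

The 623-feature registry is fixed and ordered; only the group sizes are
externally binding, and the exact memberships are this package's own
enumeration, frozen by a golden-name hash test:

* 45 intensity = 9 statistics (total, mean, sd, median, MAD, min, max,
  skewness, kurtosis) x 5 regions;
* 20 intensity-ratio = {total, mean} over the 10 unordered region pairs;
* 81 morphology = 15 mask descriptors x 5 regions + 6 cell-level
  descriptors (nucleus-cell centroid distance and area/perimeter ratios,
  bounding-box height/width/aspect) — masks only, never GFP;
* 273 Haralick = 13 co-occurrence statistics x 21 GLCM configurations
  (5 regions x distances {1,2,4} at 8 gray levels, plus the cellular
  region x {1,2,4} at 16 and 32 levels; GLCMs are angle-averaged,
  symmetric, min-max quantized within the region with a reserved
  out-of-region level);
* 18 moments = Hu's 7 invariants on the normalized GFP, Hu's 7 on GFP
  binarized at its in-cell mean, and 4 intensity-centroid offset/radial
  spread statistics;
* 186 local structure = for each of 16 odd windows w = 3..33, the binary
  structure mask B_w (adaptive threshold, bias 0 on normalized GFP,
  restricted to the cell) is summarized by six statistics — total, mean
  and sd of GFP on B_w, object count, object total area, object mean
  area — each divided by the same statistic on the whole cell (96 global
  ratios) and by its value at the previous window (90 stepwise ratios).
  Zero denominators yield 0, never NaN. The 3..33 window ladder reflects
  the observed convergence of local structures to the global pattern by
  w ≈ 33.

Empty-region statistics are 0 with a flag; a zero-signal cell produces an
all-zero vector with the flag propagated.

## Quality control

Fixed order: cell filters, NaN imputation, strain filters; idempotent.
Cells outside [300, 2000] px area are removed, then cells whose stored
shape metric exceeds 0.2. The metric is the *convex deficiency*
1 − area/convex-hull-area: the upstream description pairs the rule
"remove > 0.2" with plain solidity, but solidity of any plausible cell is
near 1 and the rule as literally stated would discard everything; the
deficiency reading ("more than 20% off convex") is the only
semantically coherent one, and the definition is isolated in a single
function so the convention can be swapped. NaNs are replaced by
within-strain per-feature medians (all-NaN features become 0 with a
warning); strains with fewer than two surviving cells, or on caller
exclusion lists, are dropped whole.

## Profiles and d_p

The SVM profile of a strain is the normal vector W of a linear
maximum-margin classifier separating the strain's cells from a fixed
reference cell pool, after z-scoring features with one scaler fit on the
pooled strain + reference cells (linear SVMs are scale-sensitive; the
shared scaler keeps profiles comparable). The cost parameter is grid-
searched over the powers-of-two ladder 2^-5..2^5 by training accuracy,
ties to the smallest cost; the termination tolerance is 0.01. W is then
normalized: the default convention divides by the *magnitude* of the sum
of its elements. Preserving the hyperplane's orientation (decision
function positive on the strain side) is essential — dividing by a signed
near-zero sum flips some profiles to their antipodes and randomly
destroys every cosine comparison downstream, which is observable as
within-class d_p rising to the between-class level. An l2 unit-norm
convention is available and the choice is recorded in the profile
metadata; d_p is invariant to positive rescaling either way.

Reference sets are selected by sampling candidate sizes (10..90 cells by
default, five repeats) from strains carrying designated source
categories, and keeping the size whose profiles best classify
single-category strains.

d_p is cosine dissimilarity (chosen because profiles are normalized
directional objects and the compartment-map clustering is cosine-based);
Euclidean distance is available behind a flag. Group scores are the mean
pairwise d_p with self-exclusion. The classification harness
(Crammer–Singer multi-class linear SVM, stratified 6-fold
cross-validation repeated over trials; the fold count is a parameter
since both 5 and 6 appear upstream) is an evaluation tool, not part of
profile construction.

## Compartment mapping

For each protein, mean d_p scores against every catalog compartment
(organelles plus protein complexes with >= 15 members; self-membership
excluded) form one sample. Most compartments are non-specific for the
protein, so the dominant rightmost bulk of the scores is its null. Two
null estimators are implemented:

* **mixture** (default): a BIC-selected Gaussian mixture (1–3 components;
  an extra component must improve BIC by 10) whose largest-mean component
  supplies (μ_null, σ_null). On unimodal pure-null scores this reduces to
  the sample mean/sd and the resulting z-scores are honestly calibrated:
  with 500 simulated pure-null proteins x 73 compartments the fraction of
  proteins receiving any assignment is ≈ α at α = 0.05 and 0 at
  α = 2.5e-4.
* **kde_mode**: trim the upper/lower fifth percentiles, Silverman-
  bandwidth Gaussian KDE on a 512-point grid (data range +/- 3
  bandwidths), take the rightmost strict local maximum (plateaus resolve
  to their rightmost grid point) as μ_null and the one-sided RMS of
  scores above it as σ_null. This mode-based route is kept and tested for
  its semantics (it also ignores a low-d_p signal cluster), but the
  sampling noise of a mode estimate at n ≈ 73 (sd ~0.03 on σ = 0.1
  scores) inflates the extreme normal tails by an order of magnitude, so
  it is not used where calibrated P-values matter.

z̃ = (d_p − μ_null)/σ_null; P-values are the lower-tail standard-normal
probabilities, Bonferroni-corrected per protein (m = compartments scored
for that protein); assignment requires adjusted P below the threshold
(2.5e-4 by default, with 1e-12 as the stringent choice). Standardization
is affine, so the within-protein compartment ranking is untouched.
σ_null is floored at 1e-6; all-equal score vectors are a degenerate-null
error. The shared-compartment ratio of two assignment sets is the Jaccard
ratio (|a∩b|/|a∪b|; the min-denominator variant is behind a flag); two
empty sets give 0.

## Downstream statistics

Subunit retrieval ranks all non-query proteins by ascending mean d_p to
the query set and evaluates precision/recall/F1 at every rank cutoff; the
annotation baseline predicts every protein carrying the query's majority
category (ties lexicographic). Method comparison uses one-sided paired
t-tests on per-complex maximum F1, Bonferroni-corrected over ordered
pairs. The permutation test permutes pooled labels (default 10,000
permutations; two-sided by absolute mean or median difference) and
reports the plain exceedance fraction; its type-I error on null normal
samples measures 0.044–0.054 at α = 0.05. Duplicate pairs are labeled DL
when their d_p reaches the stated percentile of d_p over random
non-duplicate pairs (sampled without replacement, excluding self and
duplicate pairs); by construction the fraction of null pairs labeled DL
is 1 − percentile/100. Functional similarity of a pair is the fraction of
matching annotation terms with the *smaller* term set as denominator
(robust to annotation-depth asymmetry; union denominator behind a flag),
thresholded at 0.75, and the SL/DL x similar/dissimilar table is tested
with Fisher's exact test. Affinity propagation (shared preference, sweep
utility for the cluster-count-vs-preference curve) and Ward hierarchical
clustering are delegated to scikit-learn/scipy; enrichment is the
hypergeometric upper tail with Benjamini–Hochberg adjustment across
categories.

## Synthetic data: what it does and does not show

`generate_field` renders elliptical cells (radius 12–18 px, mild
ellipticity, non-overlapping by default, bounded placement retries) on a
256x256 canvas: the DIC channel is a mid-gray baseline plus the signed
diagonal derivative of a smoothed cell indicator (watershed-segmentable
rims without modeling real optics — including DIC's genuine weak-flank
anisotropy); the DNA channel is bright only inside the one nucleus per
cell (radius fraction 0.35); GFP is drawn per pattern class (nuclear,
cytoplasmic, punctate, peripheral ring, bud neck, mixed) with exactly
20,000 intensity units per cell before noise; noise is additive Gaussian
(sd 1.0 on the 8-bit-like scale), clipped, with Poisson optional; a
configurable integer channel offset emulates camera misalignment. Fixed
seeds fix every array byte-for-byte.

`generate_feature_table` bypasses imaging: pattern classes are Gaussian
class means (effect size 1.0 x N(0, I) over 50 features by default),
strains get a class mean plus jitter (0.25 x effect size), cells are unit
-variance draws, ~20 cells/strain. Duplicate pairs interpolate strain B's
mean between A's realized mean (lambda = 0, identical parameters) and
B's own class mean (lambda = 1), so divergence is a controlled dial.

These generators establish *mechanical and statistical correctness* —
segmentation accuracy against known masks, feature-inventory integrity,
calibration of the null machinery, monotonicity of d_p in divergence.
They do not emulate real DIC optics, point-spread functions, focus
drift, autofluorescence, crowded colonies, or correlated feature noise;
passing tests therefore bounds algorithmic behaviour, not performance on
any particular real dataset.

## Problem sizes and numerical conventions

The test suite and the acceptance script run small, seeded versions of
each analysis: fields of ~10 cells, 24 strains for pattern recovery, 100
strains for retrieval, 500 pure-null proteins and 1000 permutation-test
repetitions (500 permutations each) for calibration, 50 duplicate pairs
and 2000 null pairs for divergence — sizes chosen so every check runs in
seconds while estimator noise stays well inside the asserted bands.
Throughout: 4-connectivity for components and adjacency (matching the
diamond structuring element), strict inequalities in adaptive thresholds,
reflected image borders, ratios with zero denominators defined as 0 with
a flag, and all randomness routed through seeded `numpy` generators
(stage seeds derived from one master seed).

## Known limitations

Integer-pixel alignment only (no sub-pixel, rotation or scale); the
watershed boundary-bias compensation is tuned to the synthetic DIC edge
model and is a parameter on real data; Haralick and morphology group
memberships are package-defined (counts, not compositions, are the
contract); the SVM profile depends on the reference-set distribution, and
profiles built against different references are not comparable; the
mixture null assumes the non-specific bulk is approximately Gaussian.
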