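# Methods

This note documents the models implemented in `breastcomp`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical details that matter for reproducing
results.

## Geometry and skin cropping

All voxel data live on axis-aligned grids: world coordinates are
patient-based millimetres (LPS), indices are 0-based in (slice, row,
column) order, and masks store voxel-centre membership.  Dose grids are
resampled onto the CT grid by trilinear interpolation before any
per-voxel analysis (masks are never interpolated); CT voxels outside the
dose extent are set to 0 Gy and flagged rather than extrapolated.
Contours are rasterized per axial slice by a voxel-centre-in-polygon test,
and masks are polygonized back via sub-voxel iso-contours at the 0.5
level, so mask → contour → mask round trips reproduce the original at
Dice ≥ 0.99 on smooth structures.

The breast contour is cropped a margin (default 5 mm) from the skin
because treatment-planning systems estimate superficial dose poorly and
skin effects are a separate endpoint.  The skin distance of an in-body
voxel is its Euclidean distance, at native anisotropic spacing, to the
nearest outside-body voxel centre (`scipy.ndimage.distance_transform_edt`);
voxels with distance ≤ margin are removed.  On a 1 mm grid this removes
exactly the 5 voxel layers nearest a flat surface, and a margin of 0 is
the identity.  A geodesic (along-skin) margin would differ in concave
regions; the Euclidean definition was chosen as the standard
morphological-erosion semantics and is what the tests' brute-force oracle
implements independently.

## First-order intensity features

Three features summarize the in-breast HU distribution: median, IQR
(linear-interpolation quantiles on raw voxel values — the quantile rule is
fixed because different conventions shift the IQR by a fraction of a bin),
and uniformity

    U = sum_i p(i)^2,   p(i) = count_i / n_total,

over a uniform-width histogram of the masked values.  U = 1 when all
voxels share one bin and 1/n for n equally populated bins; merging bins
can only increase it.  The histogram uses half-open bins aligned to
multiples of the bin width; a maximum sitting on the top edge opens a new
bin, so the analytic small cases are exact.  The default intensity bin
width is 25 HU, the de-facto first-order radiomics default; with fat
SD ≈ 5 HU this puts a predominantly-fatty breast's mass into very few
bins, giving the high-uniformity regime expected for the fatty cluster.
Uniformity is dimensionless; it is reported both as a fraction and as a
percentage.  Dose uniformity uses the same statistic with a 0.25 Gy
default bin width (the discretization is a knob and is logged, since the
statistic's value depends on it).

## Density clustering

Cohort feature vectors (median, IQR, uniformity) are z-scored per
dimension — HU and probability-scale features are incommensurate — and
partitioned by k-means with k = 4 (matching the four BI-RADS density
categories by design), k-means++ initialization, 10 restarts, and a fixed
default seed (20140) for reproducibility.  Clusters are named by ascending
centroid median HU (fatty → extremely dense), with ties broken by
descending uniformity; this ordering rule is a package convention
consistent with the monotone median-HU structure of the four density
classes.  The untreated-side breast can either be assigned through the
fitted model (nearest centroid) or re-clustered independently; agreement
between two labelings is summarized by a 4×4 confusion matrix, per-class
agreement and overall accuracy.

## Tissue segmentation

Each patient's in-breast HU histogram is modelled as a two-component
Gaussian mixture (fat = lower mean, fibroglandular = higher).  EM runs on
the weighted 1-HU-bin histogram of in-window voxels rather than the voxel
list — estimates identical at histogram resolution, but orders of
magnitude faster on clinical volumes — with moment-based initialization
(means at the weighted 25th/75th percentiles, pooled SD, equal weights),
so the fit is deterministic and depends only on the histogram.
Convergence is a relative log-likelihood change below 1e-6 (max 500
iterations).  Degenerate inputs are rejected: an SD collapsing below 1 HU,
or a converged fit whose components are not separated (Ashman's
D = |μ₂−μ₁| / √((σ₁²+σ₂²)/2) < 2, the classic non-bimodality regime, which
is where EM lands when the input is a single population) raise an error
suggesting single-population input; a component weight below 0.01 is
flagged.

Fitting is windowed: a coarse default window of [−200, +100] HU excludes
air, lung and high-HU outliers (surgical clips, calcifications), and one
refinement pass refits inside the union of the fitted μ ± 2σ intervals.
The refinement makes the fit robust to in-window outliers (e.g. seroma
tails) at the cost of a small truncation bias — cutting ±2σ tails shrinks
the refitted SDs by ≈ 5 % and moves means by ≲ 0.1 σ, which keeps
recovered means within 1 HU of truth on calibrated mixtures.  Parameter
recovery of the pure EM estimator (no refinement) is additionally verified
against full-likelihood EM (`sklearn.mixture.GaussianMixture`) as an
independent oracle.

Segmentation thresholds each breast voxel against the closed μ ± 2σ
intervals: fat wins overlaps (the fat peak is narrower and more distinct),
remaining fibroglandular-interval voxels are fibroglandular, everything
else stays unclassified — never reassigned, so the three masks always
partition the breast and percentages of complete breast volume sum to
100.  Because both tissues lose the same ±2σ tail mass (≈ 4.6 %) to the
unclassified pool, the composition ratio
`fat / (fat + fibroglandular)` is the near-unbiased fat-fraction estimate
and is reported alongside the complete-breast percentages; on phantoms it
tracks ground truth to well under 2 percentage points across fat fractions
0.25–0.85.

## Substructure dosimetry

Physical dose is converted voxelwise to the equivalent dose in 2 Gy
fractions under the linear-quadratic model,

    EQD2 = D (d + α/β) / (2 + α/β),   d = D / n,

with α/β = 1.7 Gy (late breast effects) and n the plan's nominal fraction
count — required explicitly, never defaulted, because EQD2 is undefined
without it.  EQD2 equals D at exactly 2 Gy/fraction, exceeds it above, and
maps 0 to 0.  A sequential boost stored as a separate grid should be
converted per phase and summed, since fraction dose differs between
phases.  Per structure (complete breast, fat, fibroglandular,
unclassified) the mean and maximum are computed on raw voxel doses and
uniformity on the binned histogram, for both dose forms.  Two exact
identities are enforced by tests: substructure-volume-weighted mean equals
the whole-breast mean (the substructures partition the breast), and the
whole-breast maximum equals the maximum over substructures.

## Toxicity association

Grades are 0–3 per endpoint (pain, oedema, atrophy, induration), timepoint
(immediately post-RT, 1 y, 2 y) and source (clinician CTCAE-style /
patient BR23-style).  The analysed grade is the maximum of the two
reports (provenance retained); a max-over-time severity summary is also
provided, since both per-timepoint and maximum-severity analyses are
common.  Models are proportional-odds cumulative-logit regressions fitted
by maximum likelihood (statsmodels `OrderedModel`); AIC = 2k − 2 logL with
k counting slopes plus cutpoints.  Analysis is complete-case per
endpoint × timepoint cell.

Selection per cell: (1) candidates with pairwise |Pearson r| ≥ 0.9 are
reduced by dropping the member with the worse univariable AIC for that
endpoint (without an endpoint context, the earlier-listed variable is
kept); (2) a baseline model with the fixed clinical covariates (the
default list — age, breast volume, boost — is configurable, since baseline
sets vary between studies) is fitted; (3) forward stepwise selection adds
the candidate with the largest AIC decrease until none decreases it,
never removing baseline variables, on a complete-case set held fixed
across candidates so AICs are comparable; (4) an optional backward pass
from the full model flags forward/backward agreement.  The trace records
every comparison; accepted steps strictly decrease AIC and the path is a
deterministic function of the data.  Significance is annotated at two
conventional tiers (p < 0.05, p < 0.001) without multiplicity correction —
reported, not endorsed: the workflow's aim is assessing the added value of
composition/dose variables over a clinical baseline, not building a
validated prediction model.  Non-converged or separated fits are excluded
from selection with a trace note.

## Synthetic data

`phantom` generates testable stand-ins for every input:

* **Imaging.**  A hemispherical breast (default radius 38 mm on a 2 mm
  grid, ≈ 13 000 voxels) protrudes from a body slab; air is −1000 HU, slab
  soft tissue ≈ 30 HU.  Tissue structure comes from a Gaussian random
  field smoothed to a correlation length and thresholded at the
  fat-fraction quantile of its in-breast values, so the ground-truth fat
  mask hits the target fraction to ±0.5 % while the correlation length
  controls "scattered" vs "heterogeneous" texture.  HU are drawn per
  tissue from archetype-calibrated Gaussians — fat/fibroglandular
  (mean, SD) = (−110, 5)/(−52, 12) for fatty through (−76, 25)/(9, 15) for
  extremely dense, following published per-cluster tissue statistics.
  Archetype fat fractions (0.90/0.72/0.55/0.35), correlation lengths and
  the volume–density coupling (fatty breasts largest) are invented
  defaults chosen to reproduce the qualitative cluster structure.
  Optional surgical-clip voxels at +800 HU fall outside the GMM window.
* **Dose.**  Base prescription (default 40.05 Gy in 15 fractions) plus an
  optional linear gradient and an optional Gaussian boost centred in a
  chosen tissue.  Cohorts draw per-patient variation: ±2 % planned-dose
  jitter, gradient amplitude ~ U(0.5, 1.5)× nominal, boost present with
  probability 0.5 and centred in fat or fibroglandular tissue with equal
  probability — the tumour bed can sit in either — which keeps fat- and
  fibroglandular-dose metrics identifiable rather than collinear.
* **Outcomes.**  Grades follow a proportional-odds latent model on
  z-scored covariates with user-specified coefficients, latent cutpoints
  (0.5, 2.0, 3.5) giving realistic grade ≥ 1/2/3 rates, a declining latent
  offset at later timepoints, and clinician/patient reports as two
  independent mis-graded (±1 with probability 0.15) observations of the
  same true grade.  Every cohort ships a truth JSON (archetypes,
  generating coefficients) for oracle-based testing.
* **Feature-level cohorts.**  For clustering studies, (median, IQR,
  uniformity) vectors are sampled directly from archetype centroids
  calibrated to reported per-cluster characteristics (fatty:
  −108 HU / 25 HU / 0.40), with a `separation` factor scaling centroid
  offsets from the grand mean; separation ≥ 3 gives the well-separated
  regime where k-means recovery is exact.

What the generator does **not** emulate: real anatomy (no chest wall,
axilla or skin-fold geometry), seroma or post-surgical distortion, CT
acquisition differences between centres, scattered-dose structure from
actual beam arrangements, informative missingness in outcomes, or the
empirical correlation structure of clinical covariates.  The imaging
phantom's HU histograms are cleaner than clinical ones, so absolute
feature values (e.g. a single phantom's uniformity) need not match
clinical cohort values even though ordering relations do.  Passing tests
demonstrate algorithmic correctness and recoverability under the stated
models — not clinical performance.

## Problem sizes and numerical tolerances

The validation suite uses: mixture recovery at 10⁵ voxels over 50 seeds
(means ±1 HU, weights ±0.02); segmentation Dice ≥ 0.95 over 50 phantoms
spanning all archetypes; clustering ARI = 1.0 on 10 cohorts of n = 200 at
separation 3; ordinal bias < 0.05 at n = 2000 over 100 replicates and Wald
type-I error in [0.03, 0.07] over 1000 null replicates at n = 400;
selection power ≥ 80 % over 100 forward runs at n = 1500 with one true
effect (β = 1) among 5 nulls; and end-to-end dose→toxicity pattern
recovery in the majority of 20 cohorts of n = 180.  The acceptance script
recomputes the same quantities at moderately reduced replicate counts so a
full from-scratch rerun stays around a minute.  Exact identities
(partition, conservation, AIC, EQD2 fixed point) are asserted at 1e-9 or
machine precision; EM convergence tolerance is 1e-6 relative
log-likelihood.
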