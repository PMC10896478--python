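# Methods

## The analysis

`fcsconn` implements a distance-resolved, voxel-wise degree-centrality
analysis of resting-state fMRI. For every grey-matter voxel *i* on a mask of
N voxels, the functional connectivity strength is

    FCS(i) = 1/(N − 1) · Σ_{j ≠ i, r_ij > r0} z_ij ,

where r_ij is the Pearson correlation between the preprocessed time courses
of voxels *i* and *j*, z_ij = atanh(r_ij) is the Fisher Z transform, and
r0 = 0.2 discards weak edges that plausibly reflect noise. Because r0 > 0,
negative correlations never contribute and FCS is nonnegative; FCS is the
weighted degree of the thresholded voxel-level connectivity graph.

The distance-resolved variant partitions the same sum by the Euclidean
distance D_ij between voxel coordinates (0-based voxel indices times the
voxel size, one common space for all subjects) into half-open bins
[w(k−1), wk), by default 18 bins of 10 mm spanning 0–180 mm. Both variants
share the 1/(N − 1) normalization — deliberately *not* a per-bin neighbour
count — so the bin maps sum exactly to the full-range map. This conservation
law is enforced in the tests at 1e−9 relative tolerance, and the short-range
(0–100 mm) / long-range (100–180 mm) aggregates are exact partial sums of
bins. A pair at exactly the top edge would be assigned to the last bin
(a documented dialect choice; it cannot occur when the bin span exceeds the
mask diameter). Pairwise correlations are streamed over voxel blocks so the
full N × N matrix is never materialized; results are block-size-invariant
up to BLAS summation order (≤1e−12).

Ties at exactly r0 are excluded (strict inequality), correlations are capped
at 1 − 1e−7 before atanh so duplicated voxels cannot produce infinities, and
zero-variance voxels are defined to correlate 0 with everything (logged),
which keeps degenerate inputs finite without special cases downstream.

## Temporal preprocessing

Order: discard the initial volumes (default 10) → zero-phase Butterworth
band-pass 0.01–0.1 Hz (order-2 sections applied forward–backward, so no
phase lag distorts correlations) → one combined OLS projection removing a
linear trend and any nuisance regressors (intercept always included). The
executed order is recorded in the run log. Filter contracts are asserted on
interior samples of long series to tolerate edge transients: pass-band gain
within [0.9, 1.1] at 0.05 Hz, stop-band gain ≤ 0.2 at 0.2 Hz and at half the
low edge.

Nuisance columns that are constant (e.g. zero-filled motion placeholders for
simulated data that contains no motion) are dropped with a log message; true
collinearity is an error naming the offending columns.

The mean masked time course (global signal) is available as a regressor but
is **off by default** for the synthetic study conditions. With a small
number of planted latent networks the global mean is nearly collinear with
the hubs' common mode, so regressing it removes planted signal and can even
invert group differences — an extreme form of the well-known ambiguity of
global-signal regression. On real data, where thousands of sources
contribute to the global mean, the regressor is meaningful; it remains a
configuration option and a fully tested operation.

## Group statistics

The group comparison is a one-way ANCOVA implemented exactly as the linear
model FCS ~ intercept + group + age + sex + education, reporting the signed
group-contrast t (patient − control; F = t²; df = n − p). The fit uses a QR
decomposition for numerical stability at raw covariate scales, and an
(almost) exact fit reports t = 0 rather than a ratio of rounding errors.
Brain–behaviour maps use the same machinery with a cognitive composite score
as the regressor of interest within the patient group (positive t = higher
FCS with better performance). Maps are smoothed with a 6 mm FWHM Gaussian
kernel before statistics — never the time series. Smoothing is
mask-weighted: the convolution runs on the full grid with zeros outside the
mask and is renormalized by the smoothed mask indicator, so boundary voxels
are not dimmed (a constant map stays exactly constant).

Family-wise error over the analysis mask is controlled by Monte Carlo
cluster-extent correction: simulate null volumes of white noise, smooth each
to the residual maps' estimated per-axis FWHM within the mask, standardize,
threshold two-sided at the voxel-level p (default 0.05), label positive and
negative suprathreshold voxels separately under 26-connectivity (6/18
configurable), and take the empirical 'higher' (1 − alpha) quantile of the
per-iteration maximum cluster size as the extent threshold. Only clusters
*strictly larger* than the extent survive, and each carries the sign of the
group difference. Per-bin analyses are corrected within their own bin masks
(the set of voxels with at least one neighbour in that distance bin), since
peripheral bins cover only part of the mask. Extent thresholds are
data-dependent quantities recomputed per run, never constants.

Residual smoothness is estimated from spatial autocorrelation at lags 1–4:
for standardized residuals, rho_k = 1 − var(diff_k)/2 and
sigma² = −k²/(4 ln rho_k) per axis; the estimate takes the largest
Gaussian-equivalent sigma over lags with rho_k > 0.05 and clips below at one
voxel. On truly Gaussian fields every lag agrees, so the estimator reduces
to the classic first-difference formula; on FCS residual fields, whose
autocorrelation has heavier-than-Gaussian tails, the lag-1 fit understates
the effective smoothness that governs null cluster sizes and makes the
correction anticonservative — the same observation that moved the field's
cluster tools from FWHM to ACF-based null models. The multi-lag estimate
restores null calibration on simulated cohorts (verified by the null-cohort
test below).

## Neuropsychological composites

Each raw test score is z-scored against a reference population (default:
the healthy-control group, configurable to the whole sample), sign-flipped
for timed tests where higher raw scores mean worse performance (trail
making, Stroop times — the shipped `data/test_catalogue.yaml` fixes the
flags and domain assignment), and averaged within its cognitive domain
(episodic memory, visuospatial, executive, information processing speed;
MMSE serves as the global screen). A subject's missing tests are excluded
from their domain mean. Cohort-table statistics: pooled-variance t-tests for
age and education, Pearson chi-square *without* continuity correction for
the 2×2 sex table (configurable), and ANCOVA with age + education covariates
for the composites — note the deliberate difference from the
age + sex + education covariate set used for voxel-wise maps.

## The synthetic cohort generator

No public dataset accompanies this analysis, so ground truth comes from a
generative model that plants exactly the structure the pipeline claims to
detect.

Geometry: an ellipsoidal "grey-matter" mask (semi-axes 45% of each grid
extent) at 3 mm isotropic, with four hub centres placed along the longest
axis (defaults at 12%, 38%, 62%, 88% of its extent on a 48×40×36 grid, so
the extreme pair sits ~107 mm apart and the 100 mm cut is meaningful).

Signals: each hub emits a band-limited (0.01–0.1 Hz, the analysis band, so
preprocessing is gain-neutral on signal) unit-variance latent series. A
subject's latent series are correlated according to a hub-by-hub coupling
matrix (base coupling 0.7 between all pairs) via a Cholesky transform of
independent filtered noise; an eigenvalue-clipping nearest-correlation
repair handles any non-positive-definite matrix (logged). Patients differ
from controls in exactly one respect: couplings of hub pairs separated by
more than the 100 mm cut are multiplied by `long_range_attenuation`
(default 0.5; 1 = null cohort). Voxel time courses mix the latent signals
with Gaussian spatial loadings (scale 4.5 mm, truncated below 0.01), plus:

- white noise, sd 0.55 per unit signal — puts control hub-to-hub
  correlations near 0.45 and attenuated patient long-range correlations
  near 0.23, i.e. reduced but above r0, as in a disease that weakens rather
  than abolishes coupling;
- spatially smooth noise (6 mm FWHM, sd 0.2) giving maps realistic local
  correlation structure;
- a per-subject *smooth log-normal noise-level field* (sd 0.5 on the log
  scale, 12 mm FWHM) emulating regional tSNR variability. This matters:
  across-subject variance of smoothed FCS maps would otherwise be dominated
  by the low-rank latent-coupling fluctuations, whose region-wide coherent
  excursions no stationary cluster-extent correction can calibrate away.
  The smooth field adds high-rank, stationary across-subject variance that
  survives map smoothing and keeps the null model honest;
- a baseline of 1000, per-voxel linear drifts, and per-subject coupling
  gain ~ N(1, 0.05) applied to all off-diagonal couplings.

Cognition: the subject's *realized* mean inter-hub Fisher-z coupling
(computed from the simulated latent series, attenuation and gain included)
is standardized across the cohort and scaled by `cognition_effect`, plus
independent noise (sd 0.3), to form the information-processing-speed score.
Patients therefore score lower whenever attenuation < 1, and the score is
genuinely linked to the subject's hub connectivity so voxel-wise recovery
is testable. The other domain scores and demographics are drawn from
group-specific normals/Bernoullis typical of an elderly small-vessel-disease
cohort (patients ~65 vs controls ~71 years, male fraction 17/36 vs 7/34,
education ~11 vs ~12 years).

Randomness: each subject draws from substreams keyed by (cohort seed,
subject index, stream), with demographics on a separate stream from voxel
data, so cohorts are reproducible subject-by-subject and table values never
share random draws with imaging noise.

What the generator does **not** emulate: head motion, physiological noise
spectra, scanner drift beyond a linear term, spatial normalization error,
anatomical folding, or the high-rank network structure of real brains.
Passing recovery tests therefore demonstrates the pipeline's correctness
against its own model class, not performance on real data.

## Evaluation experiments and problem sizes

The `experiments` module fixes scaled study designs run by both the test
suite and `scripts/acceptance.py`:

- **FWE calibration**: ~2750-voxel ellipsoid, 6 mm supplied smoothness,
  1000 Monte Carlo iterations to derive the extent, 300 fresh null fields
  to measure the realized family-wise error (target: inside the binomial
  95% interval around alpha = 0.05).
- **Distance recovery**: a 56×12×10 grid (~2500 mask voxels, max in-mask
  distance ~150 mm) with two hub pairs; three of six hub pairs lie beyond
  100 mm (108, 108, 132 mm). Ten cohorts of 16 patients + 16 controls at
  160 timepoints (150 after discard, TR 2 s); per-bin cluster-corrected
  significant-voxel counts must peak in a bin above the cut, and the mean
  group effect at hub cores must be negative, in ≥9/10 cohorts.
- **Behaviour recovery**: 32 patients (the clinical study scale) on the
  same grid; ≥80% of planted hub-core voxels (within 3 mm of a hub centre)
  must show significant positive t for the linked score on long-range FCS,
  and the mean suprathreshold fraction under 20 score permutations must sit
  near the voxel-level p.
- **Null-cohort property**: 20 replicates of 8+8 subjects at 120 timepoints
  with attenuation 1; the corrected group map must be empty in ≥95% of
  replicates.

These sizes are the package's own choices for routine, repeatable
verification; all scale knobs are plain function arguments.

## Known limitations

- Cluster-extent correction under strongly non-stationary or low-rank
  across-subject noise is approximate even with ACF-aware smoothness; the
  generator's noise-level field is part of the study design that keeps it
  calibrated.
- The Monte Carlo null thresholds at the Gaussian z quantile while t maps
  threshold at the t quantile of their own df; both cut the same voxel-level
  p, the AlphaSim convention.
- Composite-Z reference defaults to controls; switching the reference
  changes composite scales but not group contrasts.
- The uncorrected chi-square is the right dialect for the cohort tables
  this package targets; enable the continuity correction for very small
  counts.
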