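# Methods

This note records the models, algorithmic choices, parameters and known
limitations behind `ramandx`, at the level of detail a maintainer or
reviewer needs to judge what the package does and does not establish.

## Spectral model and preprocessing

A measured tissue Raman spectrum is modelled as a non-negative mixture of
reference chemical spectra sitting on a broad, smooth fluorescence
background, with additive detector noise, occasional single-point
cosmic-ray spikes and possible saturation at the detector ceiling.  The
wavenumber axis spans 450–1800 cm⁻¹.

**Artifact rejection.**  A spectrum is rejected as cosmic-ray-contaminated
when the largest absolute second difference exceeds
`spike_mad_threshold` (default 8) times the median absolute deviation of
its second differences.  The MAD measures the noise scale; on clean,
essentially noiseless spectra it collapses toward zero and smooth band
curvature would be misread as a spike, so the criterion is floored by a
robust amplitude scale (99.5th-percentile minus median intensity).  Genuine
spikes — injected at 20–100× the local signal scale — exceed the floor by
an order of magnitude; smooth bands, whose curvature per point is far below
their amplitude, do not.  The threshold of 8 gives ≤ 1 % false rejection on
clean noisy spectra and ≥ 95 % sensitivity to injected spikes in the test
suite.  Saturation is any point at or above the configured ceiling.

**Baseline estimation.**  Iterative signal removal: with window w = the
nearest odd integer to 7 % of the spectrum length (582 points available as
an explicit override for instruments where that absolute count applies),
repeat for 20 iterations: filter the working spectrum with an SG filter of
window w, replace every point lying above the filter output by it
(pointwise minimum), re-filter.  The SG polynomial order is 2: an order-2
local fit tracks the curvature of a smooth fluorescence hump without
following Raman bands; in end-to-end ablations order 2 outperformed orders
0–1 and 3–4 on downstream classification, so the default stands.  Early
stop triggers when the working envelope changes by less than 1e−12.  The
working envelope is monotone non-increasing across iterations by
construction; the SG output itself may rise locally, which is why the
envelope, not the filter output, carries the monotonicity guarantee.
Negative residuals after subtraction are retained; only the copy handed to
the factorization clips them at zero.

**Calibration.**  Spectra are aligned on the 1003 cm⁻¹ phenylalanine
ring-breathing band — usable precisely because it is strong and spectrally
isolated in tissue.  Within ±10 cm⁻¹ of the reference the band apex is
located as the argmax of the lightly smoothed, endpoint-detrended window
segment (detrending removes the tilt contributed by tails of neighbouring
bands), refined by parabolic interpolation through the three points around
it, and the spectrum is rolled by the integer number of grid points that
brings the apex onto the reference wavenumber; vacated edge points repeat
the edge value.  The sub-bin apex estimate matters: when the band centre
falls between grid points a plain argmax rule aliases into ±1-bin jitter on
perfectly aligned spectra, which measurably degrades the downstream
unmixing; with apex interpolation, aligned spectra stay untouched while
true integer drift is corrected exactly.  Windows with no interior local
maximum above the window median (flat or signal-free spectra) are left
unshifted and logged.

**Normalization and smoothing.**  Each spectrum is scaled to unit
trapezoidal area (idempotent, scale-invariant), then smoothed with an SG
filter of window 3 and order 1 — a centred three-point moving mean.
Because smoothing follows normalization, final areas are unity only up to
the smoother's edge effects (observed ≈ 1e−4).

Pipeline order: artifacts → baseline → calibration → normalization →
smoothing.  Baseline precedes calibration because apex detection is more
robust on background-free spectra; the order is configurable.

## Basis-restricted NMF

The processed matrix X (spectra × wavenumbers) is factorized as
X ≈ W·diag(A)·S with all factors non-negative, the rows of S fixed to the
reference library (free rows and per-sample group masks optional), under
the squared Frobenius loss with Lee–Seung-style multiplicative updates; A
is a diagonal scaling resolving none of the W/A scale ambiguity, which is
why all consumers use the effective score W·diag(A).  The objective is
recorded every iteration and is non-increasing; iteration stops at `n_iter`
(default 2000) or when the relative decrease falls below `tol` (1e−8).

Initialization: with S fixed the W-subproblem is convex and separable by
spectrum, so W is warm-started at the per-spectrum non-negative
least-squares solution (floored at 1e−12 so every component remains
revivable).  This is faster than a random start and avoids the zero-locking
local minima multiplicative updates are prone to; a seeded random
initialization remains available (`init="random"`), and with no fixed rows
and no mask the code path is ordinary NMF (verified against an
independently coded multiplicative-update loop).

On processed cohort spectra the relative reconstruction error is dominated
by residual fluorescence background that baseline subtraction leaves behind
(of order 10 % of the background range per spectrum), not by lack of
convergence; it is the main noise source limiting score recovery and
end-to-end accuracy.

## Sparse discriminant analysis

Optimal scoring: with Y the class indicator matrix and Θ score vectors
satisfying Θᵀ(YᵀY/n)Θ = I (orthogonal to the constant vector), alternate
(i) elastic-net regressions of YΘ on the standardized chemical scores —
ridge fixed at 1e−4, the L1 weight the tuned quantity — and (ii) a
Procrustes score update via SVD in the class-proportion metric, until the
coefficients stabilize (tol 1e−6, max 100 alternations).  The L1 weight is
bisected (budget 40 evaluations) until the union of the coefficient
supports across discriminant directions has exactly k = 8 variables; if the
support jumps past k at the bisection boundary the smallest superset is
trimmed to k by largest absolute coefficient and the model is flagged as
not exactly penalty-selected.  An unpenalized LDA is then refit on the
selected, standardized variables by the generalized eigenproblem
S_b v = λ S_w v (S_w ridge-stabilized), directions scaled to unit
within-class variance, giving at most (n_classes − 1) discriminants ordered
by explained between-class variance.  Classification is nearest class
centroid in LD space under the Mahalanobis metric of the pooled
within-class LD covariance; ties break toward the larger prior, then
lexical label order.  With k equal to the number of variables and balanced
classes the procedure reproduces ordinary LDA predictions exactly (tested
against an independent implementation).

## Clinical groupings

Gleason groups are labelled by the pattern sum (capped at 8 for this cohort
configuration, configurable).  CAPRA points follow the published UCSF
schedule — age < 50 → 0 else 1; PSA ≤ 6 → 0, ≤ 10 → 1, ≤ 20 → 2, ≤ 30 → 3,
else 4; Gleason primary 4/5 → 3, secondary 4/5 → 1, else 0; stage T3a → 1;
≥ 34 % positive cores → 1 — and band as 0–2 low, 3–5 medium, 6–10 high
(range and per-covariate monotonicity are verified by exhaustive grid
enumeration).  Ki67 is dichotomized at 3.5 %; the defining intervals are
open at the threshold, so an exact 3.5 % is assigned Low with a logged
warning.  The PSA median split uses one baseline value per patient
(earliest-listed biopsy); on the reference roster the median is 4.56 ng/mL.

## Validation

Random splits are spectrum-level (train and test may contain spectra of the
same biopsy, matching the reference protocol), 75/25 by count with the test
side floored, repeated 3× with different seeds; the mean and SD of overall
accuracy are reported, percentages rounded to the nearest integer alongside
full precision.  Leave-one-biopsy-out holds out all spectra of one biopsy;
the factorization, being unsupervised, is computed once and shared across
folds — only the discriminant model is retrained.  Threshold counts use a
closed bound (accuracy ≥ threshold), the only reading consistent with the
reference cohort's counts at its printed 60 % entry.

## Profile clustering

Biopsies are summarized by the arithmetic mean effective score of the
selected chemicals and clustered agglomeratively with Euclidean distance
and **average linkage** on per-chemical standardized columns — the
convention of clustergram tools, and necessary here: chemical scores span
orders of magnitude, and unstandardized distances are dominated by the
largest-scale chemicals.  Ward linkage (available via `method=`) weights
merges by cluster size, which makes the final merge of two compact groups
taller than a single outlier's attachment and thereby hides an
inverted-profile biopsy; under average linkage that biopsy attaches at the
greatest height, reproducing the reference dendrogram's structure.  "Least
similar" is read off the dendrogram as the leaf with the greatest
attachment height.  The pixel-chart matrix bins each chemical column
equal-width into 5 levels (min → 0, max → 4; constant columns map to the
middle level with a warning); equal-frequency binning is available.

## The synthetic cohort generator

The generator emulates the reference acquisition: 9 patients, 12
pre-treatment biopsies (clinical roster with the published ages, Gleason
patterns, CAPRA bands, % pattern 4, Ki67 and PSA values), 2–3 slices × 3
regions × 8×8 grids, wavenumber step 1 cm⁻¹ (coarser steps configurable),
with a per-biopsy spectrum inventory option matching the published counts
(total 3905).  T stage and % positive cores are not published, so they are
drawn by rejection sampling until the CAPRA points land in each biopsy's
published band.

Reference spectra are sums of 3–8 pseudo-Voigt bands (Gaussian/Lorentzian
mix 0.5, widths 5–25 cm⁻¹) with pairwise cosine similarity capped at 0.8;
the 14 chemicals named in the reference analyses head the library, a
phenylalanine entry carries the dominant, isolated 1003 cm⁻¹ calibration
band, and the remainder are numbered placeholders.  Base chemical weights
are log-normal (per-chemical means uniform in [0.5, 1.5], log-SD 0.3); the
biopsy's class adds `effect_size` (default 2) × the base score SD to the
scheme's discriminative chemicals, scaled by the class level (0…1).
Backgrounds are positive random degree-4 polynomials with amplitude 1–10×
the mean clean signal; Gaussian noise has SD 5 % of the clean-signal RMS
(≈ 26 dB SNR); cosmic rays are single-point spikes at 20–100× the signal
scale at a configurable rate; saturation clips runs of points at the
ceiling.  Every draw (true scores, backgrounds, artifact positions, class
labels, covariates) is recorded as ground truth.

The outlier biopsy (patient-99 analogue) keeps its Ki67-high label but gets
a mixed inverted signature: phospholipids at 3× the high-class level,
co-enzyme A and lactose depleted to ≈ 2 effect-sizes below baseline, amino
acids mildly depressed.  This reproduces the reference description
(phospholipids overexpressed, the co-enzyme A/lactose markers absent) and
its two observable consequences — leave-one-biopsy-out accuracy far below
50 % and the greatest attachment height in the dendrogram — without
poisoning the training set the way a wholesale sign inversion does.

**What the generator does not emulate:** within-grid spatial correlation,
tumour/stroma micro-heterogeneity, instrument line-shape and wavenumber
response, biopsy-level random effects beyond the class signature, and any
coupling between the three clinical groupings' spectral signatures (each
cohort plants signal on one scheme).  Passing tests therefore demonstrate
that the pipeline recovers the structure this model generates — they do not
certify the reference cohort's patient-level accuracies, which cannot be
recomputed without the undeposited spectra.

## Problem sizes and evaluation conditions

The acceptance evaluation treats the 31-chemical reference library as a
fixed study input (the generator's default draw); cohorts, noise, artifacts
and splits derive from the external seed.  End-to-end classification runs
on cohorts of 100 spectra per biopsy (1200 spectra) at the native 1 cm⁻¹
step for the clean cohort and 60 per biopsy for the outlier variant; unit
tests use a 2 cm⁻¹ step and smaller cohorts.  Score recovery is measured on
500-spectrum mixture cohorts at the generator's default noise level
(≈ 26 dB, within the ≥ 20 dB regime the recovery property targets); near
20 dB exactly, the worst-conditioned chemicals approach the information
limit of the library — the exact per-spectrum NNLS solution itself drops to
r ≈ 0.8–0.9 for them — so recovery claims should always be read against the
library's conditioning.  Baseline recovery is scored on sparse-peak spectra
with known polynomial backgrounds, RMS over peak-free regions (> 40 cm⁻¹
from any band centre) as a percentage of the background amplitude.

## Known limitations

- End-to-end accuracy depends visibly on the conditioning of the reference
  library; randomly re-drawn libraries span roughly 85–95 % held-out
  accuracy under otherwise identical conditions.
- The residual fluorescence background after iterative SG subtraction
  (~10 % of the background range) is the dominant noise term in the
  chemical scores; methods that co-estimate background and composition
  would likely improve on the two-stage chain but are out of scope.
- Area normalization couples all chemical scores (closure effect): a real
  increase in one chemical depresses all others' relative scores.  The
  classifier operates on, and the reported accuracies refer to, these
  relative scores.
- Integer-grid calibration cannot correct sub-bin drift; at the native
  1 cm⁻¹ step this bounds residual misalignment at half a wavenumber.
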