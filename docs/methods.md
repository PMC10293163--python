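# Methods

`amyeeg` implements a quantitative-EEG (QEEG) screening pipeline for brain
amyloid pathology in pre-dementia populations (subjective cognitive decline,
SCD, and mild cognitive impairment, MCI): resting-state eyes-closed EEG is
reduced to spectral and connectivity features, standardized against an
age/sex normative database, filtered for amyloid-specific features, and fed
into a grid of feature-set x classifier combinations whose winner is scored
once on an untouched held-out set.  Because clinical recordings with PET
ground truth are not redistributable, the package ships a synthetic cohort
generator that reproduces the statistical structure the analysis assumes;
every stage is exercised end to end on simulated data.

## Signal model of the synthetic generator

Each 19-channel recording (10-20 montage, 200/250 Hz, default 180 s) is a
sum of four components, in microvolts:

1. **Background**: Gaussian `1/f^chi` noise (default `chi = 1`, std 5 uV).
2. **Band oscillators**: one band-limited Gaussian process per analysis band
   (delta 1-4, theta 4-8, alpha1 8-10, alpha2 10-12, beta1 12-15, beta2
   15-20, beta3 20-30, gamma 30-45 Hz), scaled per channel by a gain grid
   (19 x 8, unit gain = 2 uV std).  Background and oscillators are realized
   in a single frequency-domain pass: a white Gaussian spectrum is shaped by
   the square root of the summed target power response.  This is the same
   Gaussian family as time-domain band filtering at a fraction of the cost;
   per-band realized power fluctuates around its target with relative SD
   `sqrt(2/n_bins)` (a few percent at 180 s).
3. **Lagged shared sources**: narrowband sources added to channel pairs with
   a phase lag, injecting genuine imaginary coherence (defaults: posterior
   alpha O1-O2/P3-P4, central beta1 C3-C4, frontal theta F3-F4).
4. **Artifacts**: frontally-weighted biphasic blinks (0.3-0.5 s, 160 uV,
   default 2/min — eyes-closed recordings blink rarely), EMG bursts
   (0.5-2 s of >20 Hz noise on temporal channels, 1/min) and mains
   interference (60 Hz sinusoid, 1 uV).

**Physiology knobs.** Theta gain rises linearly with age (+0.01 gain/yr,
referenced to 65) and the alpha peak slows (-0.03 Hz/yr), shifting
oscillatory mass from alpha2 toward alpha1; females get a 5 % alpha boost.
These give the normative z-scoring a real effect to remove.  Inter-subject
variability is a lognormal jitter (sigma 0.20) on every gain.

**Amyloid signature.** Positive subjects receive `+delta_theta` on the
theta gain of nine frontal/frontotemporal channels and `-delta_beta2` on
the beta2 gain of six centroparietal channels; both increments are
multiplied by `mci_multiplier` for MCI subjects.  Defaults
`delta_theta = 0.35`, `delta_beta2 = 0.20`, `mci_multiplier = 1.5` were
fixed once after a pilot simulation confirming they support held-out
accuracy >= 0.8 at study scale; with both deltas zero the cohort is
exchangeable across amyloid labels, which the null-calibration tests rely
on.

**What the generator does not model**: volume conduction and realistic
source geometry (couplings are injected directly at the sensor level),
non-stationarity beyond scheduled artifacts, institutional/equipment
effects, medication or APOE status.  Passing tests therefore demonstrate
that the *pipeline machinery* recovers planted effects of plausible size —
not that real amyloid pathology is detectable at these accuracies.

## Preprocessing

Fixed order: resample to 250 Hz (polyphase) -> zero-phase Butterworth
bandpass (nominal 1-45.5 Hz) with mains notch (Q = 30; skipped with a
warning when the line frequency lies outside the passband, where the
bandpass already suppresses it) -> common-average reference -> 4-s epochs
(0.25 Hz spectral resolution at 250 Hz) -> amplitude/variance bad-epoch
rejection (100 uV peak, 5x median channel variance) -> ocular/EMG removal.

The rejector and the ocular cleaners (least-squares regression on a <4 Hz
Fp1/Fp2 proxy, or FastICA with |r| > 0.7 proxy-correlation / > 0.7
high-frequency-fraction component rules) are deliberately simple, documented
stand-ins for heavyweight published artifact pipelines; the analysis does
not depend on their internals.

Numerical choices worth knowing:

* **Filter margins.** The Butterworth -3 dB point sits *at* the cutoff and
  zero-phase application squares the response, so cutoffs placed exactly at
  1 and 45.5 Hz would attenuate the outermost delta and gamma bins 2-4x.
  Cutoffs are therefore designed at `low/2` and `high * 1.1`; the
  attenuation contracts (>= 20 dB below 1 Hz, <= 1 dB mid-band) still hold.
* **Band-power stability.** On a clean recording the chain excluding CAR
  moves relative band powers by < 0.02 absolute; CAR adds up to ~0.01 more
  because subtracting the channel average genuinely redistributes power
  when posterior alpha is strong.  The full-chain guarantee is 0.03.
* **Epoch budget.** Spectra are averaged over a fixed number of epochs per
  subject (default `0.6 * floor(duration/2 / 4 s)`, i.e. 13 epochs at
  180 s).  The imaginary-coherence estimator carries a positive
  finite-sample bias of order `sqrt(1/(pi * n_epochs))`; without a fixed
  budget, the half-recordings created by positive-class augmentation would
  differ from whole recordings on *every* coherence feature, and classifiers
  learn segment length instead of pathology (cross-validation accuracy near
  1.0 with chance-level held-out sensitivity).  The budget is applied
  identically to normative, training (wholes and halves) and validation
  subjects.

## Features

Per 4-s Hann-tapered epoch, the cross-spectrum `S_ij(f) = <x_i(f) x_j*(f)>`
is averaged across epochs on the 0.25 Hz grid (one-sided density scaling;
Parseval holds within 1 %).  Two feature families, 1,520 named values:

* **Relative band power** `rp_<CH>_<BAND>` (152): band-integrated PSD
  divided by the channel's total over the eight bands; rows sum to 1.
* **Imaginary coherence** `ic_<CH1>-<CH2>_<BAND>` (1,368): with coherency
  `C_ij(f) = S_ij / sqrt(S_ii S_jj)`, the band value is the unweighted mean
  of `|Im C_ij(f)|` over the band's bins.  The imaginary part is blind to
  zero-lag mixing, so a duplicated channel scores exactly 0.  Values lie in
  [0, 1] and are symmetric in the pair.

Band edges follow the `[low, high)` convention with gamma closed at 45 Hz,
so touching band edges never share bins.  A rectangular taper is available
for oracle comparisons against a direct-DFT reference.

## Normative z-scoring

Per (sex x age-bin) stratum of the healthy cohort, per-feature mean and SD
(n-1 denominator; SDs below 1e-6 floored, with a warning, to keep the
feature count fixed).  Study subjects are standardized against their own
stratum: `z = (x - mu)/sigma`.  Lookup is nearest-bin only; bins default to
the generator's 10-year cells and are configurable.  Standardization is
applied *before* feature selection, so all selection operates on z-scores.

## Feature selection and confound exclusion

Six candidate sets for the amyloid-positive vs -negative contrast:

* Welch two-sample t-test and Mann-Whitney rank-sum (p < 0.05, capped at
  the 50 smallest p; constant features get p = 1).  The unequal,
  independent groups make a paired design impossible, so the two-sample
  Welch form is used.
* Elastic-net logistic regression (l1_ratio 0.5, C chosen from {0.01, 0.1,
  1} by internal 3-fold CV), features with nonzero coefficients ordered by
  |coefficient|.
* Random-forest, gradient-boosting and XGBoost importances (top 50, nonzero
  only; impurity/gain importances respectively).

The same six methods are then run on the SCD-vs-MCI contrast (ignoring
amyloid); the union of those sets is the cognitive-impairment confound set
and is removed from every amyloid set, order preserved.  No multiple-testing
correction is applied by default (matching the raw-threshold selection
style); a normality-gated correlation diagnostic (Pearson when both vectors
pass Shapiro-Wilk *or* Kolmogorov-Smirnov at p > 0.05, Spearman otherwise)
is provided as a standalone report, not a selection gate.

## Model grid, augmentation and gating

The amyloid classes are imbalanced (~1:2.5), so every positive *training*
recording is split into its first and second halves; features are
recomputed per half and the two halves replace the whole (doubling the
positive class).  Validation subjects are never augmented.

Each of the six feature sets is crossed with eight classifiers — SVM (RBF),
logistic regression, k-nearest neighbours, Gaussian naive Bayes, random
forest, AdaBoost, gradient boosting, XGBoost — giving 48 cells.  Library
defaults with fixed seeds throughout, with one exception: XGBoost uses
`tree_method="exact"` because histogram binning can place split thresholds
at a class cluster's edge rather than mid-gap at these sample sizes.
Five-fold cross-validation is stratified by label and *grouped by origin
subject*, so the two halves of one subject always share a fold (splitting
them would leak subject identity).  Cells whose CV accuracy clears the gate
(default 0.75) are refitted on all training samples and scored once on the
held-out set; candidates are ranked by validation accuracy, ties broken by
sensitivity and then smaller feature set.  Classifier scores are predicted
probabilities (min-max-scaled decision-function values for margin
classifiers); a sensitivity-targeted cut-off tuner picks, among midpoint
thresholds, the one with the highest specificity subject to the target.

A note on the null calibration: with no injected effect, the *validation
accuracy of the CV-selected cell* is the chance-level quantity (mean 0.5
over seeds).  Taking the maximum of the 48 cells' validation accuracies
would itself be max-selection bias — exactly the optimism the calibration
is meant to detect.

## Evaluation

Confusion counts (positive class = amyloid-positive), sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), accuracy, reported as fractions and
as one-decimal percentages with round-half-up (clinical-table convention);
a zero-denominator metric is reported as undefined, never 0.  ROC by
sweeping all distinct scores with simultaneous tie steps, AUC by trapezoid
(equal to the normalized Mann-Whitney U on tie-free data).  Reports are
produced overall and per diagnosis subgroup, whose confusion counts sum
cell-wise to the combined table.  Scalp topography is exported numerically:
per channel x band, group means, difference, Welch t and p for four
contrasts (amyloid within SCD, within MCI, overall, and diagnosis within
amyloid-positive).

## Determinism and problem sizes

A single master seed fans out to per-stage seeds through
`SeedSequence([master, stage_index])`; every generator, selector and
classifier is seeded, and rerunning a configuration reproduces the report
byte-for-byte.  The default study conditions are the four-stratum cohort
36/160/54/61 (311 subjects, 180 s at 250 Hz, 76 held out as 13/24/20/19)
with a 200-subject normative cohort (2 sexes x 5 ten-year bins x 20).  The
test suite exercises the same pipeline at reduced sizes chosen as the
package's own smoke profiles (60-120 subjects at 60 s; 10-seed null panel),
which keeps the planted effects detectable while the full-size run remains
the acceptance configuration.

## Known limitations

* EDF files can be read (channel labels are normalized across vendor
  decorations) but recordings are written as CSV matrix + JSON sidecar;
  no EDF writer is bundled.
* ICA-based ocular cleaning assumes artifact components are non-Gaussian
  and high-amplitude; on largely Gaussian data FastICA's rotation of the
  noise subspace is arbitrary (harmless for back-projection).
* The confound-exclusion rule (union across six methods) is aggressive;
  with strongly diagnosis-correlated amyloid effects it can empty a
  feature set, which the grid then scores as a flagged majority-class cell.
* Nested (per-fold) feature selection is deliberately out of scope;
  selection happens once on the training pool, mirroring the reference
  analysis design.
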