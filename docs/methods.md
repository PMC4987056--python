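# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a statistical-methods appendix. Everything
quantitative stated here is computed by the test suite or the acceptance
script; nothing is asserted from memory.

## Study design emulated by the generator

The synthetic cohort mirrors a resuscitation experiment on newborn pigs:
six protocol groups (n = 21/32/21/8/16/12) differing in oxygen fraction
(0.21 or 1.0), initial ventilation (30/60/90 s) and compression:ventilation
ratio (3:1, 9:3, 15:2), with plasma and urine sampled at baseline (t1) and
2 h (t2) / 4 h (t3) after return of spontaneous circulation (ROSC).
Per-group sample availability at each time point reproduces the published
counts as Bernoulli rates; animals have log-normal times to asystole and
to ROSC drawn from the published per-group median/IQR. The time-to-
asystole unit is stored with the data: the published footnote says
seconds, but the asphyxiation protocol (ventilator rate reduced every
10 min) implies the printed values of 28–37 are minutes; the generator
defaults to minutes and leaves the unit configurable rather than guessing
intent. Survival is Bernoulli(0.85) per animal (no per-group rates are
published); non-survivors contribute no t2/t3 samples.

## Concentration model

For every metabolite the baseline (first sampled time point) marginal is
log-normal with `mu = ln(median)` and `sigma = ln(q3/q1) / (2 z_0.75)`
moment-matched to the published median and IQR. Two degenerate cases are
handled explicitly: a printed lower quartile of zero (the scale is then
taken from the upper half-spread, `sigma = ln(q3/median)/z_0.75`) and a
zero-width IQR (`sigma = 0`). Where a printed IQR is not log-symmetric
about its median (e.g. plasma succinate), no log-normal can match the
median and both quartile positions; the fit preserves the median and the
IQR *ratio* exactly, which shifts the individual quartiles by up to
~10 % for the most asymmetric rows.

Later time points are built multiplicatively within animal:
`c(t+1) = c(t) · ratio(FC) · exp(noise)`, where signed fold changes follow
the field convention (−2 means a factor 1/2) and the log-scale innovation
sd defaults to 0.25 — a moderate within-animal reproducibility chosen once
as realistic for repeated biofluid sampling; the paper publishes only
marginal summaries, so the true within-animal correlation is not
recoverable. A consequence of this construction is that the *paired* fold
change is exact by design while the marginal t2/t3 medians equal
`median(t1) × ratio` rather than the independently printed t2/t3 medians
(which encode the real data's imperfect t1–t2 coupling).

Optional structure, all Gaussian-copula based: correlation clusters
(default: the hypoxia-responsive metabolites — lactate, pyruvate,
succinate, fumarate, alanine, glucose, hypoxanthine — share a latent
factor with rho = 0.5), correlations of baseline metabolites with the
(log) time to asystole (default: hypoxanthine r = −0.23), a per-animal
TSP-broadening factor (log-normal, median 1.57 and sigma 0.63, fitted so
that broadening × a 0.003-ppm natural linewidth reproduces the published
plasma TSP-FWHM median/IQR; correlated with time to asystole at r = −0.26
as a lipoprotein proxy), and a per-urine-sample dilution factor
(log-normal, sd 0.5) that creatinine normalization must remove.

## Spectral forward model

Spectra live on a uniform ppm grid (default −1…10 ppm, 16384 points).
Each panel signal is a Lorentzian multiplet (singlet/doublet/triplet, or a
five-line 1:2:3:2:1 "multiplet"; J defaults 0.012/0.011/0.006 ppm) whose
total absorptive area is `concentration × protons` in units where the TSP
singlet (9 protons at 0.5 mM — the reference concentration is arbitrary
since only ratios matter) carries area 4.5. Natural linewidth is
0.003 ppm FWHM; the TSP line is additionally broadened by the per-animal
factor. Nuisances: a zero-order phase error (sd 10°), a global
referencing offset (sd 0.005 ppm), a log-normal receiver gain (sd 0.3), a
linear baseline tilt, complex white noise (sd 0.2 intensity units), a
presaturated water remnant at 4.70 ppm, and material backgrounds —
plasma: lipoprotein CH3/CH2 Gaussian bands at 0.89/1.28 ppm
(sigma 0.08 ppm, areas 20/30 scaled by the broadening factor) plus a
macromolecule hump (2.2 ppm, sigma 1.0, area 60); urine: a urea band at
5.8 ppm. Band widths and amplitudes were set once so that the lipid
envelope dominates the aliphatic region at baseline (as in real plasma)
while remaining a *smooth* background — bands much narrower than ~25
linewidths are physically unlike lipoprotein envelopes and cannot be
separated from metabolite signals by any baseline method.

What the generator does **not** emulate: pH-dependent chemical-shift
drift (EDTA/citrate), J-coupling fine structure beyond the three stock
patterns, peak-position jitter between samples, T2/shimming variation of
the metabolite linewidth, and spectrometer raw (FID) acquisition. Passing
tests therefore demonstrate correctness of the analysis chain under this
idealization, not instrument-grade robustness.

## Preprocessing

The standard order is fixed: phase → linear baselines → referencing →
clip → TSP normalization → TSP FWHM → adaptive baseline → excision.

* **Phase.** The zero-order angle maximizing the TSP real-part height is
  computed as the argument of the complex integral over a ±0.03-ppm
  window symmetric about the apex of the (phase-invariant) magnitude
  spectrum, after removing a collar-estimated local complex offset.
  This is algebraically the height-maximizing rotation for a Lorentzian
  but immune to the ~10° bias the naive sampled-height criterion suffers
  when the peak center falls between grid points. Recovery is within
  0.5° and idempotent.
* **Linear baselines.** One straight line per side of the water artifact,
  fitted to per-chunk lowest-decile support points by quantile regression
  (tau = 0.25). Quantile loss is essential: a least-squares or
  asymmetric-IRLS line is dragged by the macromolecule hump (IRLS can
  oscillate between envelope and mean solutions).
* **Referencing.** Plasma anchors on the glucose anomeric doublet: the
  renderer centers it at the published 5.24 ppm, so the low-ppm line sits
  at 5.234 ≈ the study's "5.23"; detection is doublet-aware (two
  near-equal maxima one J apart → take the low-ppm line) because
  proximity tie-breaking mis-anchors whenever the offset exceeds J/2.
  Urine anchors on TSP at 0.0 ppm.
* **TSP normalization and FWHM.** The TSP area is a trapezoidal integral
  over ±10 measured FWHM (capped at ±0.1 ppm for heavily broadened
  peaks) above a collar-estimated local floor; the analytically known
  captured-tail fraction is stored so quantification can refer to the
  full Lorentzian area. FWHM uses linearly interpolated half-height
  crossings.
* **Adaptive baseline.** Iterative asymmetric penalized smoothing
  (second-difference penalty, lam = 3e4 grid-index units ≈ 0.009-ppm
  stiffness) with three weight zones per iteration: ~0 above one noise-sd
  of the current baseline (peaks), 1/2 inside the noise band (so the
  baseline runs through the noise *middle* — a pure lower-envelope
  estimate biases every small integral up by ~2 noise sd), and ~1 below.
  Stretches known to contain panel signals are bridged (peak-side weight
  only), which lets the estimate track lipid bands underneath crowded
  multiplet regions without climbing into the peaks. lam and the
  asymmetry p = 3e-4 were chosen by scanning against the package's own
  recovery contracts (noiseless ≤ 1 %, noisy median ≤ 10 %).
* **Excision** (water 4.55–4.95 ppm, TSP ±0.2 ppm, urine urea
  5.5–6.1 ppm) is applied last and feeds the multivariate layer;
  quantification reads the pre-excision spectrum because published urine
  signals at 4.52, 5.48 and 5.70 ppm fall inside or against the deleted
  regions.

## Quantification

Windows are the panel position ± (multiplet half-span + 2 FWHM),
truncated at neighbour midpoints. Each trapezoidal integral is corrected
by (i) a flat local floor estimated from 1–4-FWHM collars outside the
window (only on sides free of other windows) — this removes whatever
smooth band residue the adaptive baseline left, and converts the
broadening-correlated lactate bias (up to +15 % in heavy-lipid animals)
into an essentially unbiased estimate — and (ii) the analytic Lorentzian
capture fraction of the window, with the peak's own wing level at the
floor anchor deducted. Concentrations follow
`c = (A/protons)/(A_TSP/9) × c_TSP` against the full-Lorentzian TSP area.
Unidentified signals carry arbitrary units (nominal one proton) and are
excluded from mM-level claims.

Accuracy on the default synthetic plasma cohort: noiseless,
well-separated signals recover within 1 %; with full noise and
backgrounds the median absolute relative error over identified
metabolites is ≈ 2 % per cohort. Signals overlapping within ~0.03 ppm
(succinate/pyruvate, creatinine/myo-inositol, malate/methionine) and the
BCAA region riding the lipid CH3 band (leucine worst) remain
individually poor — an inherent limit of windowed integration without
deconvolution, shared with the area-based method it implements.

## Multivariate statistics

PLS uses sequential NIPALS extraction with X- and Y-deflation; PLS-DA
dummy-codes classes and centers. Segment-wise cross-validation splits a
(repetition-specific) random ordering into 7 contiguous segments;
scaling is refit inside every training fold; Q² = 1 − PRESS/TSS with TSS
against training means. Held-out class assignment is nearest dummy
target (midpoint threshold for two classes). NMC is summarized over
repeated CV (median, 2.5–97.5 percentiles) and compared with a
permuted-label null (one CV repetition per permutation). Two p-values
are reported and labeled: the empirical exceedance
`p = (1 + #{null ≤ observed median})/(nperm + 1)`, whose resolution is
bounded by the permutation count — empirical permutation p-values below
~1/nperm are unobtainable, so astronomically small published values must
come from a parametric comparison — and a Wilcoxon rank-sum p comparing
the observed-repetition and null NMC distributions, which can be very
small when both distributions are tight. Component count defaults to
the smallest achieving the maximal cross-validated Q². Comparing a
median of many repetitions against single-repetition nulls is slightly
conservative; with one observed repetition the empirical p is exactly
exchangeable (type-I error 0.04–0.05 at nominal 0.05 in the calibration
suite).

## Univariate statistics and correlation structure

Concentrations are natural-log transformed with zeros replaced by half
the smallest positive value per metabolite (the published tables contain
zero quartiles, so zeros must be representable). Fold changes are
`exp(mean within-animal log difference)`, reported signed; paired
t-tests give p, Benjamini–Hochberg within-table gives q. Welch tests
are the default for unpaired comparisons. Correlation matrices are
pairwise-complete Pearson with per-cell n; variables with fewer than 5
complete pairs against the rest are dropped greedily (worst first), as
are zero-variance variables (creatinine after normalization).
Hierarchical clustering uses average linkage on the signed distance
1 − r: signed, because inverse plasma–urine correlations are a finding
of interest and should separate, not cluster.

## Problem sizes

Desk-scale defaults used throughout the tests and the acceptance script:
100-animal cohorts for recovery and fold-change checks (matching the
study's per-time-point sample counts), 16384-point spectra, 200
simulations for calibration suites, and 10 seeds for the null-contrast
mirror. These sizes give Monte-Carlo error comfortably below the
tolerances they are tested against; the dominant uncertainty in the
cohort-median targets is the genuine sampling variability of a
100-animal median (≈ 12 % sd for lactate, ≈ 7 % for glucose, given the
published between-animal spreads).
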