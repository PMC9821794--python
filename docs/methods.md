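# Methods

## The problem and the modelling strategy

The task is to recognize fresh (legally marketable) saffron, detect blending
with expired stigmas down to 10 % (w/w), and quantify the blend level, all
from ATR-FTIR pseudo-absorbance fingerprints (Log 1/R, 4000–500 cm⁻¹ at
4 cm⁻¹, 876 variables). Because the real spectra are not publicly
distributable, the package pairs the analysis pipeline with a synthetic-data
generator that emulates the study's sampling design; the pipeline itself is
agnostic to where the spectra come from and reads the same CSV layout it
writes.

## Synthetic spectra

Each endpoint material (fresh 2020; expired 2016; expired 2018) is a sum of
18 Gaussian bands at the assigned saffron wavenumbers (O–H and C–H
stretches, carbonyl shoulders at 1745/1710 cm⁻¹, conjugated C=C, the
ester/aromatic 1578/1545 cm⁻¹ pair, the glycosidic/sugar fingerprint at
1221–1020 cm⁻¹, trans/cis =C–H bending). Aging acts multiplicatively per
band: hydrolysis depletes the crocin/picrocrocin glycosidic and ester bands
(factors 0.25–0.60 for the 2016 material), free aldehydes and acids grow the
carbonyl shoulders (×2.0–2.2), and moisture loss lowers the broad O–H band.

Aging magnitudes are generator choices; the study-level facts they encode
are the direction of each change and the near-perfect multivariate
discriminability of the classes. Two conventions are worth stating:

- The 2016 material is five years old at analysis time, the 2018 material
  three. Degradation is modelled as fast-early/slow-late (crocin-like
  kinetics): each 2018 aging multiplier is the 2016 one raised to the power
  0.75.
- The 2018 harvest additionally carries a vintage direction of its own
  (stronger O–H/C–H/trans =C–H bands, slightly weaker fingerprint,
  consistent with an unusually high-quality harvest), so vintage and aging
  are linearly independent spectral axes — without this, the two expired
  classes would differ only in aging magnitude.

Adulterated samples are convex combinations of the fresh and expired
profiles, linear in the mass fraction α (Beer–Lambert additivity for a
powder blend). Artifacts then break exact linearity the way real ATR data
do. Per batch, one multiplicative jitter ~N(1, 0.02) per band emulates
compositional batch-to-batch variation; per replicate, a scatter factor
~N(1, 0.05), a baseline offset ~U(0, 0.05), a baseline slope ~U(−2·10⁻⁵,
2·10⁻⁵) per cm⁻¹ and white noise with σ = 0.005 absorbance are applied.
Band amplitudes (0.28–1.44 peak pseudo-absorbance) are set high in absolute
terms so that this fixed noise floor corresponds to a realistic ~0.3–0.5 %
relative noise for a ten-scan FTIR average.

The default design follows the study: five compliant batches of 22–23
replicate analyses (112 total), and for each vintage two batches of pure
expired stigmas (20) plus three batches of ~10 replicates at each of
40/25/10 % — 112 samples for 2016, 110 for 2018, 334 in all. Everything is
drawn from one seeded RNG stream, so a dataset is a pure function of its
configuration.

## Pre-treatments

SNV standardizes each spectrum to mean 0, sd 1 (n−1 denominator), removing
additive offsets and multiplicative scatter exactly. D1 is a Savitzky–Golay
first derivative (quadratic polynomial, 9-point window, scaled by the
4 cm⁻¹ step; edge points from the one-sided fits), chosen over simple
differencing because it does not amplify high-frequency noise and preserves
the axis length. MC subtracts per-wavenumber column means learned from the
training block only; it is constrained to appear at most once and last in a
chain, which is what makes prediction with stored centering statistics
well-defined.

## PLS and PLS-DA

The regression engine is NIPALS with deflation of both blocks. Per
component the iteration starts from the deflated-Y column of largest
variance, stops when the weight vector's relative change falls below 1e-10
(cap 500 iterations), and flips each weight vector so its largest-magnitude
entry is positive (a reproducible sign convention). Y-loadings are the
regression of the deflated Y on each score, so the direct coefficient
matrix B = W(P′W)⁻¹Q′ reproduces the accumulated-deflation predictions to
numerical precision — an identity asserted in the tests. X and Y are
centered internally and never variance-scaled (the spectra are already on a
common scale after the chain).

Classification dummy-codes the classes and regresses the binary matrix by
the same engine. The assignment rule fits, for each class column, one
Gaussian to the in-class calibration responses and one to all remaining
calibration responses (maximum-likelihood mean and n−1 sd). The threshold
solves the density-equality quadratic, taking the root between the two
means — the only root that acts as a decision boundary; with equal sds this
is the midpoint. The posterior of a response is f_in/(f_in + f_out), a
sigmoid of the log-density difference (numerically stable via `expit`), and
a class accepts a sample when the posterior exceeds 0.5 — unless the
response exceeds the class's largest calibration response, where the
posterior would be an extrapolation and the class refuses. Densities are
unweighted by default, matching two normalized probability curves crossing
at 50 %; frequency-weighted priors are available behind a flag. Empty and
multi-class attribution sets are legitimate outcomes, and the metrics
distinguish them: sensitivity counts "set contains the true class", CCR
counts "set is exactly the true class", specificity counts "set excludes
the wrong class".

Degenerate case worth noting: with overlapping groups and a wider in-class
than out-of-class Gaussian the densities may not cross between the means at
all. Direct rule fitting raises; during cross-validation such a (chain, LV)
candidate is simply dropped from the grid, since a rule that cannot be
fitted cannot be selected.

## VIP

VIPⱼ = √( p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ) with SSYₐ = (tₐ′tₐ)·Σₘ qₐₘ².
For multi-response models SSY sums the squared Y-loadings across responses.
Σⱼ VIPⱼ² = p identically, so the mean squared score is 1 and scores ≥ 1
flag significant variables.

## Splitting and model selection

Duplex (Snee): within each stratum, the two mutually farthest samples seed
the training set, the two farthest remaining seed the test set, and
remaining samples are assigned alternately, each time the candidate with
the largest minimum Euclidean distance to the receiving set; the test set
is capped at ⌈0.3 n⌉ and training absorbs the rest. Ties break to the
lowest row index, which makes the split deterministic and permutation-
invariant. Distances are computed on SNV-treated spectra so baseline and
scatter do not drive representativeness. Strata are classes for the
discriminant models and adulteration levels for the regressions.

Selection runs a stratified, seeded 5-fold CV on the training set over the
chain candidates (SNV+MC and D1+SNV+MC) and LV counts 1–20 (capped by the
fold rank bound). The classification metric is the mean CCR of the pooled
fold-wise attributions; the regression metric is RMSECV over all held-out
predictions. Ties prefer fewer latent variables, then the shorter chain.
Fold-wise, the chain's MC means and the PLS centering are re-fitted on the
in-fold training part only. Q² = 1 − PRESS/TSS with TSS about the training
mean.

## Experiment subsetting rules

- Freshness model (Model I): pure materials only (α = 0 or 1), three
  classes by vintage.
- Compliance screen (Model II): all 334 samples; the adulterated classes
  span 10–100 %. Reported through the compliant class's external
  sensitivity and specificity.
- Regression: per vintage, compliant samples plus that vintage's 10/25/40 %
  mixtures; the 100 % samples are excluded (extending the calibration range
  to 0–100 % demonstrably worsens CV performance), and the response is α in
  percent so RMSE values read directly as % (w/w).

## What the synthetic data does and does not show

Passing tests on this generator demonstrate that the pipeline is correct,
leak-free and sensitive enough to recover the designed class structure at
the designed noise levels; they do not certify performance on real spectra,
whose within-class covariance is richer than Gaussian bands with
independent per-band jitter. Two specific caveats:

- Replicates share their batch's jitter draw, and batches are nested within
  classes, so a flexible model can partly substitute batch fingerprints for
  class signatures (visible when the two expired endmembers are made
  identical: only disabling batch jitter as well collapses their
  separability). Real designs have the same confound.
- The screen's hard cases are whole batches of low-level (10 %) mixtures
  whose jitter draw points toward the compliant class; across generator
  seeds the compliant-class external sensitivity/specificity sit at 100 %
  for most seeds and in the 91–99 % range otherwise. The acceptance script
  reports whatever the requested seed produces; nothing is tuned per seed.

Runtime scales: every experiment runs in seconds on one CPU (334 × 876
matrix, ≤ 2 × 20 × 5 NIPALS fits per selection), which is the intended
scale for the test suite and the acceptance script.
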