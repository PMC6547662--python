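# Methods

## The calibration problem

A foliar NIRS calibration maps an absorbance spectrum A(λ) = log₁₀(1/R(λ)),
measured on dried, milled and pressed leaf material over 350–2500 nm, to a
constituent content y (N, P or C, in % dry weight) via a linear model fitted
against reference chemical analyses. The workflow implemented here is the
standard chemometric sequence: wavelength masking → preprocessing-recipe
search → spectral outlier removal → representative calibration/validation
split → cross-validated PLS with parsimonious component selection → a single
external validation → optional transfer to new sample populations and
precision assessment.

## Data model and masking

Spectra live on an integer-nm grid; masked wavelengths stay in storage but are
excluded from every computation, so masks are reversible. The default
exclusion set removes the sensor-overlap windows 350–380, 760–840, 1700–1800
and 2450–2500 nm and the visible region 380–720 nm, all intervals closed at
both ends (the listed interval endpoints overlap at 380 nm; closing both ends
makes the retained count reproducible: exactly 1547 of the 2151 grid points
remain, in 721–759 ∪ 841–1699 ∪ 1801–2449 nm). Native-resolution instrument
output (≈1.4 nm below 1050 nm, 2 nm above) is linearly interpolated to 1 nm.
Replicate scans are averaged arithmetically per wavelength; averaging and
masking commute.

## Preprocessing

Per-spectrum operators need no fitting and cannot leak information across
samples: SNV (per-spectrum standardisation with the n−1 SD), moving averages
with truncated edges, an endpoint-anchored linear detrend per contiguous
retained segment as the baseline correction (one of several dialects in use;
chosen for reproducibility and exposed as a configurable step), and
Savitzky–Golay derivatives (scipy coefficients, per-nm scale). Derivatives and
smoothers never bridge a masked gap; SG edge points where the full window does
not fit are dropped from the retained set, avoiding edge-polynomial dialect
differences. Per-wavelength centering and scaling are *fitted* statistics:
estimated on the calibration subset only and reused verbatim for validation
and prediction data.

The default search grid crosses {none, SNV, baseline} × {none, MA(5), MA(11)}
× {none, SG1(11,2), SG2(11,2)} — 27 recipes covering every operator family —
followed by centering (performed inside the PLS fit). Window and polynomial
orders are package defaults; they are deliberately small and fixed rather
than searched.

## Outlier screening and splitting

Because p ≫ n makes the spectral covariance singular, Mahalanobis distances
are computed in the space of leading principal components — the smallest
number explaining ≥ 99 % of variance, capped at 10 because noise-dominated
trailing components make the chi-square reference unstable. The threshold is
√χ²₁₋α(m) with α = 0.01 by default. Screening runs per recipe (preprocessing
changes the spectral space) and *before* splitting; otherwise extreme spectra
are guaranteed Kennard–Stone calibration members.

Kennard–Stone then selects round(0.85·n) calibration samples (round-half-up):
the most distant pair first, then greedy maximin distance, ties broken toward
the lowest input index so the split is deterministic.

## PLS, cross-validation and selection

NIPALS PLS1 on column-centered X and centered y, with deflation after each
component; coefficients B = W(P′W)⁻¹q. Predicting the training-mean spectrum
returns the training-mean content by construction, and with k equal to the
rank of centered X the fit coincides with ordinary least squares (both are
regression-tested, the latter against a normal-equations oracle and
scikit-learn's PLSRegression as an independent cross-check).

Cross-validation uses seeded random folds (default seed 20190604, mandatory
in the config) of near-equal size; an optional grouping argument keeps
replicate rows of one sample in the same fold. Everything that can leak —
centering/scaling statistics and the PLS decomposition — is refitted inside
each fold; per-spectrum transforms are row-wise and applied once. RMSECV is
computed for every k up to k_max = min(25, n_cal/3) in a single NIPALS pass
per fold. The parsimony rule is quantitative: the smallest k whose RMSECV is
within 2 % of the minimum over k. Recipe selection minimises RMSECV at the
selected k (ties: fewer components, then earlier grid order); the external
validation subset is never touched by any fitting or selection step, which is
asserted structurally on every run.

## Validation and precision statistics

The external panel reports RMSEP = √mean(ŷ−y)², bias = mean(ŷ−y), the
intercept and slope of the least-squares line of predicted on measured, and
R² as the squared Pearson correlation (the common chemometric convention; the
1−SSE/SST variant is available behind a flag). Sample (n−1) SDs are used
throughout; rmsep² = bias² + (n−1)/n·SD²(error) holds as an identity.

Within-laboratory precision predicts each replicate scan separately, takes the
per-sample RSD (100·SD/mean) of those predictions, and averages across
samples. The AOAC acceptance ceiling is RSD_accepted = 2·C^(−0.15) in percent
with C the **mass fraction** (content/100): at 0.18 % P this gives 5.16 %, at
2.47 % N 3.48 %, at 45.73 % C 2.25 %. (A published acceptance table prints
5.08 % against a mean P content of 0.21 %, which the formula does not
reproduce — 2×0.0021^(−0.15) ≈ 5.04, while 0.20 % gives 5.08; the package
keeps the formula.)

## The synthetic generator

The generator produces the statistical structure the analysis assumes, with
known ground truth:

- **Contents** — truncated log-normals per functional group (forbs, grasses,
  deciduous and evergreen shrubs with weights 0.35/0.25/0.25/0.15), group
  mean N spanning 1.1–2.9 %, P 0.09–0.26 %, C 45–51 %, truncated to overall
  ranges N 0.34–6.01, P 0.04–0.70, C 32.56–56.22 % dry weight — the spread a
  broad arctic-alpine sample campaign produces, with 2–3-fold group
  differences in N and P and near-uniform C.
- **Spectra** — A₀(λ) = baseline + Σ_j content_j · Σ_b amp·exp(−(λ−c)²/2w²),
  i.e. exactly linear in the contents (a Beer–Lambert-style mixture). Band
  centres sit inside the retained windows, in physically flavoured positions
  (N near 1510/2055/2180 nm, P near 990/2260 nm, C near 1690/2100/2310 nm);
  they are test fixtures, not spectroscopic claims.
- **Noise** — per-sample multiplicative scatter α ~ LogNormal(0, 0.03) and
  offset β ~ N(0, 0.01) shared across a sample's replicates, plus iid
  N(0, 0.004) per-wavelength noise per replicate scan (3 replicates). The
  scan-noise default was calibrated once so that the within-lab NIRS RSD for
  N lands in the observed few-percent range.
- **Regions** — region B adds a smooth spectral offset (Gaussian bump at the
  2055 nm N band plus a broad tilt, default scale 0.02) and shifts the N
  content distribution by ×0.9, emulating a second biogeographic region
  measured as a separate batch.
- **New sample types** — a "senescent" analogue confines N and P to the
  bottom decile of their ranges (C unchanged); a "moss" analogue additionally
  perturbs the band library (shifted centres, damped amplitudes).

All randomness flows through numpy's seeded PCG64 generators, so outputs are
bit-reproducible across platforms. What the generator does *not* emulate:
water bands (real protocols oven-dry samples to avoid them), radiative
transfer through leaf structure, instrument line shapes, wavelength-correlated
noise, or reference-chemistry error. Passing the recovery tests therefore
shows the pipeline is correct and leak-free under its own assumptions — not
that any particular field accuracy will be achieved.

## Study-scale experiments

The simulation experiments use n = 300 per region (two regions), matching the
order of a regional calibration campaign while keeping a full grid-search
calibration around ten seconds: parameter recovery (default noise R²val ≥ 0.9;
noise off → R²val ≈ 1 because the core is exactly linear; a 3-point scan-noise
sweep at 0.004/0.04/0.2 absorbance shows monotonic degradation), the transfer
contrast (cross-region RMSEP and |bias| exceed in-region values under the
batch offset, while the combined two-region calibration's per-region RMSEP
stays within 30 % of the region-specific models — a margin of roughly 2–3
sampling SEs of RMSEP at n_val ≈ 45), and precision recovery (the observed
3-scan RSD, whose n = 3 sample SD is biased ≈ 11 % low, must stay within ±30 %
of a 30-replicate Monte-Carlo estimate at the generator's noise parameter,
averaged over 200 samples).

## Numerical and degenerate-input choices

NIPALS stops extracting when X carries no residual covariance with y
(tolerance 1e−12 relative to input scale); a constant-y fold therefore
predicts the fold-training mean. `fit_pls` rejects k above the attained rank
unless truncation is explicitly allowed. SNV rejects constant spectra;
scaling rejects zero-variance wavelengths; Mahalanobis screening rejects
numerically zero-variance components with advice to lower the component
count. Predictions outside the training content range are returned unclipped
with an extrapolation warning. Model files are JSON with full-precision float
repr, so save → load → predict is bit-identical.

## Known limitations

- The preprocessing grid is small by design; exotic treatments (MSC, OSC,
  wavelets, higher-order detrends) are out of scope.
- Only PLS1 (one constituent per model) is implemented; N, P and C are
  calibrated independently.
- The Kennard–Stone split is deterministic given the data, so there is no
  split-resampling uncertainty estimate on the external panel.
- R² conventions differ across the literature; comparisons with published
  panels should check which variant was used.
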