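# Methods

This note documents the models, defaults and numerical choices behind
`heatacc`, and what the synthetic data do and do not establish.

## Burst geometry and preprocessing

A burst is one continuous tri-axial recording: by default 110 samples per
axis at 33.3 Hz (3.3 s), one burst every 5 minutes. Counts are 12-bit
(0–4095) spanning −4 G to +4 G, so centering subtracts 2048 and
`counts_to_g` maps counts linearly at 8 G / 4096 counts. Longer labelling
recordings (6.6 s) are split into standard halves, the second offset by
n/fs seconds. Sample counts are validated per file, not hard-coded.

Collars can be fitted with the surge (x) and sway (y) axes reversed
between deployments. The orientation decision compares pooled per-axis
means between the labelled training deployment and each inference
individual and negates an axis when the signs disagree **and** both means
exceed a magnitude floor (default 100 centered counts, ≈ 0.2 G). The
floor exists because a near-zero mean carries no orientation information;
without it, sign comparison would flip axes on noise. The comparison is
made once per individual over its whole inference dataset. Heave (z) is
never flipped. Rotation of the collar *around* the neck axis mixes y and
z instead; all yz features therefore use the per-sample magnitude
`a_yz = sqrt(a_y² + a_z²)`, which is exactly invariant under that
rotation (property-tested to 1e−9).

All features are computed on centered raw counts. A linear unit change
rescales features without reordering them, so classification is
unaffected; G units are for reporting only.

## Features (19 per burst)

Per channel (x and a_yz): mean, variance (population N divisor — these
are descriptive statistics of a fixed window, not estimates of a larger
population), SD, max, min, range; and from the magnitude spectrum of the
mean-removed series over bins 1..⌊N/2⌋ (DC excluded so posture cannot
leak into the spectral features): the frequency of the largest magnitude
(ties break to the lowest frequency), that magnitude scaled by 2/N (a
pure sinusoid of amplitude A reports ≈ A counts at bin-centred
frequencies; off-bin tones lose some mass to leakage), and Shannon
entropy of the magnitude-normalised spectrum divided by log(#bins) so it
lies in [0, 1]. An all-zero spectrum (constant series) degenerates to
(0, 0, 0).

ODBA uses a per-axis running-mean static component with a 22-sample
window (one fifth of a standard burst, 0.67 s), centered with truncated
(shrinking) windows at the edges — truncation avoids padding artifacts
and keeps the statistic a pure function of observed samples. For even
windows the centre sits left of the midpoint: sample i averages indices
[i−(w−1)/2, i+w/2]. ODBA is the burst mean of the summed absolute
dynamic residuals over all three axes. The implementation is verified
against a brute-force double-loop oracle to 1e−9.

Scaling laws (counts × k ⇒ linear features × k, variance × k², spectral
location and entropy unchanged) are property-tested.

## Feature selection and classification

Greedy forward selection under a correlation filter: a candidate is
admissible only if |Pearson r| with every already-selected feature is
below 0.9; each candidate is scored by the 5-fold cross-validated
accuracy of the classifier trained on the selected set plus the
candidate. Default k = 5 features. A feature's *contribution* is its
step's accuracy gain; the first feature's baseline is majority-class
accuracy, so baseline + Σ contributions = final CV accuracy by
construction. Contributions are marginal CV gains (not permutation
importances), a documented reading of an underspecified convention.

The classifier is XGBoost multiclass with nrounds = 10, max_depth = 6,
eta = 0.3, gamma = 0, colsample_bytree = 1, min_child_weight = 1,
subsample = 1. Splits use the exact greedy method: exact split thresholds
fall midway between observed values, so held-out points inside a clear
class gap classify correctly (the histogram method places thresholds on
data values and systematically misclassifies held-out class minima).
Train/test splitting (default 75/25) and CV folds (default 5) are
stratified by behaviour; classes too small to stratify stay whole in
training with a warning. CV predictions are pooled into one confusion
matrix (observed in columns, predicted in rows) whose total equals the
input size; accuracy gets a Wilson 95% CI. Class imbalance is left
unweighted; minority-class weakness is an accepted limitation.

## Consolidation, thermal index and budgets

The 12 ethogram behaviours map onto 5 analysis categories: foraging joins
walking; sleeping and low-activity form resting; drinking, salt-licking,
grooming, trotting and running (jointly rare, ~2% in the synthetic
deployments) are excluded, with the excluded fraction reported.

Blackglobe temperature is a pluggable empirical linear regression on air
temperature, solar radiation and relative humidity. The default
coefficients (2.0 + 1.08·Ta + 0.0203·solar − 0.02·rh) are this package's
own choice, shaped so the index is monotone in temperature and solar
radiation and never falls below air temperature while the sun is up;
absolute blackglobe values are never asserted anywhere. An identity
fallback (blackglobe = air temperature) keeps the pipeline runnable
without coefficients and is labelled in logs.

Behaviour records join the nearest-in-time weather record within a 30-min
tolerance (unmatched records dropped and counted). Hours and dates are
local (configurable UTC offset, default +2). "Proportion of time" is
operationalised as the proportion of 5-min burst records — each burst is
one time tick under the recording schedule. Budget cells key on integer
blackglobe °C (floor), hour, month and individual; proportions sum to 1
within each cell. Mean-ODBA cells additionally key on category and are
kept only with ≥ 30 recordings (100 s of measurement). At the default
fixture scale (2 individuals × 20 days) afternoon cells rarely reach 30
recordings per category, so the driver reports zero retained ODBA cells;
the ODBA-response models are exercised in tests on denser aggregations.
Proportions are pooled across days per hour (rather than per hour × day),
the reading consistent with hour-of-day as a smooth covariate.

Extreme days are the n = 10 hottest and n = 10 coolest by daily maximum
air temperature within October–December, ties broken by earlier date;
the two sets are disjoint by construction.

## Penalized-spline mixed models

`heatacc.gam` implements the additive-model class the analyses need:
cubic P-splines (B-spline basis, second-difference penalty; k = 10 for
blackglobe, k = 8 for hour, reduced when the covariate has fewer distinct
values), a cyclic variant for hour-of-day in the diel models (wrapped
cardinal B-splines with a cyclic difference penalty, so the fit joins
smoothly across midnight), indicator "by"-smooths for per-species curves
and the hot-day contrast, and random intercepts as ridge-penalized group
dummies (the mixed-model representation of i.i.d. Gaussian effects).
Smooths carry a sum-to-zero constraint absorbed by a null-space
reparameterisation so they cannot compete with the intercept.

Families: proportions use a logit link with quasi-binomial variance
μ(1−μ)/w, prior weights w = cell record count, and a free dispersion
estimated from Pearson residuals; mean ODBA uses an identity link with
constant variance. Fitting is penalized IRLS; smoothing parameters
(including the random-effect variance ratio) minimise the REML criterion
of the working Gaussian model (performance iteration, Nelder-Mead over
log-λ, clipped to ±18). Month (three levels) enters as a factor — a
three-point smooth is degenerate. Random effects are intercepts only.

On a Gaussian test problem the engine reproduces `mgcv` (REML P-spline
plus random intercept) to 3 decimals in the partial effect, 0.004 in edf
and 1% in the scale estimate; this cross-check runs in the test suite
via Rscript.

Inference. Effective degrees of freedom come from the trace of the
influence decomposition. Smooth terms are tested by an approximate F
test on the deviance increase when the model is refitted without the
term; because the smoothing parameter adapts to the data, the null
deviance increase averages about 1.5 × edf rather than edf, so the
numerator df is moment-matched at 1.5 × edf. Under null simulation this
gives rejection rates at or below nominal while retaining high power
(planted effects are detected in ≥ 90% of simulated deployments).
Parametric contrasts (the hot-day intercept δ, month and species levels)
use t tests on the Bayesian posterior covariance; their null p-values
are close to uniform (Kolmogorov distance < 0.15 over 200 null
simulations, tested). The percentage difference of 24-h means is the
ratio of mean predicted hot and cool proportions over an hourly grid,
minus one (ratio of means, not mean of ratios). Worst-case concurvity
per smooth is the squared largest canonical correlation between the
smooth's working-weighted columns and the span of all other model
columns; values ≥ 0.8 are flagged. No multiple-testing correction is
applied across the behaviour × species model battery; with five
behaviours per response this is a real caveat for borderline p-values.

## Synthetic data

Signal models are phenomenological: per behaviour a static posture
vector (gravity ≈ 512 counts on z, head position on x), one periodic
component (e.g. ~1.5 Hz walking surge, ~1 Hz low-amplitude chewing on
the yz-plane for ruminating, higher frequency and amplitude for trotting
and running), Gaussian sensor noise, and a uniform collar-rotation angle
in (y, z) per burst. Defaults make the twelve behaviours pairwise
distinguishable (standardized-feature silhouette > 0.5, tested); no
biomechanical realism is claimed — in particular real behaviours overlap
far more, so the accuracies seen on real deployments cannot be
reproduced here, and desk-scale accuracy (>95%) only shows the chain is
wired correctly, not that field performance would match.

Timelines draw a category per 5-min tick from a multinomial whose
log-odds combine a per-category base rate, a cosine diel curve, and a
linear blackglobe slope (defaults: grazing −0.06 per °C, ruminating
+0.03, resting +0.04, browsing +0.01, walking 0, around a 45 °C
reference — a clearly detectable but not extreme heat response);
first-order persistence (ρ = 0.6, behaviour bouts of ~12 min) leaves the
stationary distribution unchanged while adding realistic autocorrelation
that the quasi-binomial dispersion absorbs. Ethogram labels are emitted
from category-specific sub-label mixes plus a 2% excluded-behaviour
rate. Weather is a sinusoidal diel cycle (peak 15:00, 14 °C span) with
day-level maxima uniform on 29–41 °C, a daytime solar arc and humidity
tracking temperature inversely. Hot-day plantings for the diel analyses
modify the target category's probability directly in probability space
(other categories rescaled to sum to one), so "daytime suppression with
full nocturnal compensation" holds exactly in expectation and a flat
×0.8 multiplier is exactly −20% in the 24-h mean. Ground truth is always
written next to the data; recovery tests read it rather than the
generator internals.

Default simulated deployments for model checks use 3 individuals ×
24–30 days — a size chosen to give the models realistic cell sparsity
while letting power and calibration be estimated over 50–200 replicate
simulations.

## Known limitations

- The blackglobe regression is a stand-in; site-specific coefficients
  should be configured for real data.
- Orientation harmonisation assumes the training deployment's orientation
  is canonical and uses sign-with-floor comparison; borderline postures
  (|mean| near the floor) are left unflipped.
- The smooth-term test's 1.5 × edf correction is a moment-matched
  approximation, mildly conservative in the simulated regimes; exact
  frequentist calibration under adaptive smoothing is not claimed.
- Proportions pooled across days per hour ignore day-level dependence
  beyond what dispersion and random intercepts capture.
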