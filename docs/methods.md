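# Methods

## Scope and data model

The package analyses the association between a preschool child's 24-h
movement composition — minutes of sedentary behaviour (SB), light
physical activity (LPA) and moderate-to-vigorous physical activity
(MVPA) inside a monitored day — and fundamental movement skill (FMS)
scores, adjusting for age, BMI and sex.  Processing runs in four
stages: (1) epoch-level accelerometry to day profiles, (2) inclusion
filtering and window summaries, (3) compositional descriptives, and
(4) ilr regression with isotemporal substitution.  A synthetic cohort
generator with fully known truth drives validation.

## Accelerometry

Input is a signal-vector-magnitude value per 10-s epoch from a
wrist-worn device.  Non-wear is any run of at least 90 consecutive
minutes of zero counts; everything else is wear.  Wear epochs are
classified with preschool wrist cut points (dominant wrist: SB < 8.1,
LPA [8.1, 9.3), MVPA ≥ 9.3; non-dominant: 5.3 / 8.6).  The published
thresholds print the unit "cpm" although they are applied to 10-s SVM
epochs; the package deliberately applies thresholds on whatever scale
the input magnitudes are declared in and leaves unit conversion to the
caller, because the cut-point literature itself is ambiguous here.
Interval endpoints are half-open with inclusive lower bounds so the
three classes partition [0, ∞); the source description of the bands
overlaps at the boundaries, and half-open intervals are the unique
convention that makes classification total and unambiguous.  The
"zero *or nonzero*" phrasing sometimes attached to the 90-min non-wear
rule is treated as a slip: a rule discarding nonzero runs would delete
all data.

A day is valid at ≥ 6 h wear; a child is retained with ≥ 3 valid days
including ≥ 1 weekend day (Saturday/Sunday by calendar date).  Window
summaries (week = weekdays, weekend, four_day = all valid days) are
arithmetic means of daily minutes per child; the geometric mean is
reserved for the sample level (below).  The 180-min/day guideline
classification uses mean daily LPA+MVPA over valid days.

## Compositional core

Closure rescales positive parts to a declared total (600 min of
monitored daytime by default; 1440 or 1 by configuration).  Zeros —
possible at epoch granularity for rare behaviours — are replaced by
half an epoch (1/12 min) with multiplicative shrinkage of the other
parts, below measurement resolution by construction.  The sample
centre is the component-wise geometric mean, closed to the total.
Dispersion is the 3×3 variation matrix of pairwise log-ratio variances
(denominator n−1).

The ilr basis is fixed by the sequential binary partition
{SB | LPA, MVPA} then {LPA | MVPA}: z1 contrasts sitting against both
activity intensities, z2 light against moderate-to-vigorous activity.
The basis choice is a presentation decision only: model fit, the
composition Wald test and all substitution estimates are invariant to
any orthonormal log-ratio basis (verified to 1e-8 in the tests), so
the package fixes one and exposes `ilr_basis_from_sbp` for
alternatives.

## Regression and substitution

`CompositionalOutcomeModel` fits, by ordinary least squares, outcome ~
1 + z1 + z2 + age + bmi + sex, with sex coded female = 0 / male = 1
and continuous covariates unstandardised.  The composition's joint
significance is the Wald χ² of (b1, b2) against their 2×2 covariance
block, df = 2 — the Type II / marginality construction, which for a
single composition block equals testing the block after all
covariates.  The composition partial r² is the increment in r² over
the covariate-only model.  Residual diagnostics (Shapiro-Wilk
normality, an LM test of squared residuals on fitted values,
studentised-residual flags at |r| > 3) are advisory; nothing is
auto-dropped.

Substitution moves δ minutes (default 5) from one behaviour to another
at a baseline composition — the window's sample geometric mean in the
pipeline.  The estimate is Δz′b̂ with Δz the ilr difference, the
variance Δz′V̂Δz, and the 95% CI uses the normal critical value 1.96
(a t-quantile on the residual df is available; at the default cohort
size the difference is under 1%).  Because ilr is nonlinear in
minutes, opposite swaps are not sign-symmetric.  No multiplicity
correction is applied across the 6 × 3 × 3 table; the output metadata
says so.

Feasibility: a raw-minute swap requires the donor part to exceed δ.
Where a published weekend centre holds only 4.60 min of LPA, a 5-min
LPA-donor cell is genuinely infeasible at that baseline; the package
reports such cells as infeasible (with the donor deficit) rather than
inventing a simplex-valued surrogate, because any surrogate would
break the identity between the substitution shortcut and direct model
prediction that the test suite enforces to 1e-9.  Other cells in the
same table are unaffected.

Naive per-behaviour regressions (one behaviour plus covariates,
outcome and behaviour standardised to unit variance) are provided as
the deliberately incoherent comparator that motivates the
compositional treatment.

## Synthetic cohort generator

The generator emulates the study conditions end to end:

- **Participants** (default n = 185): sex binomial with a 99:86
  boy:girl ratio (quota sampling optional), age uniform on [3, 4] y,
  height ~ N(0.99 m, 0.045), BMI ~ N(16, 1.5) (both clipped to
  plausible ranges), mass derived.
- **Day compositions**: for each of 2 weekday + 2 weekend days, ilr
  coordinates are Gaussian with mean = ilr of the day-type mean
  composition and the day-type covariance; back-transformed and closed
  to 600 min.  This logistic-normal construction respects the simplex
  and makes the downstream ilr regression correctly specified.  Mean
  compositions default to the published (559.72, 6.57, 33.71) weekday
  and (586.80, 4.60, 8.60) weekend centres; covariances are derived
  from the published pairwise log-ratio variation matrices through the
  exact identity Σ_clr = −½·G·T·G rotated into the ilr basis.  A
  day-to-day correlation knob (default 0, the only unreported
  quantity) shares a participant-level random effect across days.
- **Epoch rendering**: each day's composition becomes 8640 10-s
  epochs; per-class epoch counts are apportioned by largest remainder,
  magnitudes drawn uniformly strictly inside each cut-point band (no
  threshold ties, no zero wear epochs), the MVPA band capped at 3× the
  upper threshold.  Non-wear is zero-magnitude, placed as leading and
  trailing blocks plus an optional mid-day block; every block must
  reach the 90-min detection window so construction and detection
  agree exactly.  No bout autocorrelation is modelled — epochs within
  a day are exchangeable — so the generator validates cut-point
  accounting, not bout-structure analytics.
- **Outcomes**: total motor competence, locomotor and object-control
  scores follow the ilr linear model on the week-window composition
  plus covariates with Gaussian noise.  The true ilr coefficients were
  back-solved by least squares from the published 5-min substitution
  estimates at the weekday centre (the published table is internally
  consistent with a two-coefficient ilr-linear model to ~0.002
  points), and the noise SDs (6.87 / 3.75 / 2.49) set so the
  composition block explains ≈ 7/8/9% of outcome variance at the
  week-window composition distribution — matching the reported
  variance shares.  Outcomes are continuous; integer score granularity
  and ceiling effects of the real instrument are not emulated.

Everything above is a `GeneratorConfig` field, not a constant.  Same
seed + config reproduces every frame bit for bit.

What passing tests do and do not show: the generator's world is
exactly the fitted model's world (logistic-normal compositions, linear
outcome, exchangeable epochs), so green simulation checks demonstrate
the correctness of the estimation machinery — not robustness to
misspecification, device error, or behavioural bout structure in real
cohorts.

## FMS scoring

Twelve skills, two trials each, per-trial maxima 4 (run, gallop, hop,
horizontal jump, slide, strike, catch, kick, throw) or 3 (leap, skip,
bounce); the adapted battery swaps the underhand roll for skipping,
and the unmodified battery is available.  Skill totals sum the two
trials; subsets give locomotor (max 52), object control (max 38) and
total (max 90).  "Out of 4" is read as per trial (the totalling over
two attempts follows immediately in the source protocol); the maxima
are config-overridable.  Rater agreement is exact percent agreement on
per-trial scores, overall and per skill.

## Anthropometrics

BMI = mass / height².  Weight-status classification against
BMI-for-age (overweight at ≥ 95th percentile, boundary inclusive) and
waist-circumference cuts uses user-supplied reference CSVs with
nearest-age lookup within sex — published growth-chart data are inputs,
not embedded, and no LMS interpolation is attempted.

## Numerical choices and validation scales

Closure renormalises twice to remove last-ulp drift; compositions
declare their total and verify it to 1e-9 relative.  Rank-deficient
designs raise with the collinear columns named.  The Monte-Carlo
validation studies default to the scales the package's checks use: 100
fits for the substitution/prediction identity (agreement ~1e-15), 200
replicates at n = 500 for parameter recovery (within 3 MC SEs), 2000
null replicates at n = 200 for Wald test size (observed ≈ 0.06 against
the χ² reference — the small-sample F-vs-χ² gap at n = 200), 1000
replicates at n = 185 for 95% CI coverage (observed ≈ 0.95).

## Known limitations

Only 3-part compositions are surfaced (sleep is not separated); the
math core is written for D parts.  No raw 100-Hz signal processing,
auto-calibration or sleep detection.  No mixed-effects modelling of
day-level data — the analysis operates on per-child window summaries.
Window-level variation matrices of multi-day means are necessarily
smaller than the day-level dispersion the generator is calibrated to;
the day level is the calibration anchor.
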