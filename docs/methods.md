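# Methods

This note records the statistical model, the conventions the package
commits to where the procedure was genuinely open, and what the synthetic
generator does and does not emulate.

## Trial design and design matrix

A factorial day/night trial realizes five DMT levels (15, 17.5, 20, 22.5,
25 °C) and five DTR levels (0, 5, 10, 15, 20 °C). The specific 10
day/night pairs of the original trial are not published; the default
`synthetic_data.default_experiment_conditions()` uses the balanced subset
of the day ≥ night grid in which every DMT level and every DTR level
occurs exactly twice and the 25/15 °C optimum is included:
20/10, 25/5, 20/15, 25/10, 20/20, 25/15, 25/20, 30/15, 25/25, 35/15.

The regression design has one row per (condition, day) using the
replicate-mean cumulative germination — 10 × 16 = 160 rows — and one
predictor per temperature level: cumulative exposure level × day (°C·day)
for the condition's matching level, zero elsewhere. Two conventions are
forced by the structure:

* **Zero levels.** A constant-temperature condition has DTR = 0, and
  0 × day is an identically zero column; zero levels are therefore encoded
  as 1 × day. Standardized coefficients are invariant to positive
  per-column rescaling, so this choice only makes the zero-level
  coefficient estimable.
* **Per-variable blocks.** Each condition activates exactly one DMT-level
  and one DTR-level column, so the unit-scaled sum of either block equals
  the day column and a joint fit of both blocks (10 predictors +
  intercept) is exactly rank-deficient. The DMT and DTR blocks are fitted
  as two separate OLS regressions (5 predictors + intercept each);
  `standardized_regression` refuses rank-deficient designs and names the
  collinear columns.

Standardized coefficients are raw coefficients × sd(x)/sd(y). Significance
stars are annotations; no coefficient is dropped by p-value.

## Impact weights

The default `signed_ratio` convention divides every standardized
coefficient by the largest absolute one: each weight keeps its sign, the
extremal weight is ±1, and the transform is antisymmetric under negating
all coefficients. With tied magnitudes the lower temperature level is the
reference. A second convention, `magnitude_at_reference`
(|βₗ|/maxⱼ|βⱼ|, all non-negative, reference exactly 1), is provided
because published tables sometimes print magnitudes when the reference
coefficient is negative; it is not the default and the two conventions
disagree whenever signs are mixed.

## Weight curves

"Simplest adequate model" is operationalized as the lowest-degree
polynomial, degree ≥ 2, whose R² on the (level, weight) points exceeds
0.98; with five points, degrees 2 and 3 are tried and otherwise the exact
degree-4 interpolant (R² = 1) is used. The fitting domain is
[min level, max level]; direct evaluation outside it raises, and peaks /
sign changes are reported only inside it (derivative and polynomial roots,
refined to 0.01 °C). With five weight points a curve can carry at most
three interior extrema; richer curve shapes would need more level points
or replicate-level weight estimates, which this version does not fit
(duplicate levels with conflicting weights are rejected).

## TS equation and requirement

The combined equation TS = a·w_DMT + b·w_DTR + c comes from OLS of the 160
cumulative-germination rows on the two cumulative impact weights
(day × curve value at the condition's DMT/DTR). The requirement is the
cumulative TS at which the fitted germination-vs-cumulative-TS line
reaches the 85 % threshold (configurable), reported as a rounded integer
TS with the raw value retained. A non-positive slope is an error — the
requirement is undefined when germination does not increase with score.

## Site scoring and out-of-range temperatures

Site temperatures routinely leave the tested 15–25 °C DMT range, and the
curves say nothing reliable out there: the degree-4 interpolant's tails
have noise-dependent sign, so polynomial extrapolation can score a −20 °C
January day as favourable. The default policy, `base_cutoff`, is the
growing-degree-day convention: a day at or below the base temperature
(default 5 °C, a conventional germination base for temperate herbs)
scores 0; between the base and the coldest tested level the clamped score
is scaled linearly (partial credit on the spring/autumn shoulders); above
the tested range weights clamp to the boundary. `clamp`, `zero` and
`extrapolate` are selectable for sensitivity analysis. A hard cutoff at
the coldest tested level was rejected: days hovering around 15 °C in late
spring fragment the favourable run and can push the detected accumulation
start past the sowing cutoff.

During accumulation, negative daily TS are floored at zero by default
(cumulative germination cannot decrease); signed accumulation is available
as a switch. The accumulation period is, per year, the longest contiguous
run of days with TS > `min_ts` (default 0), intersected across years as
(latest start, earliest end). Requirement dates: the *initial* date
accumulates floored TS from the later of the sowing date (default
day-of-year 91, early April) and the year's run start, and takes the first
date the running sum meets the requirement; the *last* date is the latest
date from which the floored sum to the run's end still meets it. Years
that never meet the requirement are excluded from the initial-date mean
with a warning; a season whose total falls below the requirement is an
error for the last date. Cross-year averages are arithmetic means of
day-of-year on a non-leap reference calendar (Feb 29 shares day 60 with
Mar 1, a documented ±1-day ambiguity), rounded half-up.

The rainy month is the precipitation-maximum month, flagged as a monsoon
when its mean total is ≥ 3× the preceding month's. The sowing window runs
from the accumulation start to the day before the first day of the month
preceding the rainy month (rainy month July ⇒ window ends May 31).

## Synthetic generator

Germination: each condition has a constant true daily score
TS_true = a·w_dmt(DMT) + b·w_dtr(DTR) + c with concave-quadratic truth
weight curves (the warm-loving default profile peaks at DMT 25 °C /
DTR 20 °C, the cool-loving one at 17.5 °C / 15 °C), and expected
cumulative germination max_germ·(1 − exp(−rate·max(0, d·TS_true))) — a
saturating link chosen because it is monotone in accumulated score and
near-linear mid-range; the trial itself specifies no generative model.
Each of the default 25 seeds per dish draws one uniform variate and counts
as germinated by day d iff it falls below the expected fraction, giving
monotone cumulative counts with binomial margins. The generator ignores
moisture, light, storage and dormancy effects, and its conditions are
exchangeable across dishes — passing recovery tests therefore shows the
estimator chain is consistent under the stated noise model, not that real
trials satisfy it.

Climate: daily mean temperature is sinusoidal (mean 7.9 °C, amplitude
14 °C, coldest mid-January) plus iid N(0, 2.5 °C) noise; the diurnal range
is a zero-truncated N(8.6, 3.2 °C); precipitation is daily-exponential
with monthly scales matching the published monthly means (July 348.13 mm).
Real weather's day-to-day autocorrelation, cold snaps and typhoons are not
modelled, which mainly affects how sharply the favourable-run edges are
located.

Since no closed-form requirement exists on the fitted-TS scale (the
generative link is nonlinear while the requirement is defined through a
linear fit), "truth-implied" values in recovery checks are the outputs of
the same pipeline run on the noiseless expected-percentage dataset — the
estimand the noisy fit converges to as seed counts grow.

## Problem sizes and numerics

Tests and the acceptance script use the trial at its stated size (10
conditions × 4 replicates × 16 days), 400 seeds per dish for recovery
checks and 25 otherwise, and 4-year climate series (10–20 years for
long-run generator statistics). Polynomial roots come from the companion
matrix (`numpy.polynomial`), accepted as real below 1e-8 imaginary part
and deduplicated at 1e-9 °C; level matching tolerates 0.01 °C; OLS runs
through statsmodels (per-level blocks) and least squares on the
2-predictor stage. All dates are timezone-free `datetime.date` arithmetic.

## Known limitations

* Impact weights inherit the confounding of the balanced-but-small
  factorial: with 10 conditions each DMT level co-occurs with only two DTR
  levels, so per-block standardized coefficients absorb some of the other
  variable's effect. The recovered weight *pattern* is the estimand of
  this design, not the truth curve pointwise.
* The degree-4 interpolation fallback is exact at the levels but wiggly
  between them; peak lists from fallback curves should be read with that
  in mind.
* The 85 % requirement extrapolates the linear germination—score fit
  beyond the observed range whenever maximum observed germination is
  below 85 %.
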