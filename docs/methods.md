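# Methods

## Scoring chains

**Two-question daily PAL.** Each day's work/daytime answer maps to a base
physical activity level (1.55, 1.65, 1.85 or 2.2) and the leisure/evening
answer adds a fixed increment (0, 0.06, 0.15 or 0.29); their sum is the
daily PAL, bounded in [1.55, 2.49]. The 16 grid values are distinct and the
score is monotone in both answers. Weekly MobilePAL is the mean of the
daily values. The instrument's literal formula divides by 7; with missed
prompts that biases the score downward, so the default denominator policy
divides by answered days and records how many there were (`fixed7`
reproduces the literal formula). Answer strings are matched
case-insensitively after whitespace collapsing, for CSV robustness.

**Accelerometry.** Minute-epoch counts are processed per calendar day
(epoch length fixed at 60 s; zero runs are not merged across midnight). A
minute is non-worn iff it belongs to a maximal run of ≥ 60 consecutive
zero-count minutes — a run of exactly 60 is non-wear, runs up to 59 are
worn sedentary time, and no spike tolerance is applied. Worn minutes
classify as sedentary ≤ 100 cpm, light 101–2020, moderate 2021–5999,
vigorous ≥ 6000. A day is valid with ≥ 600 worn minutes; day means
(mean cpm, mean MET) average over worn minutes only, which is an assumption
— averaging over all minutes of a valid day would shrink means toward zero
on low-wear days. The Freedson adult regression
`MET = 1.439008 + 0.000795 × cpm` converts counts; because the map is
affine, converting each minute and averaging equals converting the averaged
cpm, an identity the tests assert to 1e-9. Participant summaries average
over valid days and require ≥ 4 of them (quality-control error otherwise).
`acc_pamin` counts all non-sedentary worn minutes (> 100 cpm); no separate
"lifestyle" band is defined, so any such band is subsumed. Alternate MET
coefficients, cut-points, run length and day thresholds are configurable.

**IPAQ.** Weekly MET-minutes are `Σ_category minutes/day × days/week ×
weight` with the official continuous-score weights (walking 3.3, moderate
4.0, vigorous 8.0); daily summaries divide by exactly 7. The official
cleaning protocol (180 min/day per-category truncation, 10-minute minimum
bout) is available as `clean="ipaq_protocol"` but is off by default, since
applying it cannot be assumed for a given dataset. When the input carries a
`domain` column, weekly minutes are summed across domains before scoring.

## Agreement statistics

Correlations are pairwise Pearson and Spearman with two-tailed p-values at
the 5% level; a zero-variance variable makes its pairs undefined (raised by
default, NaN inside the pipeline so one degenerate measure does not kill a
report). Regressions z-score the outcome and all predictors before OLS, so
coefficients are standardized betas; adjusted R², F(df1, df2) and
per-coefficient p are reported, and a condition number above 1e8 raises a
collinearity diagnostic. Bland–Altman agreement uses difference =
questionnaire − accelerometer (a positive bias means self-report
overestimation); limits are bias ± multiplier × SD of differences with
multiplier 1.96 by default (2.0 available for the older "2 SD" convention).

Day effects use a two-way fixed-effects model (day + participant block) —
the classical repeated-measures ANOVA. With complete data the closed-form
additive decomposition is used; with missing cells an OLS on day and
participant dummies, where a day contrast is the coefficient difference.
All 21 pairwise day contrasts are tested with the Tukey–Kramer studentized-
range procedure, `q = |diff| / (SE/√2)` referred to the studentized range
with k = 7 groups and the model's residual df, honoring unequal per-day n.
The implementation was cross-checked against R's `aov` + `TukeyHSD` (agrees
to 7 decimals on a shared fixture) and is monotone: adjusted p ≥ raw p.
With zero residual variance, contrasts of zero get p = 1 and nonzero
contrasts p = 0. A mixed-model alternative with richer covariance structure
is deliberately out of scope.

The Shapiro–Wilk gate flags a variable for a parallel log-scale analysis
when normality is rejected at 5% and all values are positive; the pipeline
then reports both raw- and log-scale Pearson matrices rather than replacing
the raw analysis. Constant samples short-circuit to "no transform".

## Synthetic cohort

The generator emulates a cardiac-rehabilitation cohort of 30 participants
monitored for 7 days: age truncated-normal (65.6 ± 8.8, bounded 49–85),
87% male, six-minute-walk distance 570.8 ± 96.3 m correlated −0.43 with
age, and a latent per-participant PAL truncated-normal on [1.55, 2.49]
(1.77 ± 0.12). Day PAL adds N(0, 0.08) jitter. The questionnaire answers
are the grid cell nearest the day PAL; with probability `response_noise`
(default 0.1) one answer shifts one category. The questionnaire is thus a
direct quantized readout of the latent PAL — its fidelity is set by
quantization, day jitter and response noise, not by `rho_latent`.

`rho_latent` (default 0.45) sets the convergence of the other two
instruments. The participant's target mean cpm is
`313 + 140 × (ρ·z_S + a·z_age + b·ε)` with `a` from the age–count slope
(default −9 cpm/year, capped so `a² ≤ 1−ρ²`) and `b` filling the unit
variance; `z_S` is the standardized scored weekly PAL. Keying on the
*scored* PAL makes the ρ = 1, zero-noise limit exactly affine, so all
instrument correlations equal 1 to machine precision; because quantization
attenuates corr(scored, latent) (≈ 0.95 at defaults), the signal weight is
divided by that measured attenuation (capped at 1) so the realized
corr(latent, readout) hits `rho_latent`. Day-level cpm targets track the
day's scored PAL and add N(0, 40) jitter. Worn minutes are drawn from a
sedentary/active mixture (36% active; sedentary ~ capped exponential, mean
≈ 37 cpm; active ~ gamma with mean solved so the day mean matches its
target), shuffled within the worn block; `minute_noise=0` switches to
constant minutes carrying the exact day mean. Wear is a single overnight
zero block of (24 − wear_hours) hours — by construction one maximal zero
run per day, so the non-wear rule recovers it exactly.

IPAQ MET-minutes/day are anchored physically: `(S − 1.4) × 1440`, i.e. the
PAL excess over a resting 1.4 spread over the day — which lands the mean
near 530 MET-min/day — plus normal noise with sd `σ_signal·√(1−ρ²)/ρ`,
floored at 0 (at ρ = 0 the signal is dropped and a marginal sd of 468 is
used). The record realizes the total as walking/moderate/vigorous shares of
0.50/0.35/0.15 at 7 days/week, so IPAQ_PAmin is proportional to IPAQ_met
(their near-unit empirical correlation is a known feature of the recall
instrument's arithmetic). The floor makes the IPAQ marginal right-skewed
with a small point mass at zero — a realistic self-report shape — at the
cost of a slight correlation attenuation at low ρ.

What the generator does **not** emulate: raw tri-axial accelerations,
circadian activity profiles, within-day bout structure, seasonal effects,
recall biases that correlate with activity level, or dropout beyond
whole-day missingness. Passing tests therefore demonstrate that the
pipeline's arithmetic and statistics behave as specified under the assumed
latent-variable structure, not that the instruments are valid in any real
population.

Degenerate corners: a participant whose cpm target hits the zero floor in
the zero-minute-noise limit records an all-zero week, is flagged non-wear
throughout and excluded by quality control — the pipeline handles this as
a QC exclusion, not an error. In the same limit every worn minute is
identical, so `acc_pamin` is constant and its correlations are undefined
(reported as NaN).

## Calibration checks and problem sizes

The simulation-scale checks run at n = 1000 participants × 20 seeds for
each ρ ∈ {0, 0.45, 0.9} (seed-averaged recovered correlations within
±0.05 of ρ; single-seed values carry sampling sd ≈ 0.03, so the average is
the estimator being checked), 200 cohorts at n = 30 for the small-sample
band, 2000 null replicates (30 × 7) for the Tukey–Kramer familywise error
(≤ 0.06 at nominal 0.05), and 200 000 paired normals for Bland–Altman
coverage (≥ 93% within 1.96-SD limits). These sizes keep the full suite
around five minutes on one CPU while leaving Monte-Carlo error well below
the tolerances.

## Numerical choices

Intensity boundaries use `searchsorted` with left-closed upper bounds so
integer boundary values land in the lower class (100 → sedentary,
2020 → light, 5999 → moderate). Grid scoring ties (a day PAL equidistant
between two cells) resolve to the lower value. Standardization inside the
generator uses population SD with a 1e-12 guard for degenerate cohorts;
regression z-scores use sample SD (ddof = 1). SDs of differences in
Bland–Altman use ddof = 1. Participant ids are zero-padded to the cohort
size so lexicographic and numeric orderings agree.
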