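# paltriad

Convergent-validity pipeline for a two-question daily smartphone physical-
activity questionnaire, evaluated against hip-worn accelerometry and the
International Physical Activity Questionnaire (IPAQ) in a cardiac-
rehabilitation setting.

Self-reported activity is cheap but noisy; accelerometry is objective but
burdensome. A minimal daily instrument asks two questions each evening —
one about work/daytime activity, one about leisure/evening activity — and
maps the answers to a physical activity level (PAL), the ratio of total to
resting energy expenditure over 24 h:

```
daily PAL = work base  {1.55, 1.65, 1.85, 2.2}
          + leisure increment {+0, +0.06, +0.15, +0.29}
MobilePAL = mean of the daily PALs over the monitoring week
```

The comparison measures are:

* **Acc_CPM** — mean accelerometer counts per minute over valid days.
  A minute is non-worn iff it sits in a run of ≥ 60 consecutive zero-count
  minutes; a day is valid with ≥ 10 h (600 min) of worn time; participants
  need ≥ 4 valid days. Minutes classify as sedentary ≤ 100, light 101–2020,
  moderate 2021–5999, vigorous ≥ 6000 cpm.
* **Acc_METs** — Freedson counts-to-MET regression,
  `MET = 1.439008 + 0.000795 × cpm`, averaged over worn minutes and valid
  days. **Acc_PAmin** is daily non-sedentary minutes.
* **IPAQ_met / IPAQ_PAmin** — MET-minutes/day and active minutes/day from
  the 7-day recall (`Σ minutes × days × MET weight / 7`, weights
  walking 3.3 / moderate 4.0 / vigorous 8.0).

The validity analysis computes Pearson/Spearman correlations, age-adjusted
standardized regressions (z-scored OLS), Bland–Altman agreement between
MobilePAL and Acc_METs, repeated-measures day contrasts with Tukey–Kramer
adjustment, and a Shapiro–Wilk gate that triggers a parallel log-scale
analysis.

Because no raw cohort data are public, the package includes a synthetic
cohort generator: a latent per-participant PAL drives all three instruments
at a tunable convergence `rho_latent`, with an inverse age–count gradient
and realistic wear structure. The hidden latent PAL is retained so tests
can verify that the pipeline recovers the built-in correlation.

## Worked example

```
python analysis/01_simulate_cohort.py    # 30 participants x 7 days -> scratch/cohort/
python analysis/02_score_instruments.py  # scoring chains -> results/participant_metrics.csv
python analysis/03_validity_analysis.py  # correlations, regression, Bland-Altman, day effects
```

The last step prints (seed 7):

```
n analyzed: 30
r(mobile_pal, acc_cpm)  = 0.30 (p=0.102)
r(mobile_pal, ipaq_met) = 0.27 (p=0.153)
r(age, acc_cpm)         = -0.65
acc_cpm ~ mobile_pal + age: beta=0.27/-0.64, adj R2=0.46, F(2,27)=13.42
Bland-Altman (mobile_pal - acc_mets): bias +0.07, limits [-0.18, 0.32]
no day contrasts significant after Tukey-Kramer adjustment
```

Read: with 30 participants the questionnaire–accelerometer correlation is
a noisy estimate of the generator's built-in 0.45 (the 95% sampling band
at n=30 spans roughly 0.1–0.7); age dominates the adjusted regression with
the expected negative sign; and the questionnaire overestimates
accelerometer-derived energy expenditure by a small positive bias, as
expected from self-report. At simulation scale (n=1000, 20 seeds) the
recovered correlations pin the generator's target within ±0.05 — that
check lives in the test suite.

The same pipeline runs from the shell on any four CSVs in the documented
dialects:

```
paltriad simulate --n 30 --seed 7 --out data/
paltriad run --epochs data/epochs.csv --responses data/responses.csv \
             --ipaq data/ipaq.csv --covariates data/covariates.csv --out report/
```

## Layout

```
src/paltriad/        library: synthetic, accelerometry, mobilepal, ipaq,
                     agreement, pipeline, io, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property, calibration)
scripts/acceptance.py  benchmark recomputation
docs/methods.md      model, assumptions, parameter choices, limitations
```
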