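#!/usr/bin/env python
"""Convergent-validity analysis of the scored instruments.

Consumes results/participant_metrics.csv and results/daily_pal.csv
(produced by 02_score_instruments.py) and reports: Pearson/Spearman
correlations among the six activity measures plus age and walk distance,
age-adjusted standardized regressions, Bland-Altman agreement between the
questionnaire PAL and accelerometer METs, day-to-day PAL contrasts with
Tukey-Kramer adjustment, and the Shapiro-Wilk normality gate.
"""

import json
from pathlib import Path

import pandas as pd

from paltriad import pipeline
from paltriad.synthetic import CohortConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    metrics = pd.read_csv(RESULTS / "participant_metrics.csv", dtype={"participant_id": str})
    daily_pal = pd.read_csv(RESULTS / "daily_pal.csv", index_col="participant_id")
    cfg = pipeline.PipelineConfig(synthetic=CohortConfig(), out_dir=str(RESULTS))
    report, contrasts = pipeline.build_report(metrics, daily_pal, cfg)

    pipeline._correlation_table(report).to_csv(RESULTS / "correlations.csv", index=False)
    contrasts.to_csv(RESULTS / "day_contrasts.csv", index=False)
    pipeline._bland_altman_table(metrics, report).to_csv(
        RESULTS / "bland_altman.csv", index=False
    )
    with open(RESULTS / "agreement_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    r = report["correlations"]["pearson"]["r"]
    p = report["correlations"]["pearson"]["p"]
    print(f"n analyzed: {report['n_analyzed']}")
    print(
        f"r(mobile_pal, acc_cpm)  = {r['mobile_pal']['acc_cpm']:.2f} (p={p['mobile_pal']['acc_cpm']:.3f})"
    )
    print(
        f"r(mobile_pal, ipaq_met) = {r['mobile_pal']['ipaq_met']:.2f} (p={p['mobile_pal']['ipaq_met']:.3f})"
    )
    print(f"r(age, acc_cpm)         = {r['age']['acc_cpm']:.2f}")
    fit = report["regressions"][0]
    print(
        f"acc_cpm ~ mobile_pal + age: beta={fit['betas']['mobile_pal']:.2f}/"
        f"{fit['betas']['age']:.2f}, adj R2={fit['adj_r_squared']:.2f}, "
        f"F({fit['df'][0]},{fit['df'][1]})={fit['f_statistic']:.2f}"
    )
    ba = report["bland_altman"]
    print(
        f"Bland-Altman (mobile_pal - acc_mets): bias {ba['bias']:+.2f}, "
        f"limits [{ba['lower_limit']:.2f}, {ba['upper_limit']:.2f}]"
    )
    sig = contrasts[contrasts["p_adjusted"] < 0.05]
    if len(sig):
        pairs = ", ".join(f"{a}-{b}" for a, b in zip(sig["day_a"], sig["day_b"]))
        print(f"day contrasts significant after adjustment: {pairs}")
    else:
        print("no day contrasts significant after Tukey-Kramer adjustment")


if __name__ == "__main__":
    main()
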