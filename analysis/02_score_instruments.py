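#!/usr/bin/env python
"""Score the three instruments from the simulated raw files.

Reads scratch/cohort/ (produced by 01_simulate_cohort.py), runs the
accelerometer chain (non-wear detection, valid days, Freedson METs), the
two-question daily PAL scoring, and the IPAQ MET-minute derivation, then
writes the merged per-participant metrics and the descriptive measure table
under results/.
"""

from pathlib import Path

from paltriad import io, pipeline

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "cohort"


def main() -> None:
    metrics, daily_pal, exclusions = pipeline.compute_metrics(
        io.load_epochs(DATA / "epochs.csv"),
        io.load_responses(DATA / "responses.csv"),
        io.load_ipaq(DATA / "ipaq.csv"),
        io.load_covariates(DATA / "covariates.csv"),
    )
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    metrics.to_csv(out / "participant_metrics.csv", index=False)
    daily_pal.to_csv(out / "daily_pal.csv")
    summary = pipeline.summarize_measures(metrics)
    summary.to_csv(out / "measure_summary.csv")

    print(f"analyzed n={len(metrics)} (excluded {len(exclusions)})")
    for pid, reason in exclusions:
        print(f"  excluded {pid}: {reason}")
    print(summary.round(2))


if __name__ == "__main__":
    main()
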