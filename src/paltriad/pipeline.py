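"""End-to-end orchestration: inputs -> instrument scores -> validity report.

The pipeline reads the four input files (or generates a synthetic cohort),
runs all three scoring chains, merges them into per-participant metrics,
excludes participants failing quality control (fewer than the minimum valid
accelerometer days, or a missing instrument — the analysis is complete-case),
and runs the agreement statistics.  Everything is a pure function of the
inputs and configuration: re-runs produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import agreement, io as io_
from .accelerometry import (
    EpochSeries,
    FREEDSON_INTERCEPT,
    FREEDSON_SLOPE,
    MIN_VALID_DAYS,
    NONWEAR_RUN_MINUTES,
    VALID_DAY_MINUTES,
    day_metrics_frame,
    nonwear_mask_2d,
)
from .errors import ConfigurationError, ValidationError
from .ipaq import DEFAULT_MET_WEIGHTS, IPAQRecord, derive_daily
from .mobilepal import DailyResponse, average_week, score_day
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

log = logging.getLogger("paltriad")

#: Regressions of the headline analysis: (outcome, predictor); age-adjusted.
REGRESSION_MODELS: tuple[tuple[str, str], ...] = (
    ("acc_cpm", "mobile_pal"),
    ("acc_cpm", "ipaq_met"),
    ("mobile_pal", "ipaq_met"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs; exactly one of input paths / synthetic.

    All measurement constants surface here with their standard defaults so a
    sensitivity analysis can move any of them from a YAML file.
    """

    epochs: str | None = None
    responses: str | None = None
    ipaq: str | None = None
    covariates: str | None = None
    synthetic: CohortConfig | None = None
    out_dir: str = "pipeline_out"
    min_valid_days: int = MIN_VALID_DAYS
    valid_day_minutes: int = VALID_DAY_MINUTES
    nonwear_run_minutes: int = NONWEAR_RUN_MINUTES
    met_intercept: float = FREEDSON_INTERCEPT
    met_slope: float = FREEDSON_SLOPE
    denominator_policy: str = "answered"
    met_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MET_WEIGHTS))
    ipaq_clean: str | None = None
    ba_multiplier: float = 1.96

    def __post_init__(self) -> None:
        paths = (self.epochs, self.responses, self.ipaq, self.covariates)
        have_paths = all(p is not None for p in paths)
        any_paths = any(p is not None for p in paths)
        if self.synthetic is None and not have_paths:
            raise ConfigurationError(
                "either all four input paths or a synthetic cohort config must be set"
            )
        if self.synthetic is not None and any_paths:
            raise ConfigurationError("input paths and synthetic config are mutually exclusive")
        for name in ("min_valid_days", "valid_day_minutes", "nonwear_run_minutes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.ba_multiplier <= 0:
            raise ConfigurationError("ba_multiplier must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        synth = raw.pop("synthetic", None)
        if synth is not None:
            synth = CohortConfig(**synth)
        return cls(synthetic=synth, **raw)


@dataclass(frozen=True, eq=False)
class PipelineResult:
    metrics: pd.DataFrame  # complete-case analysis set
    daily_pal: pd.DataFrame  # participants x day_index daily PAL
    summary: pd.DataFrame  # mean / sd / min / max per measure
    exclusions: list[tuple[str, str]]
    report: dict
    day_contrasts: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def compute_metrics(
    epochs: Mapping[str, EpochSeries],
    responses: Mapping[str, list[DailyResponse]],
    ipaq_records: Mapping[str, IPAQRecord],
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Score all instruments and merge into per-participant metrics.

    Returns (metrics, daily_pal, exclusions).  ``metrics`` holds complete
    cases only; every dropped participant appears in ``exclusions`` with a
    reason.  Accelerometer processing is vectorised across the whole cohort.
    """
    cfg = config or PipelineConfig(synthetic=CohortConfig())
    pids = sorted(covariates["participant_id"].astype(str))
    exclusions: list[tuple[str, str]] = []

    # --- accelerometer: one pass over all participant-days -------------------
    have_epochs = [p for p in pids if p in epochs]
    accel = pd.DataFrame(
        columns=["acc_cpm", "acc_mets", "acc_pamin", "n_valid_days"], dtype=float
    )
    if have_epochs:
        stacked = np.concatenate([epochs[p].counts for p in have_epochs], axis=0)
        row_pid = np.repeat(have_epochs, [epochs[p].n_days for p in have_epochs])
        worn = ~nonwear_mask_2d(stacked, cfg.nonwear_run_minutes)
        dm = day_metrics_frame(
            stacked,
            worn,
            valid_day_minutes=cfg.valid_day_minutes,
            met_intercept=cfg.met_intercept,
            met_slope=cfg.met_slope,
        )
        dm["participant_id"] = row_pid
        valid = dm[dm["valid"]]
        accel = valid.groupby("participant_id").agg(
            acc_cpm=("mean_cpm", "mean"),
            acc_mets=("day_mets", "mean"),
            acc_pamin=("nonsedentary_minutes", "mean"),
            n_valid_days=("valid", "sum"),
        )

    # --- questionnaire -------------------------------------------------------
    mobile_rows = {}
    daily = {}
    for pid in pids:
        resp = responses.get(pid, [])
        if not resp:
            continue
        scores = [score_day(r) for r in resp]
        weekly = average_week(scores, policy=cfg.denominator_policy)
        mobile_rows[pid] = (weekly.mobile_pal, weekly.n_answered_days)
        daily[pid] = {r.day_index: s.daily_pal for r, s in zip(resp, scores)}
    day_cols = sorted({d for v in daily.values() for d in v})
    daily_pal = pd.DataFrame(
        {pid: [daily[pid].get(d, np.nan) for d in day_cols] for pid in daily},
        index=day_cols,
    ).T
    daily_pal.columns = [f"day{d}" for d in day_cols]
    daily_pal.index.name = "participant_id"

    # --- IPAQ ----------------------------------------------------------------
    ipaq_rows = {
        pid: derive_daily(ipaq_records[pid], cfg.met_weights, cfg.ipaq_clean)
        for pid in pids
        if pid in ipaq_records
    }

    # --- merge, complete cases only ------------------------------------------
    rows = []
    for pid in pids:
        reasons = []
        if pid not in mobile_rows:
            reasons.append("no questionnaire responses")
        if pid not in accel.index:
            n_valid = 0
            reasons.append(
                f"{n_valid} valid accelerometer day(s); {cfg.min_valid_days} required"
            )
        elif accel.loc[pid, "n_valid_days"] < cfg.min_valid_days:
            reasons.append(
                f"{int(accel.loc[pid, 'n_valid_days'])} valid accelerometer day(s); "
                f"{cfg.min_valid_days} required"
            )
        if pid not in ipaq_rows:
            reasons.append("no IPAQ record")
        if reasons:
            exclusions.append((pid, "; ".join(reasons)))
            continue
        cov = covariates.loc[pid]
        rows.append(
            {
                "participant_id": pid,
                "mobile_pal": mobile_rows[pid][0],
                "n_answered_days": mobile_rows[pid][1],
                "acc_cpm": float(accel.loc[pid, "acc_cpm"]),
                "acc_mets": float(accel.loc[pid, "acc_mets"]),
                "acc_pamin": float(accel.loc[pid, "acc_pamin"]),
                "n_valid_days": int(accel.loc[pid, "n_valid_days"]),
                "ipaq_met": ipaq_rows[pid].ipaq_met,
                "ipaq_pamin": ipaq_rows[pid].ipaq_pamin,
                "age": float(cov["age"]),
                "sex": str(cov["sex"]),
                "six_mwt_m": float(cov["six_mwt_m"]),
            }
        )
    for pid, reason in exclusions:
        log.warning("excluding participant %s: %s", pid, reason)
    metrics = pd.DataFrame(rows)
    return metrics, daily_pal, exclusions


def metrics_from_cohort(
    cohort: SyntheticCohort, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """In-memory scoring of a synthetic cohort (no CSV round trip)."""
    epochs = {p.participant_id: p.epoch_series for p in cohort.participants}
    responses = {p.participant_id: p.daily_responses for p in cohort.participants}
    ipaq_records = {p.participant_id: p.ipaq_record for p in cohort.participants}
    return compute_metrics(epochs, responses, ipaq_records, cohort.covariates_frame().set_index("participant_id", drop=False), config)


def summarize_measures(metrics: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: mean, SD, min, max per analyzed measure."""
    cols = [v for v in agreement.ANALYSIS_VARIABLES if v in metrics.columns]
    data = metrics[cols].astype(float)
    return pd.DataFrame(
        {
            "mean": data.mean(),
            "sd": data.std(ddof=1),
            "min": data.min(),
            "max": data.max(),
        }
    ).rename_axis("measure")


def build_report(
    metrics: pd.DataFrame,
    daily_pal: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict, pd.DataFrame]:
    """Full agreement analysis on the merged metrics; returns (report, day contrasts)."""
    if len(metrics) < 3:
        raise ValidationError(
            f"only {len(metrics)} participant(s) survived quality control; analysis needs >= 3"
        )
    pearson = agreement.correlate(metrics, "pearson", on_constant="nan")
    spearman = agreement.correlate(metrics, "spearman", on_constant="nan")
    regressions = [
        agreement.adjusted_regression(metrics, outcome, predictor)
        for outcome, predictor in REGRESSION_MODELS
    ]
    ba = agreement.bland_altman(
        metrics["mobile_pal"], metrics["acc_mets"], config.ba_multiplier
    )
    contrasts = agreement.day_effect(daily_pal.loc[metrics["participant_id"]].to_numpy())

    normality = {
        v: agreement.normality_gate(metrics[v])
        for v in agreement.ANALYSIS_VARIABLES
        if v in metrics.columns
    }
    flagged = [v for v, dec in normality.items() if dec.log_transform]
    log_pearson = None
    if flagged:
        logged = metrics.copy()
        for v in flagged:
            logged[v] = np.log(logged[v].astype(float))
        log_pearson = agreement.correlate(logged, "pearson", on_constant="nan")

    report = {
        "n_analyzed": int(len(metrics)),
        "correlations": {
            "pearson": {"r": pearson.r.to_dict(), "p": pearson.p.to_dict()},
            "spearman": {"r": spearman.r.to_dict(), "p": spearman.p.to_dict()},
        },
        "regressions": [
            {
                "outcome": f.outcome,
                "predictors": list(f.predictors),
                "betas": f.betas,
                "p_values": f.p_values,
                "adj_r_squared": f.adj_r_squared,
                "f_statistic": f.f_statistic,
                "df": [f.df_model, f.df_resid],
                "f_pvalue": f.f_pvalue,
            }
            for f in regressions
        ],
        "bland_altman": {
            "a": "mobile_pal",
            "b": "acc_mets",
            "bias": ba.bias,
            "sd_diff": ba.sd_diff,
            "lower_limit": ba.lower,
            "upper_limit": ba.upper,
            "multiplier": ba.multiplier,
            "n": ba.n,
        },
        "normality": {
            v: {
                "statistic": dec.statistic,
                "p_value": dec.p_value,
                "log_transform": dec.log_transform,
            }
            for v, dec in normality.items()
        },
    }
    if log_pearson is not None:
        report["correlations"]["pearson_log"] = {
            "r": log_pearson.r.to_dict(),
            "p": log_pearson.p.to_dict(),
            "log_variables": flagged,
        }
    return report, contrasts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read or generate inputs, score, analyze, and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        write_cohort(cohort, out / "cohort")
        metrics, daily_pal, exclusions = metrics_from_cohort(cohort, config)
    else:
        epochs = io_.load_epochs(config.epochs)
        responses = io_.load_responses(config.responses)
        ipaq_records = io_.load_ipaq(config.ipaq)
        covariates = io_.load_covariates(config.covariates)
        metrics, daily_pal, exclusions = compute_metrics(
            epochs, responses, ipaq_records, covariates, config
        )

    report, contrasts = build_report(metrics, daily_pal, config)
    report["exclusions"] = [{"participant_id": p, "reason": r} for p, r in exclusions]
    summary = summarize_measures(metrics)

    paths = {
        "metrics": out / "metrics.csv",
        "summary": out / "summary.csv",
        "correlations": out / "correlations.csv",
        "day_contrasts": out / "day_contrasts.csv",
        "bland_altman": out / "bland_altman.csv",
        "report": out / "agreement_report.json",
    }
    metrics.to_csv(paths["metrics"], index=False)
    summary.to_csv(paths["summary"])
    _correlation_table(report).to_csv(paths["correlations"], index=False)
    contrasts.to_csv(paths["day_contrasts"], index=False)
    _bland_altman_table(metrics, report).to_csv(paths["bland_altman"], index=False)
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return PipelineResult(
        metrics=metrics,
        daily_pal=daily_pal,
        summary=summary,
        exclusions=exclusions,
        report=report,
        day_contrasts=contrasts,
        paths=paths,
    )


def _correlation_table(report: dict) -> pd.DataFrame:
    rows = []
    for method in ("pearson", "spearman"):
        r = report["correlations"][method]["r"]
        p = report["correlations"][method]["p"]
        for a in r:
            for b in r[a]:
                if a < b:
                    rows.append(
                        {"method": method, "var_a": a, "var_b": b, "r": r[a][b], "p": p[a][b]}
                    )
    return pd.DataFrame(rows).sort_values(["method", "var_a", "var_b"], ignore_index=True)


def _bland_altman_table(metrics: pd.DataFrame, report: dict) -> pd.DataFrame:
    ba = report["bland_altman"]
    out = pd.DataFrame(
        {
            "participant_id": metrics["participant_id"],
            "mean": (metrics["mobile_pal"] + metrics["acc_mets"]) / 2.0,
            "difference": metrics["mobile_pal"] - metrics["acc_mets"],
        }
    )
    out["bias"] = ba["bias"]
    out["lower_limit"] = ba["lower_limit"]
    out["upper_limit"] = ba["upper_limit"]
    return out
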