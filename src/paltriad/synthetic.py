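"""Synthetic cardiac-rehabilitation cohort generator.

No raw data ship with this project, so every analysis stage is exercised on a
simulated cohort with the statistical structure the validity analysis
assumes: a latent per-participant physical activity level (PAL) drives all
three instruments.

Generative model (per participant i, day d):

* ``latent_pal_i``   ~ truncated normal on [1.55, 2.49] (mean 1.77, sd 0.12);
* day PAL           = latent + N(0, day_pal_sd), clipped to the PAL range;
* questionnaire     — each day's two answers are the grid cell nearest the
  day PAL; with probability ``response_noise`` one answer shifts one
  category;
* accelerometer     — the participant's target mean cpm is an affine
  combination of the standardized scored weekly PAL (weight ``rho_latent``),
  a negative age gradient, and white noise filling the remaining variance,
  so that corr(scored PAL, mean cpm) ~ rho_latent; day-level cpm targets
  track the day's scored PAL; worn minutes are drawn from a
  sedentary/active mixture whose day mean matches the target;
* IPAQ              — weekly MET-minutes are an affine function of scored
  weekly PAL, (S - 1.4) x 1440 MET-min/day, plus noise scaled so
  corr(scored PAL, IPAQ_met) ~ rho_latent, floored at zero;
* wear pattern      — one overnight zero block of (24 - wear_hours) hours
  per day, the rest worn.

The questionnaire is thus a direct (quantized, noise-corrupted) readout of
the latent PAL, while ``rho_latent`` sets the convergence of the other two
instruments with it — so the pairwise instrument correlations land near
``rho_latent`` and, in the limit rho_latent=1 with all noise scales at zero,
equal 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import mobilepal
from .accelerometry import (
    EpochSeries,
    FREEDSON_INTERCEPT,
    FREEDSON_SLOPE,
    MINUTES_PER_DAY,
)
from .errors import ConfigurationError
from .ipaq import CATEGORIES, DEFAULT_MET_WEIGHTS, IPAQRecord
from .mobilepal import DailyResponse, LEISURE_ANSWERS, WORK_ANSWERS

#: First monitoring day of every synthetic participant (a Monday).
START_DATE = Date(2012, 1, 9)

# Marginals of the emulated cohort (age, functional capacity, activity):
_AGE_MEAN, _AGE_SD = 65.6, 8.8
_SIXMWT_MEAN, _SIXMWT_SD = 570.8, 96.3
_SIXMWT_RANGE = (372.0, 742.0)
_SIXMWT_AGE_R = -0.43
_MALE_FRACTION = 0.87
_LATENT_MEAN, _LATENT_SD = 1.77, 0.12
_CPM_MEAN, _CPM_SD = 313.0, 140.0
#: Resting PAL anchoring the PAL -> MET-minute link for the recall instrument.
_RESTING_PAL = 1.4
_IPAQ_NULL_SD = 468.0  # marginal sd used when rho_latent = 0 (pure noise)
#: Daily MET-minute shares attributed to walking / moderate / vigorous recall.
_IPAQ_SHARES = (0.50, 0.35, 0.15)

_SED_SCALE = 40.0  # exponential scale of sedentary worn-minute counts
_SED_CAP = 100.0
# mean of min(Exp(scale), cap): used to keep the day mean on target
_SED_MEAN = _SED_SCALE * (1.0 - np.exp(-_SED_CAP / _SED_SCALE))
_ACTIVE_SHAPE = 2.0  # gamma shape of active worn-minute counts


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults emulate the study conditions."""

    n_participants: int = 30
    n_days: int = 7
    rho_latent: float = 0.45
    age_range: tuple[float, float] = (49.0, 85.0)
    age_count_slope: float = -9.0  # cpm per year, negative
    wear_hours_mean: float = 14.0
    response_noise: float = 0.1
    seed: int = 0
    # secondary noise scales (all zero -> deterministic instruments)
    day_pal_sd: float = 0.08
    day_count_sd: float = 40.0
    minute_noise: float = 1.0  # 0 = constant worn minutes with exact day mean
    active_fraction: float = 0.36

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if not 0.0 <= self.rho_latent <= 1.0:
            raise ConfigurationError("rho_latent must be in [0, 1]")
        if not 0.0 <= self.response_noise <= 1.0:
            raise ConfigurationError("response_noise must be in [0, 1]")
        if not 0.0 < self.wear_hours_mean <= 24.0:
            raise ConfigurationError("wear_hours_mean must be in (0, 24]")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be an increasing (lo, hi) pair")
        if self.day_pal_sd < 0 or self.day_count_sd < 0:
            raise ConfigurationError("day_pal_sd and day_count_sd must be nonnegative")
        if not 0.0 <= self.minute_noise <= 1.0:
            raise ConfigurationError("minute_noise must be in [0, 1]")
        if not 0.0 < self.active_fraction < 1.0:
            raise ConfigurationError("active_fraction must be in (0, 1)")


@dataclass(frozen=True, eq=False)
class SyntheticParticipant:
    participant_id: str
    age: float
    sex: str
    six_mwt_m: float
    epoch_series: EpochSeries
    daily_responses: list[DailyResponse]
    ipaq_record: IPAQRecord
    latent_pal: float


@dataclass(frozen=True, eq=False)
class SyntheticCohort:
    config: CohortConfig
    participants: list[SyntheticParticipant] = field(default_factory=list)

    @property
    def latent_pal(self) -> np.ndarray:
        return np.array([p.latent_pal for p in self.participants])

    def latent_frame(self) -> pd.DataFrame:
        """Hidden ground truth, keyed by participant id (for recovery tests)."""
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "latent_pal": self.latent_pal,
            }
        )

    # ---- tabular views (the four CSV dialects) ------------------------------

    def epochs_frame(self) -> pd.DataFrame:
        if not self.participants:
            return pd.DataFrame(columns=["participant_id", "timestamp", "counts"])
        return pd.concat(
            [p.epoch_series.to_frame() for p in self.participants], ignore_index=True
        )

    def responses_frame(self) -> pd.DataFrame:
        rows = [
            (p.participant_id, r.day_index, r.work_answer, r.leisure_answer)
            for p in self.participants
            for r in p.daily_responses
        ]
        return pd.DataFrame(
            rows, columns=["participant_id", "day_index", "work_answer", "leisure_answer"]
        )

    def ipaq_frame(self) -> pd.DataFrame:
        rows = [
            (p.participant_id, c, p.ipaq_record.days(c), p.ipaq_record.minutes(c))
            for p in self.participants
            for c in CATEGORIES
        ]
        return pd.DataFrame(
            rows, columns=["participant_id", "category", "days_per_week", "minutes_per_day"]
        )

    def covariates_frame(self) -> pd.DataFrame:
        rows = [
            (p.participant_id, p.age, p.sex, p.six_mwt_m) for p in self.participants
        ]
        return pd.DataFrame(rows, columns=["participant_id", "age", "sex", "six_mwt_m"])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _nearest_grid_indices(day_pal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Work/leisure category indices of the grid value nearest each day PAL.

    Ties resolve to the lower PAL value (then the lower work category).
    """
    cells = sorted(
        ((mobilepal.grid_value(w, l), w, l) for w in range(4) for l in range(4))
    )
    values = np.array([v for v, _, _ in cells])
    widx = np.array([w for _, w, _ in cells])
    lidx = np.array([l for _, _, l in cells])
    k = np.argmin(np.abs(day_pal[..., None] - values), axis=-1)  # first min: low tie-break
    return widx[k], lidx[k]


def _worn_counts(rng, targets: np.ndarray, wear_min: int, cfg: CohortConfig) -> np.ndarray:
    """Integer counts for the worn block of each day, day means near targets.

    targets: (n_days_total,) nonnegative day-mean cpm targets.
    Returns (n_days_total, wear_min) integers.
    """
    n = targets.shape[0]
    if cfg.minute_noise == 0.0:
        # constant worn minutes carrying the exact day mean (up to 1 count total)
        total = np.rint(targets * wear_min).astype(np.int64)
        base = total // wear_min
        rem = total % wear_min
        out = np.broadcast_to(base[:, None], (n, wear_min)).copy()
        out[np.arange(wear_min)[None, :] < rem[:, None]] += 1
        return out
    n_active = int(round(cfg.active_fraction * wear_min))
    n_active = min(max(n_active, 1), wear_min - 1)
    n_sed = wear_min - n_active
    sed = np.minimum(rng.exponential(_SED_SCALE, size=(n, n_sed)), _SED_CAP)
    active_mean = np.maximum(
        (targets * wear_min - _SED_MEAN * n_sed) / n_active, 0.0
    )
    active = rng.gamma(_ACTIVE_SHAPE, 1.0, size=(n, n_active)) * (
        active_mean[:, None] / _ACTIVE_SHAPE
    )
    draws = np.concatenate([sed, active], axis=1)
    draws = rng.permuted(draws, axis=1)
    blended = (1.0 - cfg.minute_noise) * targets[:, None] + cfg.minute_noise * draws
    return np.rint(np.maximum(blended, 0.0)).astype(np.int64)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_participants, cfg.n_days

    ages = _truncated_normal(rng, _AGE_MEAN, _AGE_SD, *cfg.age_range, size=n)
    sex = np.where(rng.random(n) < _MALE_FRACTION, "male", "female")
    z_age = _standardize(ages)
    e6 = rng.standard_normal(n)
    z6 = _SIXMWT_AGE_R * z_age + np.sqrt(1.0 - _SIXMWT_AGE_R**2) * e6
    six_mwt = np.clip(_SIXMWT_MEAN + _SIXMWT_SD * z6, *_SIXMWT_RANGE)

    latent = _truncated_normal(
        rng, _LATENT_MEAN, _LATENT_SD, mobilepal.PAL_MIN, mobilepal.PAL_MAX, size=n
    )
    day_pal = np.clip(
        latent[:, None] + cfg.day_pal_sd * rng.standard_normal((n, d)),
        mobilepal.PAL_MIN,
        mobilepal.PAL_MAX,
    )

    widx, lidx = _nearest_grid_indices(day_pal)
    grid = np.add.outer(np.array(mobilepal.WORK_PAL), np.array(mobilepal.LEISURE_INCREMENT))
    day_score = grid[widx, lidx]  # (n, d): un-corrupted daily score
    weekly_score = day_score.mean(axis=1)  # S_i

    # --- questionnaire responses (with response noise) -----------------------
    flip = rng.random((n, d)) < cfg.response_noise
    which = rng.integers(0, 2, size=(n, d))  # 0 = work answer, 1 = leisure answer
    delta = rng.choice([-1, 1], size=(n, d))
    obs_w = np.where(flip & (which == 0), np.clip(widx + delta, 0, 3), widx)
    obs_l = np.where(flip & (which == 1), np.clip(lidx + delta, 0, 3), lidx)

    # --- accelerometer -------------------------------------------------------
    # The instruments key on the scored weekly PAL S (so the rho=1 noiseless
    # limit is exactly affine), but quantization and day noise attenuate
    # corr(S, latent); divide the signal weight by that known attenuation so
    # the realized corr(latent, readout) hits rho_latent.
    c_s = float(np.corrcoef(weekly_score, latent)[0, 1]) if n > 2 else 1.0
    if not np.isfinite(c_s) or c_s <= 0.0:
        c_s = 1.0
    rho = min(cfg.rho_latent / c_s, 1.0)
    zs = _standardize(weekly_score)
    a_target = abs(cfg.age_count_slope) * float(np.std(ages)) / _CPM_SD
    a = min(a_target, np.sqrt(max(1.0 - rho**2, 0.0)))
    b = np.sqrt(max(1.0 - rho**2 - a**2, 0.0))
    eps = rng.standard_normal(n)
    cpm_mean = _CPM_MEAN + _CPM_SD * (
        rho * zs + np.sign(cfg.age_count_slope) * a * z_age + b * eps
    )
    sd_s = float(np.std(weekly_score))
    track = rho * _CPM_SD / sd_s if sd_s > 1e-12 else 0.0
    day_cpm = np.maximum(
        cpm_mean[:, None]
        + track * (day_score - weekly_score[:, None])
        + cfg.day_count_sd * rng.standard_normal((n, d)),
        0.0,
    )

    wear_min = int(round(cfg.wear_hours_mean * 60))
    nonwear_min = MINUTES_PER_DAY - wear_min
    worn = _worn_counts(rng, day_cpm.reshape(-1), wear_min, cfg)
    counts = np.zeros((n * d, MINUTES_PER_DAY), dtype=np.int64)
    counts[:, nonwear_min:] = worn  # single overnight zero block at day start
    counts = counts.reshape(n, d, MINUTES_PER_DAY)

    # --- IPAQ ----------------------------------------------------------------
    base = (weekly_score - _RESTING_PAL) * 1440.0  # MET-minutes/day above rest
    eps_i = rng.standard_normal(n)
    if rho < 1e-9:
        ipaq_met = np.maximum(np.mean(base) + _IPAQ_NULL_SD * eps_i, 0.0)
    else:
        sd_b = float(np.std(base))
        noise_sd = sd_b * np.sqrt(max(1.0 - rho**2, 0.0)) / rho
        ipaq_met = np.maximum(base + noise_sd * eps_i, 0.0)
    weights = [DEFAULT_MET_WEIGHTS[c] for c in CATEGORIES]
    minutes = {
        c: share * ipaq_met / w
        for c, share, w in zip(CATEGORIES, _IPAQ_SHARES, weights)
    }

    participants = []
    width = max(3, len(str(n)))  # ids sort lexicographically == numerically
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        series = EpochSeries(participant_id=pid, start_date=START_DATE, counts=counts[i])
        responses = [
            DailyResponse(
                day_index=j + 1,
                work_answer=WORK_ANSWERS[obs_w[i, j]],
                leisure_answer=LEISURE_ANSWERS[obs_l[i, j]],
            )
            for j in range(d)
        ]
        record = IPAQRecord(
            days_per_week={c: 7 for c in CATEGORIES},
            minutes_per_day={c: float(minutes[c][i]) for c in CATEGORIES},
        )
        participants.append(
            SyntheticParticipant(
                participant_id=pid,
                age=float(ages[i]),
                sex=str(sex[i]),
                six_mwt_m=float(six_mwt[i]),
                epoch_series=series,
                daily_responses=responses,
                ipaq_record=record,
                latent_pal=float(latent[i]),
            )
        )
    return SyntheticCohort(config=cfg, participants=participants)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the four input CSVs; returns the path of each file.

    The hidden latent PAL is deliberately not written: downstream stages see
    only what the instruments would record.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    epochs = cohort.epochs_frame()
    if len(epochs):
        epochs = epochs.assign(
            timestamp=epochs["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        )
    paths = {
        "epochs": directory / "epochs.csv",
        "responses": directory / "responses.csv",
        "ipaq": directory / "ipaq.csv",
        "covariates": directory / "covariates.csv",
    }
    epochs.to_csv(paths["epochs"], index=False)
    cohort.responses_frame().to_csv(paths["responses"], index=False)
    cohort.ipaq_frame().to_csv(paths["ipaq"], index=False)
    cohort.covariates_frame().to_csv(paths["covariates"], index=False)
    return paths


def noiseless_config(n_participants: int = 30, seed: int = 0) -> CohortConfig:
    """Config for the deterministic limit: rho=1 and every noise scale zero."""
    return CohortConfig(
        n_participants=n_participants,
        rho_latent=1.0,
        response_noise=0.0,
        day_pal_sd=0.0,
        day_count_sd=0.0,
        minute_noise=0.0,
        seed=seed,
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
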