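"""Convergent-validity statistics.

Given the merged per-participant measures (questionnaire PAL, accelerometer
cpm/MET/active minutes, IPAQ MET-minutes and active minutes, age, six-minute
walk distance) this module computes:

* pairwise Pearson and Spearman correlation matrices with two-tailed p;
* age-adjusted ordinary least squares regressions on z-scored variables
  (standardized betas, adjusted R^2, F with its df, per-coefficient p);
* Bland-Altman agreement between two paired measures (mean bias and limits
  bias +/- multiplier x SD of the differences);
* repeated-measures day effects: a two-way fixed-effects model
  (day + participant block) with all pairwise day contrasts adjusted by the
  Tukey-Kramer studentized-range procedure;
* a Shapiro-Wilk normality gate that flags variables for a parallel
  log-scale analysis.

All tests are two-tailed at the 5% level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, UndefinedCorrelationError, ValidationError

#: Measures entering the correlation analysis, in report order.
ANALYSIS_VARIABLES: tuple[str, ...] = (
    "mobile_pal",
    "acc_cpm",
    "acc_mets",
    "acc_pamin",
    "ipaq_met",
    "ipaq_pamin",
    "age",
    "six_mwt_m",
)

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationMatrix:
    method: str
    r: pd.DataFrame
    p: pd.DataFrame

    def significant(self) -> pd.DataFrame:
        return self.p < ALPHA


@dataclass(frozen=True)
class RegressionFit:
    outcome: str
    predictors: tuple[str, ...]
    betas: dict[str, float]  # standardized coefficients
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    f_pvalue: float
    n: int


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    lower: float
    upper: float
    multiplier: float
    n: int


@dataclass(frozen=True)
class NormalityDecision:
    statistic: float
    p_value: float
    log_transform: bool
    all_positive: bool


def correlate(metrics: pd.DataFrame, method: str = "pearson",
              variables: tuple[str, ...] = ANALYSIS_VARIABLES,
              on_constant: str = "raise") -> CorrelationMatrix:
    """Pairwise correlation matrix with two-tailed p-values.

    A zero-variance variable makes every coefficient involving it undefined:
    with ``on_constant="raise"`` (default) an UndefinedCorrelationError is
    raised, with ``"nan"`` those pairs are reported as NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method: {method!r}")
    if on_constant not in ("raise", "nan"):
        raise ValidationError(f"unknown on_constant policy: {on_constant!r}")
    cols = [v for v in variables if v in metrics.columns]
    data = metrics[cols].astype(float)
    if len(data) < 3:
        raise ValidationError("correlation requires at least 3 participants")
    constant = {c for c in cols if float(np.std(data[c])) == 0.0}
    if constant and on_constant == "raise":
        raise UndefinedCorrelationError(
            f"variable(s) {sorted(constant)} have zero variance"
        )
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, j in itertools.combinations(range(k), 2):
        if cols[i] in constant or cols[j] in constant:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        res = fn(data[cols[i]], data[cols[j]])
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        method=method,
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def adjusted_regression(
    metrics: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = ("age",),
) -> RegressionFit:
    """OLS of z-scored outcome on z-scored predictor + covariates.

    Because every variable is standardized, the coefficients are
    standardized betas; with a single predictor and no covariates the beta
    equals the Pearson correlation.
    """
    predictors = (predictor, *covariates)
    n = len(metrics)
    if n <= len(predictors) + 1:
        raise ValidationError("too few observations for the requested model")
    y = _zscore(metrics[outcome].to_numpy(dtype=float))
    X = np.column_stack([_zscore(metrics[v].to_numpy(dtype=float)) for v in predictors])
    Xc = sm.add_constant(X)
    if np.linalg.cond(Xc) > 1e8:
        raise CollinearityError(
            f"design matrix for {outcome} ~ {' + '.join(predictors)} is numerically collinear"
        )
    fit = sm.OLS(y, Xc).fit()
    return RegressionFit(
        outcome=outcome,
        predictors=predictors,
        betas={v: float(fit.params[i + 1]) for i, v in enumerate(predictors)},
        p_values={v: float(fit.pvalues[i + 1]) for i, v in enumerate(predictors)},
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
        n=n,
    )


def bland_altman(a, b, limit_multiplier: float = 1.96) -> BlandAltman:
    """Agreement between paired measures a and b (difference = a - b).

    limit_multiplier 1.96 gives the conventional 95% limits; 2.0 reproduces
    the older "2 SD" convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"paired series length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("Bland-Altman requires at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        lower=bias - limit_multiplier * sd,
        upper=bias + limit_multiplier * sd,
        multiplier=limit_multiplier,
        n=a.size,
    )


def day_effect(pal_matrix, _force_ols: bool = False) -> pd.DataFrame:
    """Pairwise day contrasts from a repeated-measures model.

    ``pal_matrix`` is participants x days (NaN = unanswered day).  A two-way
    fixed-effects model (day + participant block) is fitted; every pairwise
    day contrast is tested with the Tukey-Kramer studentized-range
    procedure, which honors unequal per-day n.  Returns one row per day
    pair: estimate, SE, q, raw two-tailed p (t reference) and adjusted p
    (studentized-range reference).
    """
    X = np.asarray(pal_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("pal_matrix must be 2-dimensional (participants x days)")
    n_sub, k = X.shape
    if n_sub < 2:
        raise ValidationError("day_effect requires at least 2 participants")
    obs = ~np.isnan(X)
    if np.any(obs.sum(axis=0) == 0):
        missing = [int(j) + 1 for j in np.flatnonzero(obs.sum(axis=0) == 0)]
        raise ValidationError(f"day(s) {missing} have no observations")

    if obs.all() and not _force_ols:
        # balanced complete data: classical additive two-way decomposition
        day_means = X.mean(axis=0)
        resid = X - day_means[None, :] - X.mean(axis=1)[:, None] + X.mean()
        df_resid = (n_sub - 1) * (k - 1)
        mse = float((resid**2).sum() / df_resid)
        n_per_day = np.full(k, n_sub)
        est = {
            (i, j): day_means[i] - day_means[j]
            for i, j in itertools.combinations(range(k), 2)
        }
        se = {
            pair: np.sqrt(mse * (1.0 / n_sub + 1.0 / n_sub)) for pair in est
        }
    else:
        # unbalanced: OLS with day and participant dummies (treatment coding);
        # in the additive model a day contrast is the coefficient difference.
        rows, cols = np.nonzero(obs)
        y = X[rows, cols]
        n_obs = y.size
        D = np.zeros((n_obs, 1 + (k - 1) + (n_sub - 1)))
        D[:, 0] = 1.0
        for j in range(1, k):
            D[cols == j, j] = 1.0
        for s in range(1, n_sub):
            D[rows == s, (k - 1) + s] = 1.0
        beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        df_resid = n_obs - rank
        if df_resid <= 0:
            raise ValidationError("no residual degrees of freedom for the day-effect model")
        mse = float((resid**2).sum() / df_resid)
        cov = mse * np.linalg.pinv(D.T @ D)
        n_per_day = obs.sum(axis=0)
        est, se = {}, {}
        for i, j in itertools.combinations(range(k), 2):
            c = np.zeros(D.shape[1])
            if i > 0:
                c[i] = 1.0
            if j > 0:
                c[j] -= 1.0
            est[(i, j)] = float(c @ beta)
            se[(i, j)] = float(np.sqrt(c @ cov @ c))

    records = []
    for (i, j), diff in est.items():
        s = se[(i, j)]
        if s == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
            t = q
        else:
            q = abs(diff) / (s / np.sqrt(2.0))
            t = abs(diff) / s
        p_raw = 2.0 * stats.t.sf(t, df_resid) if np.isfinite(t) else (1.0 if t == 0 else 0.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        if q == 0.0:
            p_adj = 1.0
        records.append(
            {
                "day_a": i + 1,
                "day_b": j + 1,
                "estimate": diff,
                "se": s,
                "n_a": int(n_per_day[i]),
                "n_b": int(n_per_day[j]),
                "q": q,
                "p_raw": min(p_raw, 1.0),
                "p_adjusted": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame.from_records(records)


def normality_gate(values, alpha: float = ALPHA) -> NormalityDecision:
    """Shapiro-Wilk test deciding whether a log-scale rerun is warranted.

    The log transform is flagged when normality is rejected and all values
    are positive; with nonpositive values the transform is skipped.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("normality test requires n >= 3")
    if np.ptp(x) == 0.0:  # degenerate constant sample: nothing to transform
        return NormalityDecision(
            statistic=float("nan"),
            p_value=1.0,
            log_transform=False,
            all_positive=bool(np.all(x > 0)),
        )
    stat, p = stats.shapiro(x)
    positive = bool(np.all(x > 0))
    return NormalityDecision(
        statistic=float(stat),
        p_value=float(p),
        log_transform=bool(p < alpha and positive),
        all_positive=positive,
    )
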