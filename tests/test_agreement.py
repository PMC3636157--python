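"""Correlation, regression, Bland-Altman, day-effect and normality machinery."""

import numpy as np
import pandas as pd
import pytest

from paltriad import agreement
from paltriad.errors import UndefinedCorrelationError, ValidationError


def pearson_oracle(x, y):
    """Textbook sum-formula Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(n * (y**2).sum() - y.sum() ** 2)
    return num / den


def frame(**cols):
    return pd.DataFrame(cols)


class TestCorrelate:
    def test_perfect_linearity(self, rng):
        x = rng.normal(size=30)
        m = agreement.correlate(frame(a=x, b=2 * x + 1), variables=("a", "b"))
        assert m.r.loc["a", "b"] == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self, rng):
        x = rng.normal(size=30)
        y = np.exp(3 * x)  # monotone, nonlinear
        pear = agreement.correlate(frame(a=x, b=y), variables=("a", "b"))
        spear = agreement.correlate(frame(a=x, b=y), "spearman", variables=("a", "b"))
        assert spear.r.loc["a", "b"] == pytest.approx(1.0)
        assert pear.r.loc["a", "b"] < 1.0

    def test_matches_sum_formula_oracle(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        m = agreement.correlate(frame(a=x, b=y), variables=("a", "b"))
        assert m.r.loc["a", "b"] == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_matrix_is_symmetric_with_unit_diagonal(self, default_metrics):
        metrics, _ = default_metrics
        m = agreement.correlate(metrics)
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)
        assert np.allclose(m.p, m.p.T)

    def test_zero_variance_raises_or_nans(self, rng):
        data = frame(a=rng.normal(size=10), b=np.ones(10))
        with pytest.raises(UndefinedCorrelationError, match="b"):
            agreement.correlate(data, variables=("a", "b"))
        m = agreement.correlate(data, variables=("a", "b"), on_constant="nan")
        assert np.isnan(m.r.loc["a", "b"])


class TestRegression:
    def test_outcome_equals_predictor(self, rng):
        x = rng.normal(size=20)
        with np.errstate(divide="ignore", invalid="ignore"):
            fit = agreement.adjusted_regression(
                frame(y=x, x=x), "y", "x", covariates=()
            )
        assert fit.betas["x"] == pytest.approx(1.0, abs=1e-8)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-8)

    def test_null_model_betas_shrink(self, rng):
        n = 2000
        fit = agreement.adjusted_regression(
            frame(y=rng.normal(size=n), x=rng.normal(size=n), age=rng.normal(size=n)),
            "y",
            "x",
        )
        assert abs(fit.betas["x"]) < 0.1
        assert fit.adj_r_squared < 0.05

    def test_single_predictor_beta_equals_pearson(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        fit = agreement.adjusted_regression(frame(y=y, x=x), "y", "x", covariates=())
        assert fit.betas["x"] == pytest.approx(pearson_oracle(x, y), abs=1e-10)

    def test_sign_recovery_on_synthetic_cohort(self, default_metrics):
        metrics, _ = default_metrics
        fit = agreement.adjusted_regression(metrics, "acc_cpm", "mobile_pal")
        assert fit.betas["mobile_pal"] > 0
        assert fit.betas["age"] < 0
        assert fit.df_model == 2 and fit.df_resid == len(metrics) - 3

    def test_collinear_design_raises(self, rng):
        x = rng.normal(size=20)
        from paltriad.errors import CollinearityError

        with pytest.raises(CollinearityError):
            agreement.adjusted_regression(
                frame(y=rng.normal(size=20), x=x, age=2 * x), "y", "x"
            )


class TestBlandAltman:
    def test_identity(self):
        ba = agreement.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.lower == 0.0 and ba.upper == 0.0

    def test_constant_offset(self):
        a = np.array([1.5, 1.7, 1.9])
        ba = agreement.bland_altman(a + 0.08, a)
        assert ba.bias == pytest.approx(0.08)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_matches_mean_sd_oracle(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        ba = agreement.bland_altman(a, b, limit_multiplier=2.0)
        d = a - b
        assert ba.bias == pytest.approx(d.mean(), abs=1e-12)
        assert ba.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert ba.upper == pytest.approx(d.mean() + 2.0 * d.std(ddof=1), abs=1e-12)
        # limits symmetric about bias
        assert ba.upper - ba.bias == pytest.approx(ba.bias - ba.lower, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            agreement.bland_altman([1.0, 2.0], [1.0])


class TestDayEffect:
    def test_no_variation_gives_unit_pvalues(self):
        out = agreement.day_effect(np.full((5, 7), 1.7))
        assert (out["p_adjusted"] == 1.0).all()

    def test_large_shift_detected_and_matches_permutation_oracle(self, rng):
        X = rng.normal(1.8, 0.1, (30, 7))
        X[:, 6] += 1.0  # +10 within-participant SDs on day 7
        out = agreement.day_effect(X)
        day7 = out[(out["day_a"] == 7) | (out["day_b"] == 7)]
        assert (day7["p_adjusted"] < 0.001).all()

        # permutation oracle on the day-7-vs-rest contrast
        def stat(M):
            return abs(M[:, 6].mean() - M[:, :6].mean())

        observed = stat(X)
        hits = 0
        n_perm = 300
        for _ in range(n_perm):
            perm = np.array([row[rng.permutation(7)] for row in X])
            hits += stat(perm) >= observed
        assert (hits + 1) / (n_perm + 1) < 0.01

    def test_adjustment_never_below_raw_p(self, rng):
        out = agreement.day_effect(rng.normal(1.8, 0.1, (12, 7)))
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()

    def test_balanced_and_ols_paths_agree(self, rng):
        X = rng.normal(0, 1, (10, 5))
        fast = agreement.day_effect(X)
        slow = agreement.day_effect(X, _force_ols=True)
        for col in ("estimate", "se", "q", "p_raw", "p_adjusted"):
            assert np.allclose(fast[col], slow[col], atol=1e-8), col

    def test_missing_cells_reduce_contrast_n(self, rng):
        X = rng.normal(0, 1, (10, 4))
        X[0, 0] = np.nan
        out = agreement.day_effect(X)
        assert out.loc[out["day_a"] == 1, "n_a"].iloc[0] == 9

    def test_fully_missing_day_rejected(self, rng):
        X = rng.normal(0, 1, (5, 3))
        X[:, 1] = np.nan
        with pytest.raises(ValidationError, match=r"\[2\]"):
            agreement.day_effect(X)


class TestNormalityGate:
    def test_normal_sample_passes(self, rng):
        dec = agreement.normality_gate(rng.normal(size=1000))
        assert dec.p_value > 0.05
        assert not dec.log_transform

    def test_lognormal_sample_flagged(self, rng):
        dec = agreement.normality_gate(np.exp(rng.normal(size=1000)))
        assert dec.p_value < 0.05
        assert dec.log_transform

    def test_nonpositive_values_skip_transform(self, rng):
        x = np.exp(rng.normal(size=500))
        x[0] = 0.0
        dec = agreement.normality_gate(x)
        assert not dec.log_transform and not dec.all_positive

    def test_deterministic_given_sample(self, rng):
        x = rng.normal(size=100)
        a = agreement.normality_gate(x)
        b = agreement.normality_gate(x)
        assert a == b
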