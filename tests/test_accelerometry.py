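"""Accelerometer count processing: wear detection, cut-points, METs, summaries."""

from datetime import date

import numpy as np
import pytest

from paltriad import accelerometry as acc
from paltriad.errors import QualityControlError, ValidationError

DAY = date(2012, 1, 9)


def series(rows: np.ndarray) -> acc.EpochSeries:
    return acc.EpochSeries("P001", DAY, np.atleast_2d(rows))


def brute_force_nonwear(counts: np.ndarray, run: int = 60) -> np.ndarray:
    """Independent oracle: scan every maximal zero run in a 1-day stream."""
    counts = np.asarray(counts)
    mask = np.zeros(counts.size, dtype=bool)
    i = 0
    while i < counts.size:
        if counts[i] == 0:
            j = i
            while j < counts.size and counts[j] == 0:
                j += 1
            if j - i >= run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


class TestNonwear:
    def test_all_zero_day_is_fully_nonworn(self):
        mask = acc.detect_nonwear(series(np.zeros(1440, dtype=int)))
        assert not mask.worn.any()

    def test_59_zero_run_stays_worn(self):
        counts = np.ones(1440, dtype=int)
        counts[100:159] = 0
        mask = acc.detect_nonwear(series(counts))
        assert mask.worn.all()

    def test_60_zero_run_is_nonworn_exactly(self):
        counts = np.ones(1440, dtype=int)
        counts[100:160] = 0
        mask = acc.detect_nonwear(series(counts))
        assert (~mask.worn).sum() == 60
        assert not mask.worn[0, 100:160].any()

    def test_matches_brute_force_on_random_streams(self, rng):
        for _ in range(200):
            counts = (rng.random(1440) < 0.35) * rng.integers(1, 500, 1440)
            got = acc.nonwear_mask_2d(counts[None, :])[0]
            assert np.array_equal(got, brute_force_nonwear(counts))

    def test_runs_do_not_merge_across_days(self):
        two_days = np.ones((2, 1440), dtype=int)
        two_days[0, 1410:] = 0  # 30 zeros at end of day 1
        two_days[1, :30] = 0  # 30 zeros at start of day 2
        assert not acc.nonwear_mask_2d(two_days).any()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            acc.nonwear_mask_2d(np.full((1, 1440), -1))


class TestIntensity:
    @pytest.mark.parametrize(
        ("cpm", "category"),
        [
            (0, "sedentary"),
            (100, "sedentary"),
            (101, "light"),
            (2020, "light"),
            (2021, "moderate"),
            (5999, "moderate"),
            (6000, "vigorous"),
            (20000, "vigorous"),
        ],
    )
    def test_cutpoint_boundaries(self, cpm, category):
        assert acc.classify_intensity(cpm) == category

    def test_exhaustive_partition_over_integer_cpm(self):
        cats = acc.classify_intensity(np.arange(0, 7001))
        counts = {c: int((cats == c).sum()) for c in acc.INTENSITY_CATEGORIES}
        assert counts == {"sedentary": 101, "light": 1920, "moderate": 3979, "vigorous": 1001}

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            acc.classify_intensity(-1)


class TestMets:
    @pytest.mark.parametrize(
        ("cpm", "expected", "digits"),
        [(0, 1.439, 3), (313, 1.69, 2), (702, 2.00, 2)],
    )
    def test_known_values(self, cpm, expected, digits):
        assert round(acc.counts_to_mets(cpm), digits) == pytest.approx(expected)

    def test_monotone_and_affine(self, rng):
        cpm = np.sort(rng.integers(0, 8000, 100))
        mets = acc.counts_to_mets(cpm)
        assert (np.diff(mets) >= 0).all()
        assert np.allclose(mets, 1.439008 + 0.000795 * cpm)


class TestDaySummary:
    @staticmethod
    def _day(worn_minutes: int, cpm: int) -> tuple[acc.EpochSeries, acc.WearMask]:
        counts = np.zeros(1440, dtype=int)
        counts[:worn_minutes] = cpm
        s = series(counts)
        return s, acc.detect_nonwear(s)

    def test_valid_day_boundary(self):
        s, m = self._day(600, 313)
        assert acc.summarize_day(s, m, DAY).valid
        s, m = self._day(599, 313)
        assert not acc.summarize_day(s, m, DAY).valid

    def test_constant_day_means(self):
        s, m = self._day(600, 313)
        d = acc.summarize_day(s, m, DAY)
        assert d.wear_minutes == 600
        assert d.mean_cpm == pytest.approx(313.0)
        assert round(d.day_mets, 2) == pytest.approx(1.69)
        assert d.intensity_minutes["light"] == 600

    def test_all_worn_zero_minutes_floor(self):
        # zeros can only be worn in runs < 60; force the floor case with an
        # explicit mask marking only zero minutes as worn
        counts = np.ones(1440, dtype=int)
        counts[0:59] = 0
        s = series(counts)
        mask = acc.WearMask(worn=(s.counts == 0))
        d = acc.summarize_day(s, mask, DAY)
        assert d.mean_cpm == pytest.approx(0.0)
        assert d.day_mets == pytest.approx(1.439008)
        assert d.intensity_minutes["sedentary"] == d.wear_minutes == 59

    def test_intensity_minutes_partition_wear(self, rng):
        counts = rng.integers(0, 7000, (5, 1440))
        frame = acc.day_metrics_frame(counts)
        total = frame[list(acc.INTENSITY_CATEGORIES)].sum(axis=1)
        assert (total == frame["wear_minutes"]).all()

    def test_raising_one_epoch_never_decreases_means(self, rng):
        counts = rng.integers(1, 1000, 1440)
        base = acc.day_metrics_frame(counts[None, :]).iloc[0]
        bumped = counts.copy()
        bumped[rng.integers(0, 1440)] += 500
        after = acc.day_metrics_frame(bumped[None, :]).iloc[0]
        assert after["mean_cpm"] >= base["mean_cpm"]
        assert after["day_mets"] >= base["day_mets"]


class TestParticipantSummary:
    @staticmethod
    def _metrics(valid_days: int, invalid_days: int, cpm: float = 313.0):
        rows = []
        for i in range(valid_days + invalid_days):
            valid = i < valid_days
            rows.append(
                acc.DayMetrics(
                    date=DAY,
                    valid=valid,
                    wear_minutes=700 if valid else 100,
                    mean_cpm=cpm if valid else 5000.0,
                    intensity_minutes={"sedentary": 100 if valid else 0},
                    day_mets=acc.counts_to_mets(cpm if valid else 5000.0),
                )
            )
        return rows

    def test_identical_days_are_idempotent(self):
        summary = acc.summarize_participant(self._metrics(7, 0))
        assert summary.acc_cpm == pytest.approx(313.0)
        assert summary.acc_mets == pytest.approx(acc.counts_to_mets(313.0))
        assert summary.acc_pamin == pytest.approx(600.0)
        assert summary.n_valid_days == 7

    def test_invalid_days_excluded_from_average(self):
        summary = acc.summarize_participant(self._metrics(4, 3))
        assert summary.n_valid_days == 4
        assert summary.acc_cpm == pytest.approx(313.0)  # untouched by invalid 5000s

    def test_too_few_valid_days_raises(self):
        with pytest.raises(QualityControlError, match="3 valid"):
            acc.summarize_participant(self._metrics(3, 4))


def test_mean_affine_consistency_on_random_streams(rng):
    # averaging commutes with the affine counts->MET map
    counts = rng.integers(0, 4000, (20, 1440))
    counts[:, :300] = 0  # an overnight nonwear block
    frame = acc.day_metrics_frame(counts)
    assert np.allclose(
        frame["day_mets"], 1.439008 + 0.000795 * frame["mean_cpm"], atol=1e-9, rtol=0
    )
    summary = acc.summarize_participant(frame)
    assert summary.acc_mets == pytest.approx(
        1.439008 + 0.000795 * summary.acc_cpm, abs=1e-9
    )


def test_series_validation():
    with pytest.raises(ValidationError):
        acc.EpochSeries("P1", DAY, np.zeros((2, 100)))
    with pytest.raises(ValidationError):
        acc.EpochSeries("P1", DAY, -np.ones((1, 1440)))
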