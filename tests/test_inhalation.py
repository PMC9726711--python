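"""Inhalation dose formula, sheltering modes and short-lived corrections."""

from datetime import date, datetime

import numpy as np
import pytest

from tedrecon.inhalation import (
    DoseResult,
    ExposureParameters,
    ShortLivedCorrection,
    apply_short_lived_correction,
    band_age,
    inhalation_ted,
    per_day_breakdown,
)
from tedrecon.plume import HourlyExposureSeries
from tedrecon.trajectory import MicroEnv


def params(v=24.0, e_p=1.0e-3, e_el=0.0, e_met=0.0, fc=0.62, df=0.5, **kw):
    return ExposureParameters(
        v_m3_per_day=v,
        e_inhal={"particulate": e_p, "elemental": e_el, "methyl": e_met},
        e_ingest=3.75e-3,
        ptwi_m3_per_day=9.2e-4,
        fc=fc,
        df_shelter=df,
        **kw,
    )


def constant_series(c_p=1.0, c_el=0.0, c_met=0.0, n=330):
    vals = np.tile([c_p, c_el, c_met], (n, 1))
    return HourlyExposureSeries("p", vals)


class TestInhalationFormula:
    def test_null_exposure_gives_zero_dose(self):
        _, total = inhalation_ted(constant_series(0.0), params())
        assert total == 0.0

    def test_closed_form_hand_evaluation(self):
        # V/24 = 1; 330 h of 1 Bq/m3 particulate at 1e-3 mSv/Bq, FC 0.62, DF 0.5
        _, total = inhalation_ted(constant_series(1.0), params())
        assert total == pytest.approx(330 * 1e-3 * 0.62 * 0.5, rel=1e-12)
        assert total == pytest.approx(0.1023, rel=1e-12)

    def test_doubling_concentrations_doubles_dose(self):
        _, t1 = inhalation_ted(constant_series(1.0, 2.0, 3.0), params(e_el=2e-3, e_met=5e-4))
        _, t2 = inhalation_ted(constant_series(2.0, 4.0, 6.0), params(e_el=2e-3, e_met=5e-4))
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_homogeneous_in_v_fc_df(self):
        base = params()
        _, t0 = inhalation_ted(constant_series(1.0), base)
        _, tv = inhalation_ted(constant_series(1.0), params(v=48.0))
        _, tf = inhalation_ted(constant_series(1.0), params(fc=1.24))
        _, td = inhalation_ted(constant_series(1.0), params(df=0.25))
        assert tv == pytest.approx(2 * t0, rel=1e-12)
        assert tf == pytest.approx(2 * t0, rel=1e-12)
        assert td == pytest.approx(0.5 * t0, rel=1e-12)

    def test_monotone_in_each_hourly_concentration(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, size=(330, 3))
        p = params(e_el=2e-3, e_met=5e-4)
        _, t0 = inhalation_ted(HourlyExposureSeries("p", vals), p)
        bumped = vals.copy()
        bumped[177, 1] += 10.0
        _, t1 = inhalation_ted(HourlyExposureSeries("p", bumped), p)
        assert t1 > t0

    def test_agrees_with_naive_hourly_loop(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0, 1e4, size=(330, 3))
        p = params(v=5.16, e_p=1.4e-3, e_el=3.2e-3, e_met=2.6e-3)
        per_hour, total = inhalation_ted(HourlyExposureSeries("p", vals), p)
        e = [p.e_inhal["particulate"], p.e_inhal["elemental"], p.e_inhal["methyl"]]
        expected = [
            (p.v_m3_per_day / 24.0)
            * (vals[i, 0] * e[0] + vals[i, 1] * e[1] + vals[i, 2] * e[2])
            * p.fc
            * p.df_shelter
            for i in range(330)
        ]
        np.testing.assert_allclose(per_hour, expected, rtol=1e-12)
        assert total == pytest.approx(sum(expected), rel=1e-12)

    def test_per_hour_df_mode_leaves_outdoor_unsheltered(self):
        env = [MicroEnv.OUTDOOR] * 100 + [MicroEnv.INDOOR] * 130 + [MicroEnv.VEHICLE] * 100
        per_hour, _ = inhalation_ted(constant_series(1.0), params(), env, df_mode="per_hour")
        assert per_hour[0] == pytest.approx(2 * per_hour[150], rel=1e-12)  # DF 0.5 indoors
        assert per_hour[250] == pytest.approx(per_hour[150], rel=1e-12)  # vehicle sheltered

    def test_wrong_length_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            inhalation_ted(constant_series(1.0, n=100), params())


class TestShortLivedCorrection:
    def test_dose_in_first_window_scaled_by_1_59(self, window):
        correction = ShortLivedCorrection(
            ((date(2011, 3, 12), date(2011, 3, 13), 1.59), (date(2011, 3, 15), date(2011, 3, 16), 1.08))
        )
        per_hour = np.zeros(330)
        # 12-13 March: window hours 1..42 (06:00 of 12 Mar to 24:00 of 13 Mar)
        per_hour[:42] = 2.0 / 42
        _, total = apply_short_lived_correction(per_hour, correction, window)
        assert total == pytest.approx(2.0 * 1.59, rel=1e-12)

    def test_dose_outside_windows_unchanged(self, window):
        correction = ShortLivedCorrection(((date(2011, 3, 12), date(2011, 3, 13), 1.59),))
        per_hour = np.zeros(330)
        i = window.hour_index_of(datetime(2011, 3, 20, 12, 0))
        per_hour[i - 1] = 5.0
        _, total = apply_short_lived_correction(per_hour, correction, window)
        assert total == pytest.approx(5.0, rel=1e-12)

    def test_split_dose_across_both_windows(self, window):
        correction = ShortLivedCorrection(
            ((date(2011, 3, 12), date(2011, 3, 13), 1.59), (date(2011, 3, 15), date(2011, 3, 16), 1.08))
        )
        per_hour = np.zeros(330)
        per_hour[10] = 1.0  # 12 March
        i15 = window.hour_index_of(datetime(2011, 3, 15, 12, 0))
        per_hour[i15 - 1] = 1.0
        _, total = apply_short_lived_correction(per_hour, correction, window)
        assert total == pytest.approx(1.59 + 1.08, rel=1e-12)

    def test_unit_factors_reproduce_uncorrected_total(self, window):
        correction = ShortLivedCorrection(((date(2011, 3, 12), date(2011, 3, 13), 1.0),))
        rng = np.random.default_rng(1)
        per_hour = rng.uniform(0, 1, 330)
        corrected, total = apply_short_lived_correction(per_hour, correction, window)
        np.testing.assert_array_equal(corrected, per_hour)
        assert total == per_hour.sum()

    def test_overlapping_windows_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            ShortLivedCorrection(
                ((date(2011, 3, 12), date(2011, 3, 15), 1.59), (date(2011, 3, 14), date(2011, 3, 16), 1.08))
            )

    def test_per_day_breakdown_sums_to_total(self, window):
        rng = np.random.default_rng(2)
        per_hour = rng.uniform(0, 1, 330)
        daily = per_day_breakdown(per_hour, window)
        assert len(daily) == 14  # 12..25 March
        assert daily.sum() == pytest.approx(per_hour.sum(), rel=1e-12)
        assert daily.index[0] == date(2011, 3, 12)


class TestAgeHandling:
    @pytest.mark.parametrize(
        "age,group",
        [(0, 1), (1, 1), (2, 1), (3, 5), (7, 5), (8, 10), (12, 10), (13, 15), (17, 15), (18, 20), (45, 20)],
    )
    def test_half_open_age_banding(self, age, group):
        assert band_age(age) == group

    def test_missing_age_group_error_names_group(self, coefficients):
        broken = type(coefficients)(
            {g: p for g, p in coefficients.by_group.items() if g != 10}, coefficients.sf_by_group
        )
        with pytest.raises(KeyError, match="10"):
            broken.params_for_age(9)

    def test_default_table_covers_reporting_grid(self, coefficients):
        for age in (1, 5, 10, 15, 20):
            p = coefficients.params_for_age(age)
            assert p.fc == pytest.approx(18.6 / 30)
            assert set(p.e_inhal) == {"particulate", "elemental", "methyl"}

    def test_sf_fallback_to_age_1(self, coefficients):
        sf = coefficients.sf_for_age(10)
        assert sf.factor_for(date(2011, 3, 12)) == 1.59
        assert sf.factor_for(date(2011, 3, 16)) == 1.08
        assert sf.factor_for(date(2011, 3, 20)) == 1.0


class TestDoseResult:
    def test_total_is_sum_of_components(self):
        r = DoseResult("p", 1, 1.5, 0.25)
        assert r.ted_total == pytest.approx(1.75)

    def test_negative_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseResult("p", 1, -0.1, 0.0)
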