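"""Score engine: formulas, classification, panel composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from steatoscore import (
    AdiposityCutoffs,
    ScoreThresholds,
    classify_adiposity,
    classify_score,
    compute_bmi,
    convert_mgdl_to_mmol,
    fld,
    fli,
    friedewald_ldl,
    hsi,
    lap,
    score_cohort,
    score_panel,
    zju,
)
from steatoscore.errors import ConfigurationError, DomainError, ValidityError

finite_pos = st.floats(0.5, 500.0)


class TestBasics:
    @pytest.mark.parametrize("weight,height,expected", [
        (81.2, 175.8, 26.27),   # male cohort means
        (100.0, 200.0, 25.0),
        (63.9, 162.5, 24.20),   # female cohort means
    ])
    def test_bmi(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(DomainError, match="height"):
            compute_bmi(70, 0)
        with pytest.raises(DomainError, match="weight"):
            compute_bmi(-1, 170)

    @pytest.mark.parametrize("value,analyte,expected", [
        (88.57, "triglycerides", 1.0),
        (18.016, "glucose", 1.0),
        (107.8, "triglycerides", 1.217),
    ])
    def test_unit_conversion(self, value, analyte, expected):
        assert convert_mgdl_to_mmol(value, analyte) == pytest.approx(
            expected, abs=5e-4)

    def test_unknown_analyte(self):
        with pytest.raises(DomainError, match="analyte"):
            convert_mgdl_to_mmol(100, "cholesterol")

    @pytest.mark.parametrize("tc,hdl,tg,expected", [
        (200, 50, 100, 130.0),
        (191.8, 49.2, 107.8, 121.04),  # male cohort means
    ])
    def test_friedewald(self, tc, hdl, tg, expected):
        assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected)

    def test_friedewald_invalid_above_400(self):
        with pytest.raises(ValidityError):
            friedewald_ldl(150, 50, 500)

    def test_friedewald_negative_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert friedewald_ldl(100, 60, 300) == pytest.approx(-20.0)

    @given(tc=finite_pos, hdl=finite_pos, tg=st.floats(0.5, 400.0))
    @settings(max_examples=50, derandomize=True)
    def test_friedewald_roundtrip_conservation(self, tc, hdl, tg):
        assert friedewald_ldl(tc, hdl, tg) + hdl + tg / 5.0 == pytest.approx(
            tc, rel=1e-12)


class TestFli:
    def test_reference_point(self):
        # independent oracle: high-precision evaluation of the linear
        # predictor, then the logistic
        L = (0.953 * np.log(100) + 0.139 * 25 + 0.718 * np.log(30)
             + 0.053 * 90 - 15.745)
        expected = 100.0 * np.exp(L) / (1 + np.exp(L))
        assert fli(100, 25, 30, 90) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(33.87, abs=0.05)

    def test_lower_limit_as_tg_vanishes(self):
        assert fli(1e-12, 25, 30, 90) < 1e-6

    @given(tg=finite_pos, bmi=st.floats(10, 60), ggt=finite_pos,
           wc=st.floats(40, 160))
    @settings(max_examples=100, derandomize=True)
    def test_range_open_zero_hundred(self, tg, bmi, ggt, wc):
        value = fli(tg, bmi, ggt, wc)
        assert 0.0 < value < 100.0

    @given(tg=finite_pos, bmi=st.floats(10, 60), ggt=finite_pos,
           wc=st.floats(40, 160), bump=st.floats(0.1, 20))
    @settings(max_examples=60, derandomize=True)
    def test_strictly_increasing_each_argument(self, tg, bmi, ggt, wc, bump):
        base = fli(tg, bmi, ggt, wc)
        assert fli(tg + bump, bmi, ggt, wc) > base
        assert fli(tg, bmi + bump, ggt, wc) > base
        assert fli(tg, bmi, ggt + bump, wc) > base
        assert fli(tg, bmi, ggt, wc + bump) > base

    def test_log_domain_errors(self):
        with pytest.raises(DomainError):
            fli(0, 25, 30, 90)
        with pytest.raises(DomainError):
            fli(100, 25, 0, 90)


class TestLinearScores:
    def test_hsi_trivial_points(self):
        assert hsi(20, 20, 25, False, False) == pytest.approx(33.0)
        assert hsi(20, 20, 25, True, True) == pytest.approx(37.0)
        assert hsi(29.3, 24.4, 26.2735, False, False) == pytest.approx(
            35.88, abs=0.01)

    def test_zju_trivial_points(self):
        assert zju(25, 90.08, 88.57, 10, 10, False) == pytest.approx(34.0)
        assert zju(25, 90.08, 88.57, 10, 10, True) == pytest.approx(36.0)
        # male cohort means, exact arithmetic through the conversions
        expected = (26.273522 + 93.4 / 18.016 + 107.8 / 88.57
                    + 3 * 29.3 / 24.4)
        assert zju(26.273522, 93.4, 107.8, 29.3, 24.4, False) == pytest.approx(
            expected, rel=1e-6)

    def test_fld_trivial_points(self):
        assert fld(25, 88.57, 10, 10, False) == pytest.approx(29.0)
        assert fld(25, 88.57, 10, 10, True) == pytest.approx(31.0)
        assert fld(24.1995, 81.5, 17.3, 18.2, False) == pytest.approx(
            27.97, abs=0.01)

    def test_lap_reference_points(self):
        assert lap(66, 88.57, "male") == pytest.approx(1.0)
        assert lap(58, 177.14, "female") == pytest.approx(0.0)
        assert lap(89.8, 107.8, "male") == pytest.approx(30.18, abs=0.01)

    def test_lap_negative_returned_with_warning(self):
        with pytest.warns(UserWarning, match="negative LAP"):
            assert lap(60, 88.57, "male") == pytest.approx(-5.0)

    def test_ast_zero_domain_error(self):
        for fn in (lambda: hsi(20, 0, 25, False, False),
                   lambda: zju(25, 90, 88, 20, 0, False),
                   lambda: fld(25, 88, 20, 0, False)):
            with pytest.raises(DomainError):
                fn()

    @given(bmi=st.floats(15, 45), delta=st.floats(0.1, 10),
           alt=finite_pos, ast=finite_pos, tg=finite_pos,
           glucose=st.floats(50, 300))
    @settings(max_examples=60, derandomize=True)
    def test_unit_slope_in_bmi(self, bmi, delta, alt, ast, tg, glucose):
        """HSI/ZJU/FLD are affine in BMI with slope exactly one."""
        assert hsi(alt, ast, bmi + delta, False, False) - hsi(
            alt, ast, bmi, False, False) == pytest.approx(delta, rel=1e-9)
        assert zju(bmi + delta, glucose, tg, alt, ast, False) - zju(
            bmi, glucose, tg, alt, ast, False) == pytest.approx(delta, rel=1e-9)
        assert fld(bmi + delta, tg, alt, ast, False) - fld(
            bmi, tg, alt, ast, False) == pytest.approx(delta, rel=1e-9)

    @given(bmi=st.floats(15, 45), alt=finite_pos, ast=finite_pos,
           tg=finite_pos, glucose=st.floats(50, 300))
    @settings(max_examples=60, derandomize=True)
    def test_female_offset_exactly_two(self, bmi, alt, ast, tg, glucose):
        assert hsi(alt, ast, bmi, False, True) - hsi(
            alt, ast, bmi, False, False) == pytest.approx(2.0, abs=1e-12)
        assert zju(bmi, glucose, tg, alt, ast, True) - zju(
            bmi, glucose, tg, alt, ast, False) == pytest.approx(2.0, abs=1e-12)

    @given(wc=st.floats(40, 160), tg=finite_pos)
    @settings(max_examples=60, derandomize=True)
    def test_lap_linear_in_tg_with_zero_at_offset(self, wc, tg):
        tg_mmol = tg / 88.57
        assert lap(wc, tg, "male") == pytest.approx((wc - 65) * tg_mmol,
                                                    rel=1e-9, abs=1e-12)
        assert lap(65.0, tg, "male") == pytest.approx(0.0, abs=1e-12)
        assert lap(58.0, tg, "female") == pytest.approx(0.0, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("score,scale,expected", [
        (60.0, "fli", "high"),      # boundary is inclusive
        (59.999, "fli", "moderate"),
        (29.999, "fli", "low"),
        (42.69, "lap", "low"),
        (42.7, "lap", "high"),
        (36.0, "hsi", "high"),
        (38.0, "zju", "high"),
        (37.0, "fld", "high"),
        (35.0, "hsi", "moderate"),
    ])
    def test_tiers(self, score, scale, expected):
        assert classify_score(score, scale) == expected

    def test_partition_over_cohort(self, small_cohort):
        panel, _ = score_cohort(small_cohort)
        for scale in ("fli", "hsi", "zju", "fld", "lap"):
            counts = panel[f"{scale}_category"].value_counts()
            assert counts.sum() == len(panel)
            assert set(counts.index) <= {"low", "moderate", "high"}

    def test_threshold_validation(self):
        with pytest.raises(ConfigurationError):
            ScoreThresholds(fli_low_upper=70.0)  # low boundary above high

    def test_adiposity_boundaries(self, male_means_record):
        rec = male_means_record
        rec.visceral_fat_rating = 10
        assert classify_adiposity(rec)[1] is True
        rec.visceral_fat_rating = 9.9
        assert classify_adiposity(rec)[1] is False

    def test_high_body_fat_female_default_table(self, female_means_record):
        rec = female_means_record
        rec.age, rec.body_fat_pct = 40, 45.0
        assert classify_adiposity(rec)[0] is True

    def test_body_fat_table_must_cover_age_range(self):
        with pytest.raises(ConfigurationError):
            AdiposityCutoffs(body_fat_high={("male", 18, 39): 25.0,
                                            ("female", 18, 69): 39.0})


class TestPanel:
    def test_male_means_panel(self, male_means_record):
        panel = score_panel(male_means_record)
        assert panel.fli == pytest.approx(40.2, abs=0.1)
        assert panel.hsi == pytest.approx(35.88, abs=0.01)
        assert panel.zju == pytest.approx(36.28, abs=0.01)
        assert panel.fld == pytest.approx(31.1, abs=0.1)
        assert panel.lap == pytest.approx(30.18, abs=0.01)
        assert panel.bmi == pytest.approx(26.27, abs=0.005)
        assert panel.ldl == pytest.approx(121.04)  # Friedewald fill
        assert panel.hsi_category == "moderate"
        assert panel.high_visceral_fat is False

    def test_cohort_continues_past_bad_rows(self, small_cohort):
        cohort = small_cohort.copy()
        cohort.loc[cohort.index[3], "ast"] = 0.0
        cohort.loc[cohort.index[5], "ggt"] = -1.0
        panel, errors = score_cohort(cohort)
        assert len(panel) == len(cohort) - 2
        assert set(errors["row"]) == {cohort.index[3], cohort.index[5]}

    def test_ldl_left_missing_when_tg_above_400(self, small_cohort):
        cohort = small_cohort.copy().drop(columns=["ldl"], errors="ignore")
        cohort["triglycerides"] = 120.0
        cohort.loc[cohort.index[0], "triglycerides"] = 450.0
        panel, _ = score_cohort(cohort)
        assert np.isnan(panel.loc[panel.index[0], "ldl"])
        assert panel["ldl"].notna().sum() == len(panel) - 1

    def test_vectorised_panel_matches_scalar(self, small_cohort):
        sub = small_cohort.head(20)
        panel, _ = score_cohort(sub)
        from steatoscore.records import record_from_row
        for idx, row in sub.iterrows():
            scalar = score_panel(record_from_row(row.to_dict()))
            for scale in ("fli", "hsi", "zju", "fld", "lap"):
                assert panel.loc[idx, scale] == pytest.approx(
                    getattr(scalar, scale), rel=1e-12)
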