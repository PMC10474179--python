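import math

import numpy as np
import pandas as pd
import pytest

from dtialps import classify_ckd, derive_covariates, derive_table, metabolic_syndrome


def _record(**kw):
    base = {"sex": "male"}
    base.update(kw)
    return base


class TestMetabolicSyndrome:
    def test_boundary_reading_of_cutoffs(self):
        # waist 90 (>=), SBP 130 (>=), sugar 100 (>=) positive;
        # HDL 40 negative for a male (< 40 is false at 40); TG 149 negative
        status, n = metabolic_syndrome(
            _record(waist=90, systolic_bp=130, diastolic_bp=70,
                    fasting_glucose=100, hdl=40, tg=149)
        )
        assert status is True and n == 3

    def test_female_cutoffs_differ(self):
        # waist 85 and HDL 45: negative for males, positive for females
        male = metabolic_syndrome(_record(sex="male", waist=85, hdl=45,
                                          systolic_bp=120, diastolic_bp=70,
                                          fasting_glucose=90, tg=100))
        female = metabolic_syndrome(_record(sex="female", waist=85, hdl=45,
                                            systolic_bp=120, diastolic_bp=70,
                                            fasting_glucose=90, tg=100))
        assert male == (False, 0)
        assert female == (False, 2)

    def test_all_normal_female(self):
        status, n = metabolic_syndrome(
            _record(sex="female", waist=70, systolic_bp=110, diastolic_bp=70,
                    fasting_glucose=85, hdl=65, tg=90)
        )
        assert status is False and n == 0

    def test_dbp_alone_triggers_bp_criterion(self):
        status, n = metabolic_syndrome(
            _record(waist=95, systolic_bp=120, diastolic_bp=85,
                    fasting_glucose=105, hdl=50, tg=100)
        )
        assert status is True and n == 3

    def test_indeterminate_when_missing_can_flip_outcome(self):
        # two positives, two unknowns: could reach 3 or stay at 2
        status, n = metabolic_syndrome(
            _record(waist=95, systolic_bp=140, diastolic_bp=90, hdl=50, tg=100)
        )
        assert status is None and n == 2

    def test_forced_false_despite_missing(self):
        # one unknown but at most 2 criteria can ever be positive
        status, _ = metabolic_syndrome(
            _record(waist=70, systolic_bp=110, diastolic_bp=70, hdl=60, tg=300)
        )
        assert status is False

    def test_missing_sex_makes_sexed_criteria_unevaluable(self):
        status, n = metabolic_syndrome(
            {"waist": 95, "hdl": 30, "systolic_bp": 140, "diastolic_bp": 90,
             "fasting_glucose": 110, "tg": 200}
        )
        # sexed criteria unknown but the three unsexed positives force True
        assert status is True and n == 3

    def test_monotone_in_single_inputs(self, rng):
        """Worsening any input never decreases the positive count."""
        worse = {
            "waist": +5, "systolic_bp": +10, "diastolic_bp": +5,
            "fasting_glucose": +15, "hdl": -10, "tg": +40,
        }
        for _ in range(200):
            rec = _record(
                sex=rng.choice(["male", "female"]),
                waist=rng.uniform(60, 110),
                systolic_bp=rng.uniform(95, 165),
                diastolic_bp=rng.uniform(55, 100),
                fasting_glucose=rng.uniform(70, 140),
                hdl=rng.uniform(25, 75),
                tg=rng.uniform(50, 250),
            )
            _, n0 = metabolic_syndrome(rec)
            for key, delta in worse.items():
                bumped = dict(rec)
                bumped[key] = rec[key] + delta
                _, n1 = metabolic_syndrome(bumped)
                assert n1 >= n0

    def test_against_independent_rule_table(self, rng):
        """200 random records vs. a hand-coded truth table of the rule."""
        for _ in range(200):
            sex = rng.choice(["male", "female"])
            rec = _record(
                sex=sex,
                waist=rng.uniform(60, 110),
                systolic_bp=rng.uniform(95, 165),
                diastolic_bp=rng.uniform(55, 100),
                fasting_glucose=rng.uniform(70, 140),
                hdl=rng.uniform(25, 75),
                tg=rng.uniform(50, 250),
            )
            hits = [
                rec["waist"] >= (90 if sex == "male" else 80),
                rec["systolic_bp"] >= 130 or rec["diastolic_bp"] >= 85,
                rec["fasting_glucose"] >= 100,
                rec["hdl"] < (40 if sex == "male" else 50),
                rec["tg"] >= 150,
            ]
            status, n = metabolic_syndrome(rec)
            assert n == sum(hits)
            assert status is (sum(hits) >= 3)


class TestCKD:
    @pytest.mark.parametrize(
        "record, expected",
        [
            ({"egfr": 59.9}, True),
            ({"egfr": 60.0, "albumin_creatinine_ratio": 30.0}, True),
            ({"egfr": 75, "urine_protein_grade": 0.5,
              "albumin_creatinine_ratio": 10, "protein_creatinine_ratio": 100}, False),
            ({"urine_protein_grade": 1.0}, True),
            ({"protein_creatinine_ratio": 150.0}, True),
            ({"egfr": 90.0}, False),
            ({}, None),
            ({"egfr": float("nan")}, None),
        ],
    )
    def test_rule_boundaries(self, record, expected):
        assert classify_ckd(record) is expected


class TestDerivedCovariates:
    def test_bmi_overweight_boundary(self):
        flags = derive_covariates({"height": 1.60, "weight": 64.0})
        assert flags.bmi == pytest.approx(25.0)
        # the >= boundary itself, on values exact in binary arithmetic
        assert derive_covariates({"height": 2.0, "weight": 100.0}).overweight is True

    def test_ratio_and_anion_gap_arithmetic(self):
        flags = derive_covariates(
            {"tchol": 200.0, "hdl": 50.0, "bun": 18.0, "creatinine": 0.9,
             "sodium": 140.0, "chloride": 104.0, "bicarbonate": 24.0}
        )
        assert flags.tchol_hdl_ratio == pytest.approx(4.0)
        assert flags.bun_cr_ratio == pytest.approx(20.0)
        assert flags.anion_gap_est == pytest.approx(12.0)

    def test_missing_inputs_yield_nan_not_zero(self):
        flags = derive_covariates({"tchol": 200.0})
        assert math.isnan(flags.tchol_hdl_ratio)
        assert math.isnan(flags.bmi)
        assert flags.overweight is None

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError, match="height"):
            derive_covariates({"height": 0.0, "weight": 70.0})

    def test_idempotent_and_order_independent(self):
        rec = {"height": 1.7, "weight": 80, "sex": "female", "waist": 85,
               "systolic_bp": 135, "diastolic_bp": 80, "fasting_glucose": 101,
               "hdl": 45, "tg": 160, "egfr": 70}
        a = derive_covariates(rec)
        b = derive_covariates(dict(reversed(list(rec.items()))))
        assert a == b == derive_covariates(rec)


def test_derive_table_propagates_indeterminate_as_missing():
    df = pd.DataFrame(
        [
            {"sex": "male", "height": 1.7, "weight": 80.0, "egfr": 55.0},
            {"sex": "female", "height": 1.6, "weight": np.nan, "egfr": np.nan},
        ]
    )
    out = derive_table(df)
    assert out.loc[0, "ckd"] == True  # noqa: E712  (pandas BooleanDtype)
    assert pd.isna(out.loc[1, "ckd"])
    assert pd.isna(out.loc[1, "overweight"])
    assert out.loc[0, "bmi"] == pytest.approx(80.0 / 1.7**2)


def test_derive_table_column_map():
    df = pd.DataFrame([{"hgt": 1.6, "wgt": 64.0}])
    out = derive_table(df, column_map={"hgt": "height", "wgt": "weight"})
    assert out.loc[0, "bmi"] == pytest.approx(25.0)
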