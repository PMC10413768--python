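import dataclasses
import math

import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from reekit.config import Settings
from reekit.equations import (
    Cohort,
    EnergyUnit,
    EQUATION_IDS,
    Sex,
    Subject,
    convert_energy,
    equation_registry,
    get_equation,
    predict_all,
    predict_ree,
)
from reekit.exceptions import (
    ConfigurationError,
    DispatchError,
    DomainError,
    InapplicableError,
)

from equation_fixtures import HAND_CASES


def make_subject(sex="male", age=12.0, weight=60.0, height=150.0, **kw):
    return Subject(id=kw.pop("id", "s1"), sex=sex, age=age, weight=weight,
                   height=height, **kw)


# ---------------------------------------------------------------------------
# convert_energy
# ---------------------------------------------------------------------------

class TestConvertEnergy:
    def test_kj_to_kcal(self):
        assert convert_energy(4184.0, "kJ_per_day", "kcal_per_day") == pytest.approx(1000.0)

    def test_mj_to_kcal(self):
        assert convert_energy(1.0, "MJ_per_day", "kcal_per_day") == pytest.approx(1000.0 / 4.184)

    @pytest.mark.parametrize("unit", ["kcal_per_day", "kJ_per_day", "MJ_per_day"])
    def test_zero(self, unit):
        assert convert_energy(0.0, unit, "kcal_per_day") == 0.0

    def test_unknown_unit(self):
        with pytest.raises(ConfigurationError):
            convert_energy(1.0, "cal_per_day", "kcal_per_day")

    @given(
        value=st.floats(min_value=1e-3, max_value=1e6),
        a=st.sampled_from(list(EnergyUnit)),
        b=st.sampled_from(list(EnergyUnit)),
    )
    def test_round_trip(self, value, a, b):
        back = convert_energy(convert_energy(value, a, b), b, a)
        assert back == pytest.approx(value, rel=1e-12)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class TestRegistry:
    def test_size_is_14(self, registry):
        assert len(registry) == 14

    def test_ids(self, registry):
        assert set(EQUATION_IDS) == {
            "who", "schofield", "iom", "kim", "henry", "molnar", "muller_a",
            "muller_b", "derumeaux_burel", "schmelzle", "tverskaya",
            "lazzer_a", "lazzer_b", "new_ffm",
        }

    def test_lazzer_a_native_unit_and_height_meters(self):
        spec = get_equation("lazzer_a")
        assert spec.native_unit is EnergyUnit.kJ_per_day
        assert "height_m" in spec.variants[0].coefficients

    def test_tverskaya_sex_code(self):
        spec = get_equation("tverskaya")
        assert spec.sex_code[Sex.male] == 1
        assert spec.sex_code[Sex.female] == 0

    def test_muller_sex_code_as_printed(self):
        # printed male=0/female=1 even though the original publication differs
        for eq in ("muller_a", "muller_b"):
            spec = get_equation(eq)
            assert spec.sex_code[Sex.male] == 0
            assert spec.sex_code[Sex.female] == 1

    def test_registry_immutable(self, registry):
        assert equation_registry() is registry
        with pytest.raises(dataclasses.FrozenInstanceError):
            registry[0].equation_id = "other"

    def test_every_sex_code_maps_both_sexes(self, registry):
        for spec in registry:
            assert set(spec.sex_code) == {Sex.male, Sex.female}

    def test_spec_json_round_trip(self, registry):
        from reekit.equations import EquationSpec

        for spec in registry:
            assert EquationSpec.from_dict(spec.to_dict()) == spec


# ---------------------------------------------------------------------------
# predict_ree: hand-computed fixtures and dispatch
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "case", HAND_CASES, ids=[f"{c['eq']}-{c['sex']}-{c['age']}" for c in HAND_CASES]
)
def test_hand_computed_point(case):
    subject = make_subject(
        sex=case["sex"], age=case["age"], weight=case["weight"],
        height=case["height"], fat_free_mass=case["ffm"], fat_mass=case["fm"],
    )
    pred = predict_ree(get_equation(case["eq"]), subject)
    assert pred.predicted_ree == pytest.approx(case["expected"], abs=0.01)


def test_prediction_consistency_native_vs_kcal():
    subject = make_subject(sex="female", age=12, fat_free_mass=35.0, fat_mass=15.0)
    pred = predict_ree(get_equation("muller_b"), subject)
    assert pred.predicted_ree == pytest.approx(
        convert_energy(pred.native_value, pred.native_unit, "kcal_per_day")
    )


class TestDispatch:
    @pytest.mark.parametrize("eq", ["who", "schofield", "henry"])
    def test_child_variant_below_10(self, eq):
        child = predict_ree(get_equation(eq), make_subject(age=8.0, weight=30, height=130))
        teen = predict_ree(get_equation(eq), make_subject(age=10.0, weight=30, height=130))
        assert child.predicted_ree != teen.predicted_ree

    def test_boundary_age_10_uses_adolescent_variant(self):
        # WHO male 10-18: 18.4*WT + 651
        pred = predict_ree(get_equation("who"), make_subject(age=10.0, weight=30))
        assert pred.predicted_ree == pytest.approx(18.4 * 30 + 651)

    def test_boundary_flip_setting(self):
        flipped = Settings(age_boundary_to_lower=True)
        pred = predict_ree(get_equation("who"), make_subject(age=10.0, weight=30), flipped)
        assert pred.predicted_ree == pytest.approx(22.7 * 30 + 495)  # child variant

    @given(age=st.floats(min_value=3, max_value=18), sex=st.sampled_from(list(Sex)))
    def test_dispatch_total_and_unambiguous(self, age, sex):
        subject = make_subject(sex=sex, age=age, weight=40, height=140,
                               fat_free_mass=30, fat_mass=10)
        for spec in equation_registry():
            matches = [
                v for v in spec.variants
                if v.sex in (None, subject.sex) and v.age_lo <= age < v.age_hi
            ]
            assert len(matches) <= 1
            predict_ree(spec, subject)  # total: always evaluates

    def test_out_of_range_flagged_not_refused(self):
        # 17-year-old under Kim (4-11): evaluated with the printed formula, flagged
        subject = make_subject(age=17.0, weight=60, height=170)
        pred = predict_ree(get_equation("kim"), subject)
        assert pred.out_of_stated_range
        assert pred.predicted_ree == pytest.approx(632.4 + 15.66 * 17 + 9.53 * 60, abs=0.01)

    def test_in_range_not_flagged(self):
        pred = predict_ree(get_equation("kim"), make_subject(age=8.0, weight=30))
        assert not pred.out_of_stated_range

    def test_strict_mode_refuses_out_of_range(self):
        strict = Settings(strict_age_range=True)
        with pytest.raises(DispatchError):
            predict_ree(get_equation("kim"), make_subject(age=17.0), strict)

    def test_missing_ffm_names_field(self):
        with pytest.raises(InapplicableError, match="fat_free_mass"):
            predict_ree(get_equation("new_ffm"), make_subject())


# positivity over the plausible anthropometric box
@hyp_settings(max_examples=200)
@given(
    sex=st.sampled_from(list(Sex)),
    age=st.floats(min_value=6, max_value=18),
    weight=st.floats(min_value=15, max_value=120),
    height=st.floats(min_value=100, max_value=195),
    ffm=st.floats(min_value=10, max_value=90),
    fm=st.floats(min_value=1, max_value=60),
)
def test_predictions_strictly_positive(sex, age, weight, height, ffm, fm):
    subject = make_subject(sex=sex, age=age, weight=weight, height=height,
                           fat_free_mass=ffm, fat_mass=fm)
    for spec in equation_registry():
        assert predict_ree(spec, subject).predicted_ree > 0


# ---------------------------------------------------------------------------
# predict_all / Cohort
# ---------------------------------------------------------------------------

class TestPredictAll:
    def test_full_cohort_counts(self, default_cohort):
        preds = predict_all(default_cohort)
        assert len(preds) == 275 * 14
        assert preds["inapplicable_reason"].isna().all()

    def test_missing_ffm_marks_five_equations(self):
        cohort = Cohort((make_subject(id="x", fat_mass=None, fat_free_mass=None),))
        preds = predict_all(cohort)
        inapplicable = set(preds.loc[preds["inapplicable_reason"].notna(), "equation_id"])
        assert inapplicable == {
            "muller_b", "derumeaux_burel", "tverskaya", "lazzer_b", "new_ffm"
        }
        computed = preds[preds["predicted_ree_kcal_d"].notna()]
        assert len(computed) == 14 - 5

    def test_child_uses_child_variants(self):
        cohort = Cohort((make_subject(id="m8", age=8.0, weight=30, height=130),))
        preds = predict_all(cohort, ["who", "schofield", "henry"]).set_index("equation_id")
        assert preds.loc["who", "predicted_ree_kcal_d"] == pytest.approx(22.7 * 30 + 495)
        assert preds.loc["schofield", "predicted_ree_kcal_d"] == pytest.approx(
            19.589 * 30 + 1.302 * 130 + 414.7
        )
        assert preds.loc["henry", "predicted_ree_kcal_d"] == pytest.approx(
            15.1 * 30 + 0.742 * 130 + 306
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            predict_all(Cohort(()))

    def test_unknown_equation_rejected(self, default_cohort):
        with pytest.raises(ConfigurationError):
            predict_all(default_cohort, ["nope"])


class TestSubjectAndCohort:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(DomainError):
            Cohort((make_subject(id="a"), make_subject(id="a")))

    def test_nonpositive_height_rejected(self):
        with pytest.raises(DomainError):
            make_subject(height=0.0)

    def test_bmi_positive(self):
        assert make_subject(weight=50, height=100).bmi == pytest.approx(50.0)

    def test_mass_consistency_tolerance(self):
        s = make_subject(weight=50.0, fat_free_mass=40.0, fat_mass=9.5)
        assert s.mass_consistent(tolerance=1.0)
        assert not s.mass_consistent(tolerance=0.1)

    def test_quality_counts(self):
        cohort = Cohort((
            make_subject(id="a", fat_mass=-1.0, fat_free_mass=41.0, weight=40.0),
            make_subject(id="b", fat_mass=10.0, fat_free_mass=40.0, weight=50.0),
        ))
        q = cohort.quality()
        assert q["negative_fat_mass"] == 1
        assert q["negative_fat_mass_fraction"] == pytest.approx(0.5)
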