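"""Decision-tree factor assignment and half-log combination."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxscreen.evidence import (
    CancerEvidence,
    CancerFinding,
    DatabaseCompleteness,
    DurationProfile,
    EndocrineEvidence,
    EndocrineFinding,
)
from rxscreen.factors import (
    FactorAssignment,
    FactorId,
    TOTAL_MAX,
    TOTAL_MIN,
    assign_all,
    assign_cancer_af,
    assign_database_uf,
    assign_duration_uf,
    assign_endocrine_af,
    assign_loael_noael_uf,
    combine_factors,
    resolve_cancer_endocrine,
)

from conftest import make_profile


class TestCancerAf:
    def test_threshold_near_mrhd_gets_10(self):
        ev = CancerEvidence(finding="threshold_hed_near_or_below_mrhd")
        assert assign_cancer_af(ev).value == 10

    @pytest.mark.parametrize(
        "finding",
        ["none_reported", "threshold_hed_far_above_mrhd",
         "tumor_type_not_human_relevant", "site_of_administration_only"],
    )
    def test_other_findings_get_1(self, finding):
        assert assign_cancer_af(CancerEvidence(finding=finding)).value == 1

    def test_non_threshold_is_a_contract_error(self):
        with pytest.raises(ValueError, match="ineligible"):
            assign_cancer_af(CancerEvidence(finding="non_threshold_or_genotoxic"))


_ENDOCRINE_EXPECTED = {
    EndocrineFinding.none: 1,
    EndocrineFinding.animal_positive_human_negative: 3,
    EndocrineFinding.small_insignificant_hormone_changes: 3,
    EndocrineFinding.frequent_postmarket_only_animal_negative: 3,
    EndocrineFinding.infrequent_human_no_animal_support: 3,
    EndocrineFinding.intended_therapeutic_effect: 10,
    EndocrineFinding.warnings_or_pharmacodynamics_section: 10,
    EndocrineFinding.adverse_reaction_causing_discontinuation: 10,
    EndocrineFinding.hormonal_lab_monitoring_required: 10,
    EndocrineFinding.frequent_with_animal_support: 10,
    EndocrineFinding.aggravation_only: 1,
    EndocrineFinding.rare_effect_only: 1,
    EndocrineFinding.masks_endocrine_disease: 1,
}


@pytest.mark.parametrize("finding", list(EndocrineFinding))
def test_endocrine_af_value_per_finding(finding):
    assignment = assign_endocrine_af(EndocrineEvidence(finding=finding))
    assert assignment.value == _ENDOCRINE_EXPECTED[finding]
    if assignment.value > 1:
        assert assignment.rationale_codes


class TestLoaelNoaelUf:
    def test_default_is_3_never_1(self):
        assignment = assign_loael_noael_uf(make_profile())
        assert assignment.value == 3

    @pytest.mark.parametrize(
        "overrides, code",
        [
            ({"pregnancy_category": "X"}, "UF_L_N.pregnancy_d_or_x"),
            ({"pregnancy_category": "D"}, "UF_L_N.pregnancy_d_or_x"),
            (
                {"pregnancy_category": "C", "category_c_ltd_near_reprotox_dose": True},
                "UF_L_N.category_c_near_reprotox",
            ),
            ({"life_threatening_indication": True}, "UF_L_N.life_threatening_indication"),
            (
                {"not_tested_in_children_or_different_pediatric_profile": True},
                "UF_L_N.pediatric_untested",
            ),
            ({"serious_effects_at_ltd": True}, "UF_L_N.serious_effects_at_ltd"),
            ({"black_box_warning_relevant": True}, "UF_L_N.blackbox"),
        ],
    )
    def test_each_criterion_raises_to_10(self, overrides, code):
        assignment = assign_loael_noael_uf(make_profile(**overrides))
        assert assignment.value == 10
        assert code in assignment.rationale_codes

    def test_multiple_criteria_apply_the_factor_once_but_log_all(self):
        assignment = assign_loael_noael_uf(
            make_profile(black_box_warning_relevant=True, serious_effects_at_ltd=True)
        )
        assert assignment.value == 10
        assert len(assignment.rationale_codes) == 2


@pytest.mark.parametrize(
    "completeness, expected",
    [("complete", 1), ("missing_key_study", 3), ("no_or_minimal_animal_data", 10)],
)
def test_database_uf(completeness, expected):
    profile = make_profile(database_completeness=completeness)
    assert assign_database_uf(profile).value == expected


_DURATION_EXPECTED = {
    DurationProfile.chronic_fully_tested_no_concern: 1,
    DurationProfile.chronic_untested_long_human_history: 3,
    DurationProfile.chronic_tested_duration_related_risk: 3,
    DurationProfile.chronic_tested_new_to_market: 3,
    DurationProfile.short_term_use: 10,
    DurationProfile.subchronic_limited_chronic_testing: 10,
    DurationProfile.chronic_limited_testing_severity_increases: 10,
}


@pytest.mark.parametrize("duration", list(DurationProfile))
def test_duration_uf_value_per_profile(duration):
    profile = make_profile(duration_profile=duration)
    assert assign_duration_uf(profile).value == _DURATION_EXPECTED[duration]


class TestResolveCancerEndocrine:
    def _af(self, fid, value):
        codes = ("test.code",) if value > 1 else ()
        return FactorAssignment(fid, value, codes)

    @pytest.mark.parametrize(
        "afc_value, afe_value, applied_value",
        [(10, 10, 10), (10, 3, 10), (1, 3, 3), (1, 10, 10), (1, 1, 1)],
    )
    def test_applied_value_is_never_the_product(self, afc_value, afe_value, applied_value):
        afc, afe = resolve_cancer_endocrine(
            self._af(FactorId.AF_C, afc_value), self._af(FactorId.AF_E, afe_value)
        )
        applied = [a for a in (afc, afe) if a.applied]
        assert len(applied) == 1
        assert applied[0].value == applied_value

    def test_cancer_wins_but_endocrine_stays_noted(self):
        afc, afe = resolve_cancer_endocrine(
            self._af(FactorId.AF_C, 10), self._af(FactorId.AF_E, 10)
        )
        assert afc.applied and not afe.applied
        assert afe.value == 10  # retained in the record
        assert afe.rationale_codes


class TestCombineFactors:
    @pytest.mark.parametrize(
        "values, display",
        [
            ([3, 10], 30),
            ([3, 3], 10),
            ([10, 10, 10, 3, 10], 30000),
            ([1, 1, 10, 3, 1, 1], 30),
            ([10, 10, 10, 10, 10], 100000),
            ([1], 1),
            ([3], 3),
        ],
    )
    def test_half_log_display(self, values, display):
        assert combine_factors(values).display_value == display

    def test_rejects_values_off_the_scale(self):
        with pytest.raises(ValueError, match="1, 3 or 10"):
            combine_factors([3, 5])

    def test_exhaustive_agreement_with_brute_force_product(self):
        # oracle: straight floating product with 3 -> 10^0.5
        for values in itertools.product([1, 3, 10], repeat=6):
            total = combine_factors(list(values))
            oracle = math.prod(10 ** 0.5 if v == 3 else float(v) for v in values)
            assert math.isclose(
                math.log10(oracle), total.half_log_exponent, abs_tol=1e-9
            )
            # display value re-expresses the exponent on the half-log lattice
            whole, rem = divmod(total.half_logs, 2)
            assert total.display_value == (3 if rem else 1) * 10 ** whole

    @given(st.lists(st.sampled_from([1, 3, 10]), max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_permutation_invariance(self, values):
        assert combine_factors(values) == combine_factors(sorted(values))


class TestAssignAll:
    def test_default_profile_hits_the_30_floor(self):
        fs = assign_all(make_profile())
        assert [a.value for a in fs.assignments] == [1, 1, 10, 3, 1, 1]
        assert fs.total.display_value == TOTAL_MIN == 30

    def test_all_maximal_profile_hits_the_100000_ceiling_with_warning(self):
        profile = make_profile(
            endocrine=EndocrineEvidence(finding="intended_therapeutic_effect"),
            pregnancy_category="X",
            database_completeness="no_or_minimal_animal_data",
            duration_profile="short_term_use",
        )
        with pytest.warns(UserWarning, match="100,000"):
            fs = assign_all(profile)
        assert fs.total.display_value == TOTAL_MAX == 100000

    def test_intraspecies_factor_is_always_10(self):
        fs = assign_all(make_profile())
        assert fs[FactorId.UF_Human].value == 10

    def test_genotoxic_profile_never_produces_a_factor_set(self):
        profile = make_profile(
            carcinogenicity=CancerEvidence(finding="non_threshold_or_genotoxic")
        )
        with pytest.raises(ValueError):
            assign_all(profile)

    def test_published_sulfamethoxazole_factor_pattern(self, sulfamethoxazole_profile):
        fs = assign_all(sulfamethoxazole_profile)
        values = {a.factor_id: a.value for a in fs.assignments}
        assert values[FactorId.AF_E] == 10
        assert values[FactorId.UF_L_N] == 10
        assert values[FactorId.UF_DB] == 3
        assert values[FactorId.UF_S_C] == 10
        assert fs.total.display_value == 30000
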