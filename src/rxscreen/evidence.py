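"""Evidence vocabulary for rapid pharmaceutical screening assessments.

An :class:`EvidenceProfile` collects the facts a curator extracts from an
FDA-approved drug label (dosing regimens, pregnancy category, boxed
warnings, carcinogenicity and endocrine findings, database completeness,
duration of use). The decision-tree factor engine and the screening-value
derivation consume these profiles; nothing downstream re-reads label text.

Evidence is a closed vocabulary: every decision criterion of the framework
is one enumeration value or boolean here, so that rule firing is exactly
reproducible. The module also provides the eligibility screen that removes
APIs the method cannot assess (non-oral routes, OTC-only products,
genotoxic carcinogens, ...).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Route",
    "ProductStatus",
    "CancerFinding",
    "EndocrineFinding",
    "PregnancyCategory",
    "DatabaseCompleteness",
    "DurationProfile",
    "DoseUnits",
    "DoseRegimen",
    "CancerEvidence",
    "EndocrineEvidence",
    "EvidenceProfile",
    "ExclusionReason",
    "EligibilityDecision",
    "screen_eligibility",
    "evidence_profile_schema",
]


class Route(str, enum.Enum):
    oral = "oral"
    non_oral = "non_oral"


class ProductStatus(str, enum.Enum):
    prescription = "prescription"
    otc_only = "otc_only"
    nutritional_supplement = "nutritional_supplement"
    illicit = "illicit"
    discontinued_or_unapproved = "discontinued_or_unapproved"
    veterinary_only = "veterinary_only"


class CancerFinding(str, enum.Enum):
    """Label carcinogenicity evidence, classified for the cancer AF.

    ``non_threshold_or_genotoxic`` marks linear carcinogens, which the
    method excludes outright: dividing a therapeutic dose by uncertainty
    factors is not a valid treatment of a no-threshold mode of action.
    """

    none_reported = "none_reported"
    threshold_hed_near_or_below_mrhd = "threshold_hed_near_or_below_mrhd"
    threshold_hed_far_above_mrhd = "threshold_hed_far_above_mrhd"
    tumor_type_not_human_relevant = "tumor_type_not_human_relevant"
    site_of_administration_only = "site_of_administration_only"
    non_threshold_or_genotoxic = "non_threshold_or_genotoxic"


class EndocrineFinding(str, enum.Enum):
    """Strongest applicable endocrine-activity observation on the label."""

    none = "none"
    animal_positive_human_negative = "animal_positive_human_negative"
    small_insignificant_hormone_changes = "small_insignificant_hormone_changes"
    frequent_postmarket_only_animal_negative = "frequent_postmarket_only_animal_negative"
    infrequent_human_no_animal_support = "infrequent_human_no_animal_support"
    intended_therapeutic_effect = "intended_therapeutic_effect"
    warnings_or_pharmacodynamics_section = "warnings_or_pharmacodynamics_section"
    adverse_reaction_causing_discontinuation = "adverse_reaction_causing_discontinuation"
    hormonal_lab_monitoring_required = "hormonal_lab_monitoring_required"
    frequent_with_animal_support = "frequent_with_animal_support"
    aggravation_only = "aggravation_only"
    rare_effect_only = "rare_effect_only"
    masks_endocrine_disease = "masks_endocrine_disease"


class PregnancyCategory(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    X = "X"
    none_stated = "none_stated"


class DatabaseCompleteness(str, enum.Enum):
    complete = "complete"
    missing_key_study = "missing_key_study"
    no_or_minimal_animal_data = "no_or_minimal_animal_data"


class DurationProfile(str, enum.Enum):
    chronic_fully_tested_no_concern = "chronic_fully_tested_no_concern"
    chronic_untested_long_human_history = "chronic_untested_long_human_history"
    chronic_tested_duration_related_risk = "chronic_tested_duration_related_risk"
    chronic_tested_new_to_market = "chronic_tested_new_to_market"
    short_term_use = "short_term_use"
    subchronic_limited_chronic_testing = "subchronic_limited_chronic_testing"
    chronic_limited_testing_severity_increases = "chronic_limited_testing_severity_increases"


class DoseUnits(str, enum.Enum):
    mg_per_day_total = "mg_per_day_total"
    mg_per_administration = "mg_per_administration"
    mg_per_kg_day = "mg_per_kg_day"


class DoseRegimen(BaseModel):
    """One labeled dose schedule.

    ``amount_mg`` is interpreted according to ``units``: a per-administration
    amount, a total daily amount, or (for pediatric per-weight dosing) a
    mg/kg-day value that passes through the LTD calculation unchanged.
    Regimens restricted to special populations (renal/hepatic impairment,
    titrated dosing) are never used as the lowest therapeutic dose.
    """

    amount_mg: float = Field(gt=0)
    administrations_per_day: int = Field(default=1, ge=1)
    age_min_years: float = Field(default=18.0, ge=0)
    age_max_years: float = Field(default=99.0)
    units: DoseUnits = DoseUnits.mg_per_day_total
    special_population_only: bool = False

    @model_validator(mode="after")
    def _age_range_ordered(self) -> "DoseRegimen":
        if not self.age_max_years > self.age_min_years:
            raise ValueError("age_max_years must exceed age_min_years")
        return self


class CancerEvidence(BaseModel):
    finding: CancerFinding = CancerFinding.none_reported
    hed_mg_per_kg_day: Optional[float] = Field(default=None, gt=0)
    mrhd_mg_per_kg_day: Optional[float] = Field(default=None, gt=0)


class EndocrineEvidence(BaseModel):
    finding: EndocrineFinding = EndocrineFinding.none


class EvidenceProfile(BaseModel):
    """All label-derived facts about one API that the framework consumes."""

    api_name: str
    casrn: Optional[str] = None
    route: Route = Route.oral
    regimens: list[DoseRegimen] = Field(default_factory=list)
    product_status: ProductStatus = ProductStatus.prescription
    discontinued_override: bool = False
    carcinogenicity: CancerEvidence = Field(default_factory=CancerEvidence)
    endocrine: EndocrineEvidence = Field(default_factory=EndocrineEvidence)
    pregnancy_category: PregnancyCategory = PregnancyCategory.none_stated
    category_c_ltd_near_reprotox_dose: bool = False
    black_box_warning_relevant: bool = False
    life_threatening_indication: bool = False
    not_tested_in_children_or_different_pediatric_profile: bool = False
    serious_effects_at_ltd: bool = False
    database_completeness: DatabaseCompleteness = DatabaseCompleteness.complete
    duration_profile: DurationProfile = DurationProfile.chronic_fully_tested_no_concern
    otc_pediatric_use: bool = False
    label_source: Optional[str] = None

    @model_validator(mode="after")
    def _category_c_flag_requires_category_c(self) -> "EvidenceProfile":
        if (
            self.category_c_ltd_near_reprotox_dose
            and self.pregnancy_category is not PregnancyCategory.C
        ):
            raise ValueError(
                "category_c_ltd_near_reprotox_dose requires pregnancy_category = C"
            )
        return self


class ExclusionReason(str, enum.Enum):
    """The seven exclusion criteria, in screening precedence order."""

    non_oral = "non_oral"
    nutritional_supplement = "nutritional_supplement"
    otc_only = "otc_only"
    illicit = "illicit"
    discontinued_or_unapproved = "discontinued_or_unapproved"
    veterinary_only = "veterinary_only"
    genotoxic_or_non_threshold_carcinogen = "genotoxic_or_non_threshold_carcinogen"


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    reason: Optional[ExclusionReason] = None
    all_reasons: tuple[ExclusionReason, ...] = field(default_factory=tuple)


_STATUS_EXCLUSIONS = {
    ProductStatus.nutritional_supplement: ExclusionReason.nutritional_supplement,
    ProductStatus.otc_only: ExclusionReason.otc_only,
    ProductStatus.illicit: ExclusionReason.illicit,
    ProductStatus.discontinued_or_unapproved: ExclusionReason.discontinued_or_unapproved,
    ProductStatus.veterinary_only: ExclusionReason.veterinary_only,
}


def screen_eligibility(profile: EvidenceProfile) -> EligibilityDecision:
    """Apply the exclusion criteria to a profile.

    All matching criteria are collected (``all_reasons``); the decision
    carries the first match in precedence order so reason codes are
    deterministic. A discontinued product with an explicit curator
    override remains eligible — assessors may choose to evaluate recently
    discontinued APIs from archived labels plus supplementary sources.
    """

    reasons: list[ExclusionReason] = []
    if profile.route is Route.non_oral:
        reasons.append(ExclusionReason.non_oral)
    for status, reason in _STATUS_EXCLUSIONS.items():
        if profile.product_status is status:
            if (
                reason is ExclusionReason.discontinued_or_unapproved
                and profile.discontinued_override
            ):
                continue
            reasons.append(reason)
    if profile.carcinogenicity.finding is CancerFinding.non_threshold_or_genotoxic:
        reasons.append(ExclusionReason.genotoxic_or_non_threshold_carcinogen)

    # precedence = declaration order of ExclusionReason
    order = list(ExclusionReason)
    reasons.sort(key=order.index)
    if reasons:
        return EligibilityDecision(False, reasons[0], tuple(reasons))
    return EligibilityDecision(True)


def evidence_profile_schema() -> dict:
    """JSON schema for :class:`EvidenceProfile` (draft 2020-12)."""
    return EvidenceProfile.model_json_schema()
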