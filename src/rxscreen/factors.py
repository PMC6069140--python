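"""Uncertainty/adjustment factor decision tree and half-log combination.

Six factors, each valued 1, 3 or 10, adjust the lowest therapeutic dose:

* ``AF_C`` — threshold-carcinogen adjustment (10 when the tumor-associated
  human-equivalent dose is near or below the maximum recommended human
  dose or the LTD);
* ``AF_E`` — endocrine-activity adjustment (3 or 10 by strength of the
  label evidence; noted but NOT applied when AF_C already fires, so the
  two are never multiplied together);
* ``UF_Human`` — intraspecies variability, always 10;
* ``UF_L_N`` — LOAEL-to-NOAEL extrapolation, default 3, raised to 10 by
  any of six severity criteria (pregnancy category D/X, boxed warning,
  life-threatening indication, ...), applied once however many fire;
* ``UF_DB`` — database deficiencies (3 missing key study, 10 essentially
  no animal data);
* ``UF_S_C`` — duration of use (3 for chronic-use caveats, 10 for
  short-term/subchronic products with limited chronic testing).

Factors multiply on a half-log scale: 3 counts as 10^0.5, so 3 x 10 = 30
and 3 x 3 = 10^0.5 x 10^0.5 = 10. Totals are stored as an exponent (an
integer count of half-logs) so repeated combination never drifts; a
half-integral exponent displays with a leading 3 (3 x 10^n), the field's
convention. The admissible totals for a full factor set span 30 (all
defaults) to 100,000 (every factor maximal).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

from .evidence import (
    CancerEvidence,
    CancerFinding,
    DatabaseCompleteness,
    DurationProfile,
    EndocrineEvidence,
    EndocrineFinding,
    EvidenceProfile,
    PregnancyCategory,
)

__all__ = [
    "FactorId",
    "FactorAssignment",
    "TotalFactor",
    "FactorSet",
    "assign_cancer_af",
    "assign_endocrine_af",
    "assign_loael_noael_uf",
    "assign_database_uf",
    "assign_duration_uf",
    "resolve_cancer_endocrine",
    "combine_factors",
    "assign_all",
    "TOTAL_MIN",
    "TOTAL_MAX",
]

TOTAL_MIN = 30
TOTAL_MAX = 100_000

# half-log exponent contribution of each admissible factor value
_HALF_LOGS = {1: 0, 3: 1, 10: 2}


class FactorId(str, enum.Enum):
    AF_C = "AF_C"
    AF_E = "AF_E"
    UF_Human = "UF_Human"
    UF_L_N = "UF_L_N"
    UF_DB = "UF_DB"
    UF_S_C = "UF_S_C"


@dataclass(frozen=True)
class FactorAssignment:
    factor_id: FactorId
    value: int
    rationale_codes: tuple[str, ...] = ()
    applied: bool = True

    def __post_init__(self):
        if self.value not in _HALF_LOGS:
            raise ValueError(f"{self.factor_id.value}: factor value must be 1, 3 or 10")
        if self.value > 1 and not self.rationale_codes:
            raise ValueError(f"{self.factor_id.value}: value > 1 requires a rationale")


@dataclass(frozen=True)
class TotalFactor:
    """A product of factors on the half-log lattice.

    ``half_logs`` counts contributions of 10^0.5; the display value is
    10^(half_logs/2) rendered as 10^n or 3x10^n.
    """

    half_logs: int

    @property
    def half_log_exponent(self) -> float:
        return self.half_logs / 2

    @property
    def display_value(self) -> int:
        whole, rem = divmod(self.half_logs, 2)
        return (3 if rem else 1) * 10**whole

    def __str__(self) -> str:  # e.g. "30,000"
        return f"{self.display_value:,}"


def combine_factors(values: list[int]) -> TotalFactor:
    """Combine factor values by summing half-log exponents (1→0, 3→0.5, 10→1)."""
    try:
        half_logs = sum(_HALF_LOGS[v] for v in values)
    except KeyError as exc:
        raise ValueError(f"factor value must be 1, 3 or 10, got {exc.args[0]}") from exc
    return TotalFactor(half_logs)


def assign_cancer_af(ev: CancerEvidence) -> FactorAssignment:
    """Cancer adjustment: 10 only when tumors occur at human-equivalent
    doses near or below the recommended human dose; rodent-specific tumor
    types and injection-site-only findings do not count."""
    if ev.finding is CancerFinding.non_threshold_or_genotoxic:
        raise ValueError(
            "non-threshold/genotoxic carcinogens are ineligible for factor assignment"
        )
    if ev.finding is CancerFinding.threshold_hed_near_or_below_mrhd:
        return FactorAssignment(FactorId.AF_C, 10, ("AF_C.hed_near_or_below_mrhd",))
    return FactorAssignment(FactorId.AF_C, 1)


_ENDOCRINE_10 = {
    EndocrineFinding.intended_therapeutic_effect: "AF_E.intended_effect",
    EndocrineFinding.warnings_or_pharmacodynamics_section: "AF_E.warnings_or_pd_section",
    EndocrineFinding.adverse_reaction_causing_discontinuation: "AF_E.discontinuation",
    EndocrineFinding.hormonal_lab_monitoring_required: "AF_E.lab_monitoring",
    EndocrineFinding.frequent_with_animal_support: "AF_E.frequent_with_animal_support",
}
_ENDOCRINE_3 = {
    EndocrineFinding.animal_positive_human_negative: "AF_E.animal_positive_human_negative",
    EndocrineFinding.small_insignificant_hormone_changes: "AF_E.small_hormone_changes",
    EndocrineFinding.frequent_postmarket_only_animal_negative: "AF_E.postmarket_only",
    EndocrineFinding.infrequent_human_no_animal_support: "AF_E.infrequent_no_animal_support",
}


def assign_endocrine_af(ev: EndocrineEvidence) -> FactorAssignment:
    if ev.finding in _ENDOCRINE_10:
        return FactorAssignment(FactorId.AF_E, 10, (_ENDOCRINE_10[ev.finding],))
    if ev.finding in _ENDOCRINE_3:
        return FactorAssignment(FactorId.AF_E, 3, (_ENDOCRINE_3[ev.finding],))
    return FactorAssignment(FactorId.AF_E, 1)


def assign_loael_noael_uf(profile: EvidenceProfile) -> FactorAssignment:
    """LOAEL-NOAEL factor: 3 by default because the therapeutic dose is a
    frank-effect level; 10 when the label signals severity at that dose.
    Several criteria may fire; all are logged but the factor applies once."""
    fired: list[str] = []
    if profile.pregnancy_category in (PregnancyCategory.D, PregnancyCategory.X):
        fired.append("UF_L_N.pregnancy_d_or_x")
    if (
        profile.pregnancy_category is PregnancyCategory.C
        and profile.category_c_ltd_near_reprotox_dose
    ):
        fired.append("UF_L_N.category_c_near_reprotox")
    if profile.life_threatening_indication:
        fired.append("UF_L_N.life_threatening_indication")
    if profile.not_tested_in_children_or_different_pediatric_profile:
        fired.append("UF_L_N.pediatric_untested")
    if profile.serious_effects_at_ltd:
        fired.append("UF_L_N.serious_effects_at_ltd")
    if profile.black_box_warning_relevant:
        fired.append("UF_L_N.blackbox")
    if fired:
        return FactorAssignment(FactorId.UF_L_N, 10, tuple(fired))
    return FactorAssignment(FactorId.UF_L_N, 3, ("UF_L_N.default",))


def assign_database_uf(profile: EvidenceProfile) -> FactorAssignment:
    db = profile.database_completeness
    if db is DatabaseCompleteness.missing_key_study:
        return FactorAssignment(FactorId.UF_DB, 3, ("UF_DB.missing_key_study",))
    if db is DatabaseCompleteness.no_or_minimal_animal_data:
        return FactorAssignment(FactorId.UF_DB, 10, ("UF_DB.no_animal_data",))
    return FactorAssignment(FactorId.UF_DB, 1)


_DURATION_3 = {
    DurationProfile.chronic_untested_long_human_history: "UF_S_C.chronic_untested_long_history",
    DurationProfile.chronic_tested_duration_related_risk: "UF_S_C.duration_related_risk",
    DurationProfile.chronic_tested_new_to_market: "UF_S_C.new_to_market",
}
_DURATION_10 = {
    DurationProfile.short_term_use: "UF_S_C.short_term_use",
    DurationProfile.subchronic_limited_chronic_testing: "UF_S_C.subchronic_limited_testing",
    DurationProfile.chronic_limited_testing_severity_increases: "UF_S_C.severity_increases",
}


def assign_duration_uf(profile: EvidenceProfile) -> FactorAssignment:
    d = profile.duration_profile
    if d in _DURATION_3:
        return FactorAssignment(FactorId.UF_S_C, 3, (_DURATION_3[d],))
    if d in _DURATION_10:
        return FactorAssignment(FactorId.UF_S_C, 10, (_DURATION_10[d],))
    return FactorAssignment(FactorId.UF_S_C, 1)


def resolve_cancer_endocrine(
    afc: FactorAssignment, afe: FactorAssignment
) -> tuple[FactorAssignment, FactorAssignment]:
    """Enforce AF_C/AF_E exclusivity.

    When the cancer adjustment fires it takes precedence: the endocrine
    adjustment is still noted in the record but marked not-applied, so the
    total never contains both. Otherwise the endocrine value applies.
    """
    if afc.value > 1:
        return replace(afc, applied=True), replace(afe, applied=False)
    return replace(afc, applied=False), replace(afe, applied=True)


@dataclass(frozen=True)
class FactorSet:
    assignments: tuple[FactorAssignment, ...]
    total: TotalFactor = field(init=False)

    def __post_init__(self):
        ids = [a.factor_id for a in self.assignments]
        if ids != list(FactorId):
            raise ValueError("FactorSet needs exactly one assignment per factor, in order")
        applied_afs = [
            a
            for a in self.assignments
            if a.factor_id in (FactorId.AF_C, FactorId.AF_E) and a.applied and a.value > 1
        ]
        if len(applied_afs) > 1:
            raise ValueError("AF_C and AF_E may never both apply")
        object.__setattr__(
            self, "total", combine_factors([a.value for a in self.assignments if a.applied])
        )
        if not TOTAL_MIN <= self.total.display_value <= TOTAL_MAX:
            raise ValueError(
                f"total UF/AF {self.total} outside the admissible range "
                f"[{TOTAL_MIN}, {TOTAL_MAX:,}]"
            )

    def __getitem__(self, factor_id: FactorId) -> FactorAssignment:
        return self.assignments[list(FactorId).index(factor_id)]

    @property
    def applied_values(self) -> list[int]:
        return [a.value for a in self.assignments if a.applied]


def assign_all(profile: EvidenceProfile) -> FactorSet:
    """Run the full decision tree for an eligible profile."""
    afc, afe = resolve_cancer_endocrine(
        assign_cancer_af(profile.carcinogenicity),
        assign_endocrine_af(profile.endocrine),
    )
    fs = FactorSet(
        (
            afc,
            afe,
            FactorAssignment(FactorId.UF_Human, 10, ("UF_Human.intraspecies_default",)),
            assign_loael_noael_uf(profile),
            assign_database_uf(profile),
            assign_duration_uf(profile),
        )
    )
    if fs.total.display_value == TOTAL_MAX:
        warnings.warn(
            f"{profile.api_name}: total UF/AF reached the {TOTAL_MAX:,} ceiling; "
            "such a profile signals insufficient data for even a screening value",
            stacklevel=2,
        )
    return fs
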