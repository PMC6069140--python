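"""Synthetic evidence profiles for property testing.

Profiles are drawn uniformly over the closed evidence vocabulary so that
property tests exercise every branch of the eligibility screen and the
factor decision tree, including combinations no real label would show.
These are schema-valid but scientifically arbitrary inputs: they establish
that the rule engine is total, deterministic and bounded, not that any
particular API is assessed correctly.
"""

from __future__ import annotations

import numpy as np

from .evidence import (
    CancerEvidence,
    CancerFinding,
    DatabaseCompleteness,
    DoseRegimen,
    DoseUnits,
    DurationProfile,
    EndocrineEvidence,
    EndocrineFinding,
    EvidenceProfile,
    PregnancyCategory,
    ProductStatus,
    Route,
    screen_eligibility,
)

__all__ = ["generate_synthetic_profiles"]


def _random_regimen(rng: np.random.Generator) -> DoseRegimen:
    units = DoseUnits(rng.choice([u.value for u in DoseUnits]))
    # log-uniform amounts spanning the potency range seen on real labels
    amount = float(np.round(10 ** rng.uniform(-3, 1.5), 6))
    if units is DoseUnits.mg_per_kg_day:
        age_min, age_max = 0.0, 18.0
        n_admin = 1
    else:
        if rng.random() < 0.7:
            age_min, age_max = 18.0, 99.0
        else:
            age_min = float(rng.integers(6, 17))
            age_max = float(rng.integers(int(age_min) + 1, 19))
        n_admin = int(rng.integers(1, 5)) if units is DoseUnits.mg_per_administration else 1
    return DoseRegimen(
        amount_mg=amount,
        administrations_per_day=n_admin,
        age_min_years=age_min,
        age_max_years=age_max,
        units=units,
        special_population_only=bool(rng.random() < 0.1),
    )


def _random_profile(rng: np.random.Generator, index: int) -> EvidenceProfile:
    pregnancy = PregnancyCategory(rng.choice([p.value for p in PregnancyCategory]))
    regimens = [_random_regimen(rng) for _ in range(int(rng.integers(1, 4)))]
    # guarantee at least one general-population regimen
    if all(r.special_population_only for r in regimens):
        regimens[0] = regimens[0].model_copy(update={"special_population_only": False})
    return EvidenceProfile(
        api_name=f"synthetic-{index:05d}",
        casrn=None,
        route=Route(rng.choice([r.value for r in Route])),
        regimens=regimens,
        product_status=ProductStatus(rng.choice([s.value for s in ProductStatus])),
        discontinued_override=bool(rng.random() < 0.5),
        carcinogenicity=CancerEvidence(
            finding=CancerFinding(rng.choice([c.value for c in CancerFinding]))
        ),
        endocrine=EndocrineEvidence(
            finding=EndocrineFinding(rng.choice([e.value for e in EndocrineFinding]))
        ),
        pregnancy_category=pregnancy,
        category_c_ltd_near_reprotox_dose=(
            pregnancy is PregnancyCategory.C and bool(rng.random() < 0.5)
        ),
        black_box_warning_relevant=bool(rng.random() < 0.5),
        life_threatening_indication=bool(rng.random() < 0.5),
        not_tested_in_children_or_different_pediatric_profile=bool(rng.random() < 0.5),
        serious_effects_at_ltd=bool(rng.random() < 0.5),
        database_completeness=DatabaseCompleteness(
            rng.choice([d.value for d in DatabaseCompleteness])
        ),
        duration_profile=DurationProfile(
            rng.choice([d.value for d in DurationProfile])
        ),
        otc_pediatric_use=bool(rng.random() < 0.1),
        label_source="synthetic fixture generator",
    )


def generate_synthetic_profiles(
    seed: int, n: int, eligible_only: bool = False
) -> list[EvidenceProfile]:
    """Generate ``n`` schema-valid random profiles; same seed, same output.

    With ``eligible_only`` profiles failing the eligibility screen are
    resampled, so every returned profile can flow through the full
    derivation pipeline.
    """

    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[EvidenceProfile] = []
    i = 0
    while len(out) < n:
        profile = _random_profile(rng, i)
        i += 1
        if eligible_only and not screen_eligibility(profile).eligible:
            continue
        out.append(profile)
    return out
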