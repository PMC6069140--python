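import pytest

from rxscreen.evidence import (
    CancerEvidence,
    DoseRegimen,
    EndocrineEvidence,
    EvidenceProfile,
)


def make_profile(**overrides) -> EvidenceProfile:
    """A minimal eligible profile (oral prescription, LTD 1 mg/kg-d,
    no flags) that derives to the floor total UF/AF of 30. Override any
    field to strengthen the evidence."""
    base = dict(
        api_name="test-api",
        regimens=[
            DoseRegimen(
                amount_mg=1.0, units="mg_per_kg_day", age_min_years=0, age_max_years=99
            )
        ],
    )
    base.update(overrides)
    return EvidenceProfile(**base)


@pytest.fixture
def minimal_profile() -> EvidenceProfile:
    return make_profile()


@pytest.fixture(scope="session")
def table3_records():
    from rxscreen.published import load_table3

    return load_table3()


@pytest.fixture
def sulfamethoxazole_profile() -> EvidenceProfile:
    """The published comparison inputs for sulfamethoxazole: LTD 4.57
    mg/kg-d, endocrine AF 10 (thyroid class effect in the warnings
    section), LOAEL-NOAEL 10, database 3, duration 10 (short-term
    antibiotic)."""
    return make_profile(
        api_name="Sulfamethoxazole",
        casrn="723-46-6",
        regimens=[
            DoseRegimen(
                amount_mg=4.57, units="mg_per_kg_day", age_min_years=0, age_max_years=99
            )
        ],
        endocrine=EndocrineEvidence(finding="warnings_or_pharmacodynamics_section"),
        black_box_warning_relevant=True,
        database_completeness="missing_key_study",
        duration_profile="short_term_use",
    )


@pytest.fixture
def carbamazepine_profile() -> EvidenceProfile:
    """The published comparison inputs for carbamazepine: LTD 1 mg/kg-d,
    threshold-cancer AF 10, LOAEL-NOAEL 10 (pregnancy category D),
    duration 3; database complete."""
    return make_profile(
        api_name="Carbamazepine",
        casrn="298-46-4",
        regimens=[
            DoseRegimen(
                amount_mg=1.0, units="mg_per_kg_day", age_min_years=0, age_max_years=99
            )
        ],
        carcinogenicity=CancerEvidence(finding="threshold_hed_near_or_below_mrhd"),
        pregnancy_category="D",
        duration_profile="chronic_tested_duration_related_risk",
    )
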