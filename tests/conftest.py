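import pytest

from kindex.instruments import default_schemas
from kindex.scoring import KindexInterview


@pytest.fixture(scope="session")
def schemas():
    return default_schemas()


def make_interview(**overrides) -> KindexInterview:
    """A fully benign respondent; override fields to inject risks."""
    base = dict(
        respondent_id="r1",
        age_years=30,
        gestational_week=30,
        mother_foreign_born=False,
        father_foreign_born=False,
        cohabiting_with_father=True,
        financial_worry=False,
        rooms=3,
        persons=2,
        pregnancy_planned=True,
        joy_mother=10,
        worries_mother=0,
        joy_father=10,
        worries_father=0,
        pss4_items=(0, 0, 0, 0),
        physical_symptoms=False,
        complications=False,
        medical_risk=False,
        childhood_physical_abuse=False,
        childhood_sexual_abuse=False,
        ipv_increase_8w=False,
        ipv_vociferous_8w=False,
        ipv_physical_8w=False,
        ipv_ever=False,
        smoke_mother=False,
        alcohol_mother=False,
        drugs_mother=False,
        smoke_father=False,
        alcohol_father=False,
        drugs_father=False,
        psych_diagnosis_ever=False,
        psych_inpatient_ever=False,
        psychotropic_ever=False,
        sought_help_ever=False,
        interview_unit="outpatient",
        interviewer_profession="midwife",
    )
    base.update(overrides)
    return KindexInterview(**base)


def make_maximal_interview(**overrides) -> KindexInterview:
    """Archetype with every one of the 31 risk conditions present."""
    risky = dict(
        respondent_id="rmax",
        age_years=19,
        mother_foreign_born=True,
        father_foreign_born=True,
        cohabiting_with_father=False,
        financial_worry=True,
        rooms=1,
        persons=3,
        pregnancy_planned=False,
        joy_mother=0,
        worries_mother=10,
        joy_father=0,
        worries_father=10,
        pss4_items=(4, 0, 0, 4),  # reverse-coded items answered at 0 -> sum 16
        physical_symptoms=True,
        complications=True,
        medical_risk=True,
        childhood_physical_abuse=True,
        childhood_sexual_abuse=True,
        ipv_increase_8w=True,
        ipv_vociferous_8w=True,
        ipv_physical_8w=True,
        ipv_ever=True,
        smoke_mother=True,
        alcohol_mother=True,
        drugs_mother=True,
        smoke_father=True,
        alcohol_father=True,
        drugs_father=True,
        psych_diagnosis_ever=True,
        psych_inpatient_ever=True,
        psychotropic_ever=True,
        sought_help_ever=True,
    )
    risky.update(overrides)
    return make_interview(**risky)


@pytest.fixture
def benign_interview():
    return make_interview()


@pytest.fixture
def maximal_interview():
    return make_maximal_interview()
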