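"""KINDEX risk-indicator derivation and sum score.

The KINDEX is a short structured prenatal interview covering 11 psychosocial
risk areas (maternal age, migration background, single parenthood, financial
strain, medical risks, prenatal bonding, perceived stress, childhood trauma,
intimate partner violence, substance use, mental-health history).  Every raw
answer is recoded into one of 31 binary risk indicators via fixed cutoff
rules; the indicators are counted into a 0-31 sum score, and respondents at
or above a referral threshold (default: 2 risks) are flagged for referral to
psychosocial services.

Recoding rules implemented here:

* age at or below 21 years;
* mother or father born abroad;
* not cohabiting with the child's father (single parent);
* worry about financial problems; housing index rooms/persons <= 0.5;
* physical symptoms, pregnancy complications, medical risk factors;
* unplanned pregnancy; parental prenatal-bonding ratings recoded at the
  extreme quartiles of the 0-10 scale (joy 0-3, worries 7-10, for mother
  and father separately);
* PSS-4 perceived-stress sum at or above 12 (upper quartile of 0-16);
* childhood physical or sexual abuse;
* four intimate-partner-violence questions (conflict increase, vociferous
  fights and physical violence in the past 8 weeks; violence in any past
  relationship);
* maternal and paternal smoking, alcohol and drug use (six indicators);
* lifetime psychiatric diagnosis, inpatient treatment, psychotropic
  medication, having sought psychological help.

Missing raw answers follow complete-case analysis: the affected indicator is
missing, the sum score is missing, and per-area partial counts are still
reported together with a diagnostic naming the failed rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .instruments import ResponseSet, load_schema, reverse_code

__all__ = [
    "KindexInterview",
    "RiskIndicatorVector",
    "RiskProfile",
    "ScoringConfig",
    "RISK_AREAS",
    "INDICATOR_AREAS",
    "INDICATOR_NAMES",
    "housing_index",
    "pss4_stress_risk",
    "derive_indicators",
    "sum_score",
    "flag_referral",
    "score_cohort",
]

# Ordered map: risk area -> indicator names in that area.  The area item
# counts (1, 2, 1, 2, 3, 5, 1, 2, 4, 6, 4) sum to the 31 dichotomous items.
RISK_AREAS: dict[str, tuple[str, ...]] = {
    "age": ("age_21_or_younger",),
    "migration": ("mother_foreign_born", "father_foreign_born"),
    "single_parent": ("single_parent",),
    "financial": ("financial_worry", "crowded_housing"),
    "medical": ("physical_symptoms", "pregnancy_complications", "medical_risk"),
    "bonding": (
        "unplanned_pregnancy",
        "low_joy_mother",
        "high_worries_mother",
        "low_joy_father",
        "high_worries_father",
    ),
    "stress": ("high_perceived_stress",),
    "childhood_trauma": ("childhood_physical_abuse", "childhood_sexual_abuse"),
    "ipv": (
        "ipv_conflict_increase",
        "ipv_vociferous_fights",
        "ipv_physical_violence",
        "ipv_ever",
    ),
    "substance": (
        "smoking_mother",
        "alcohol_mother",
        "drugs_mother",
        "smoking_father",
        "alcohol_father",
        "drugs_father",
    ),
    "mental_illness": (
        "psychiatric_diagnosis_ever",
        "inpatient_treatment_ever",
        "psychotropic_medication_ever",
        "sought_psychological_help",
    ),
}

INDICATOR_AREAS: dict[str, str] = {
    name: area for area, names in RISK_AREAS.items() for name in names
}
INDICATOR_NAMES: tuple[str, ...] = tuple(INDICATOR_AREAS)
assert len(INDICATOR_NAMES) == 31

_PSS4_SCHEMA = load_schema("pss4")
PSS4_RISK_CUTOFF = 12  # upper quartile of the 0-16 PSS-4 sum


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable recoding rules.

    ``housing_comparator`` selects whether a housing index exactly equal to
    0.5 counts as a risk (``"le"``, the rule-sheet convention, default) or
    only strictly smaller values do (``"lt"``).
    """

    housing_comparator: str = "le"  # "le" | "lt"
    housing_cutoff: Fraction = Fraction(1, 2)
    age_cutoff: int = 21
    joy_risk_max: int = 3
    worries_risk_min: int = 7
    pss4_cutoff: int = PSS4_RISK_CUTOFF
    referral_threshold: int = 2

    def __post_init__(self) -> None:
        if self.housing_comparator not in ("le", "lt"):
            raise ValueError("housing_comparator must be 'le' or 'lt'")


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class KindexInterview:
    """Raw answers of one KINDEX interview.

    Booleans may be ``None`` for unanswered questions (complete-case
    handling applies downstream).  ``support_wish`` and the free-text
    "specify" fields are recorded but never scored.
    """

    respondent_id: str
    age_years: Optional[int] = None
    gestational_week: Optional[int] = None
    mother_foreign_born: Optional[bool] = None
    father_foreign_born: Optional[bool] = None
    cohabiting_with_father: Optional[bool] = None
    financial_worry: Optional[bool] = None
    rooms: Optional[int] = None
    persons: Optional[int] = None
    pregnancy_planned: Optional[bool] = None
    joy_mother: Optional[int] = None
    worries_mother: Optional[int] = None
    joy_father: Optional[int] = None
    worries_father: Optional[int] = None
    pss4_items: tuple[Optional[int], ...] = (None, None, None, None)
    physical_symptoms: Optional[bool] = None
    complications: Optional[bool] = None
    medical_risk: Optional[bool] = None
    childhood_physical_abuse: Optional[bool] = None
    childhood_sexual_abuse: Optional[bool] = None
    ipv_increase_8w: Optional[bool] = None
    ipv_vociferous_8w: Optional[bool] = None
    ipv_physical_8w: Optional[bool] = None
    ipv_ever: Optional[bool] = None
    smoke_mother: Optional[bool] = None
    alcohol_mother: Optional[bool] = None
    drugs_mother: Optional[bool] = None
    smoke_father: Optional[bool] = None
    alcohol_father: Optional[bool] = None
    drugs_father: Optional[bool] = None
    psych_diagnosis_ever: Optional[bool] = None
    psych_inpatient_ever: Optional[bool] = None
    psychotropic_ever: Optional[bool] = None
    sought_help_ever: Optional[bool] = None
    interview_unit: Optional[str] = None
    interviewer_profession: Optional[str] = None
    support_wish: str = ""

    def __post_init__(self) -> None:
        for name in ("joy_mother", "worries_mother", "joy_father", "worries_father"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 10):
                raise ValueError(
                    f"{name}={v} out of the 0-10 rating range "
                    f"(respondent {self.respondent_id})"
                )
        for v in self.pss4_items:
            if v is not None and not (0 <= v <= 4):
                raise ValueError(
                    f"PSS-4 item value {v} out of range 0-4 "
                    f"(respondent {self.respondent_id})"
                )
        if self.interview_unit is not None and self.interview_unit not in (
            "outpatient", "fetal_medicine", "hospitalized", "emergency"
        ):
            raise ValueError(f"unknown interview unit {self.interview_unit!r}")
        if self.interviewer_profession is not None and (
            self.interviewer_profession not in ("midwife", "gynecologist")
        ):
            raise ValueError(
                f"unknown interviewer profession {self.interviewer_profession!r}"
            )
        gw = self.gestational_week
        if gw is not None and not (24 <= gw <= 36):
            # eligibility window, not a scoring rule -> warn only
            warnings.warn(
                f"gestational week {gw} outside the 24-36 eligibility window "
                f"(respondent {self.respondent_id})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RiskIndicatorVector:
    """The 31 named binary indicators (``None`` where underivable)."""

    values: Mapping[str, Optional[bool]]
    diagnostics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if tuple(self.values) != INDICATOR_NAMES:
            raise ValueError("indicator vector must carry exactly the 31 "
                             "named indicators in canonical order")

    def area_counts(self) -> dict[str, Optional[int]]:
        """True-indicator count per risk area; partial counts stay reported
        (missing indicators simply cannot add to them)."""
        out: dict[str, Optional[int]] = {}
        for area, names in RISK_AREAS.items():
            out[area] = sum(bool(self.values[n]) for n in names)
        return out

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values.values())


@dataclass(frozen=True)
class RiskProfile:
    respondent_id: str
    indicators: RiskIndicatorVector
    area_counts: Mapping[str, Optional[int]]
    sum_score: Optional[int]
    referral_flag: Optional[bool]


def housing_index(rooms: int, persons: int) -> Fraction:
    """Rooms-per-person ratio as an exact rational (risk when <= 0.5)."""
    if rooms < 1 or persons < 1:
        raise ValueError(
            f"rooms and persons must be positive integers "
            f"(got rooms={rooms}, persons={persons})"
        )
    return Fraction(rooms, persons)


def _housing_risk(ratio: Fraction, config: ScoringConfig) -> bool:
    if config.housing_comparator == "le":
        return ratio <= config.housing_cutoff
    return ratio < config.housing_cutoff


def pss4_stress_risk(
    pss4_items: Sequence[Optional[int]], config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[Optional[int], Optional[bool]]:
    """PSS-4 sum and the high-stress flag (sum >= 12, the upper quartile
    of the 0-16 range).

    Expects the four items *after* reverse coding (the positive items of
    the raw interview are reflected by the PSS-4 schema before this step;
    :func:`derive_indicators` does that for stored raw answers).  Returns
    ``(None, None)`` when any item is missing (complete case).
    """
    if len(pss4_items) != 4:
        raise ValueError("PSS-4 takes exactly 4 items")
    for v in pss4_items:
        if v is not None and not (0 <= v <= 4):
            raise ValueError(f"PSS-4 item value {v} out of range 0-4")
    if any(v is None for v in pss4_items):
        return None, None
    total = int(sum(pss4_items))
    return total, total >= config.pss4_cutoff


def _not(value: Optional[bool]) -> Optional[bool]:
    return None if value is None else not value


def derive_indicators(
    interview: KindexInterview, config: ScoringConfig = DEFAULT_CONFIG
) -> RiskIndicatorVector:
    """Apply every recoding rule, producing the 31 binary indicators.

    Total and deterministic: every indicator is defined, or missing with a
    diagnostic naming the rule that could not be evaluated.
    """
    iv = interview
    vals: dict[str, Optional[bool]] = {}

    vals["age_21_or_younger"] = (
        None if iv.age_years is None else iv.age_years <= config.age_cutoff
    )
    vals["mother_foreign_born"] = iv.mother_foreign_born
    vals["father_foreign_born"] = iv.father_foreign_born
    vals["single_parent"] = _not(iv.cohabiting_with_father)
    vals["financial_worry"] = iv.financial_worry
    if iv.rooms is None or iv.persons is None:
        vals["crowded_housing"] = None
    else:
        vals["crowded_housing"] = _housing_risk(
            housing_index(iv.rooms, iv.persons), config
        )
    vals["physical_symptoms"] = iv.physical_symptoms
    vals["pregnancy_complications"] = iv.complications
    vals["medical_risk"] = iv.medical_risk
    vals["unplanned_pregnancy"] = _not(iv.pregnancy_planned)
    for name, rating, kind in (
        ("low_joy_mother", iv.joy_mother, "joy"),
        ("high_worries_mother", iv.worries_mother, "worries"),
        ("low_joy_father", iv.joy_father, "joy"),
        ("high_worries_father", iv.worries_father, "worries"),
    ):
        if rating is None:
            vals[name] = None
        elif kind == "joy":
            vals[name] = rating <= config.joy_risk_max
        else:
            vals[name] = rating >= config.worries_risk_min
    rs = ResponseSet(iv.respondent_id, "pss4",
                     dict(zip(_PSS4_SCHEMA.items, iv.pss4_items)))
    recoded = reverse_code(_PSS4_SCHEMA, rs)
    _, stress_flag = pss4_stress_risk(
        tuple(recoded.values[i] for i in _PSS4_SCHEMA.items), config
    )
    vals["high_perceived_stress"] = stress_flag
    vals["childhood_physical_abuse"] = iv.childhood_physical_abuse
    vals["childhood_sexual_abuse"] = iv.childhood_sexual_abuse
    vals["ipv_conflict_increase"] = iv.ipv_increase_8w
    vals["ipv_vociferous_fights"] = iv.ipv_vociferous_8w
    vals["ipv_physical_violence"] = iv.ipv_physical_8w
    vals["ipv_ever"] = iv.ipv_ever
    vals["smoking_mother"] = iv.smoke_mother
    vals["alcohol_mother"] = iv.alcohol_mother
    vals["drugs_mother"] = iv.drugs_mother
    vals["smoking_father"] = iv.smoke_father
    vals["alcohol_father"] = iv.alcohol_father
    vals["drugs_father"] = iv.drugs_father
    vals["psychiatric_diagnosis_ever"] = iv.psych_diagnosis_ever
    vals["inpatient_treatment_ever"] = iv.psych_inpatient_ever
    vals["psychotropic_medication_ever"] = iv.psychotropic_ever
    vals["sought_psychological_help"] = iv.sought_help_ever

    diagnostics = tuple(
        f"indicator {name!r} missing: underlying answer unavailable"
        for name, v in vals.items()
        if v is None
    )
    ordered = {name: vals[name] for name in INDICATOR_NAMES}
    return RiskIndicatorVector(ordered, diagnostics)


def sum_score(vector: RiskIndicatorVector) -> Optional[int]:
    """Count of true indicators (0-31); missing under complete-case when any
    indicator is missing."""
    if not vector.complete:
        return None
    return sum(bool(v) for v in vector.values.values())


def flag_referral(
    profile_or_sum, threshold: int = DEFAULT_CONFIG.referral_threshold
) -> Optional[bool]:
    """Referral flag: true iff the sum score reaches ``threshold`` risks."""
    s = (
        profile_or_sum.sum_score
        if isinstance(profile_or_sum, RiskProfile)
        else profile_or_sum
    )
    if s is None:
        return None
    return s >= threshold


def risk_profile(
    interview: KindexInterview, config: ScoringConfig = DEFAULT_CONFIG
) -> RiskProfile:
    """Full per-respondent profile: indicators, area counts, sum, referral."""
    vec = derive_indicators(interview, config)
    s = sum_score(vec)
    return RiskProfile(
        respondent_id=interview.respondent_id,
        indicators=vec,
        area_counts=vec.area_counts(),
        sum_score=s,
        referral_flag=flag_referral(s, config.referral_threshold),
    )


def interviews_to_frame(interviews: Sequence[KindexInterview]) -> pd.DataFrame:
    """Wide one-row-per-respondent frame (PSS-4 items as pss4_1..pss4_4)."""
    rows = []
    for iv in interviews:
        row = {f: getattr(iv, f) for f in iv.__dataclass_fields__
               if f != "pss4_items"}
        for i, v in enumerate(iv.pss4_items, start=1):
            row[f"pss4_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("respondent_id")


# Direct pass-through booleans: interview column -> indicator name.
_PASSTHROUGH: tuple[tuple[str, str], ...] = (
    ("mother_foreign_born", "mother_foreign_born"),
    ("father_foreign_born", "father_foreign_born"),
    ("financial_worry", "financial_worry"),
    ("physical_symptoms", "physical_symptoms"),
    ("complications", "pregnancy_complications"),
    ("medical_risk", "medical_risk"),
    ("childhood_physical_abuse", "childhood_physical_abuse"),
    ("childhood_sexual_abuse", "childhood_sexual_abuse"),
    ("ipv_increase_8w", "ipv_conflict_increase"),
    ("ipv_vociferous_8w", "ipv_vociferous_fights"),
    ("ipv_physical_8w", "ipv_physical_violence"),
    ("ipv_ever", "ipv_ever"),
    ("smoke_mother", "smoking_mother"),
    ("alcohol_mother", "alcohol_mother"),
    ("drugs_mother", "drugs_mother"),
    ("smoke_father", "smoking_father"),
    ("alcohol_father", "alcohol_father"),
    ("drugs_father", "drugs_father"),
    ("psych_diagnosis_ever", "psychiatric_diagnosis_ever"),
    ("psych_inpatient_ever", "inpatient_treatment_ever"),
    ("psychotropic_ever", "psychotropic_medication_ever"),
    ("sought_help_ever", "sought_psychological_help"),
)


def score_cohort(
    interviews: Sequence[KindexInterview] | pd.DataFrame,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Score a cohort into a profile table (vectorized).

    Accepts a sequence of :class:`KindexInterview` or a wide interview
    DataFrame indexed by respondent id (see :mod:`kindex.io` for the column
    dictionary).  Returns one row per respondent: the 31 indicator columns
    (nullable boolean), the 11 ``n_risks_<area>`` counts, ``sum_score`` and
    ``referral_flag``; all missing-value handling is complete-case, with
    per-area partial counts still reported.
    """
    if not isinstance(interviews, pd.DataFrame):
        interviews = interviews_to_frame(interviews)
    df = interviews
    if len(df) == 0:
        raise ValueError("empty cohort")

    for name in ("joy_mother", "worries_mother", "joy_father", "worries_father"):
        vals = pd.to_numeric(df[name], errors="raise")
        bad = vals.dropna()
        bad = bad[(bad < 0) | (bad > 10)]
        if len(bad):
            raise ValueError(
                f"{name}={bad.iloc[0]} out of the 0-10 rating range "
                f"(respondent {bad.index[0]})"
            )

    ind = pd.DataFrame(index=df.index)
    age = df["age_years"].astype("Int64")
    ind["age_21_or_younger"] = age <= config.age_cutoff
    ind["single_parent"] = ~df["cohabiting_with_father"].astype("boolean")

    rooms = df["rooms"].astype("Int64")
    persons = df["persons"].astype("Int64")
    nonpos = ((rooms < 1) | (persons < 1)).fillna(False)
    if bool(nonpos.any()):
        r = nonpos[nonpos].index[0]
        raise ValueError(
            f"rooms and persons must be positive integers "
            f"(respondent {r}: rooms={rooms[r]}, persons={persons[r]})"
        )
    # exact rational comparison rooms/persons vs p/q without floats
    p, q = config.housing_cutoff.numerator, config.housing_cutoff.denominator
    if config.housing_comparator == "le":
        ind["crowded_housing"] = rooms * q <= persons * p
    else:
        ind["crowded_housing"] = rooms * q < persons * p

    for src, name in _PASSTHROUGH:
        ind[name] = df[src].astype("boolean")
    ind["unplanned_pregnancy"] = ~df["pregnancy_planned"].astype("boolean")

    for name, col, kind in (
        ("low_joy_mother", "joy_mother", "joy"),
        ("high_worries_mother", "worries_mother", "worries"),
        ("low_joy_father", "joy_father", "joy"),
        ("high_worries_father", "worries_father", "worries"),
    ):
        rating = df[col].astype("Int64")
        if kind == "joy":
            ind[name] = rating <= config.joy_risk_max
        else:
            ind[name] = rating >= config.worries_risk_min

    from .instruments import score_table  # avoid top-level name clutter

    pss4_wide = df[[f"pss4_{i}" for i in range(1, 5)]].copy()
    pss4_wide.columns = list(_PSS4_SCHEMA.items)
    pss4_scores = score_table(_PSS4_SCHEMA, pss4_wide)
    pss4_total = pss4_scores["total"]
    ind["high_perceived_stress"] = (
        pd.Series(pss4_total >= config.pss4_cutoff, index=df.index)
        .astype("boolean")
        .mask(pss4_total.isna())
    )

    ind = ind[list(INDICATOR_NAMES)].astype("boolean")
    out = ind.copy()
    counts = ind.astype("Int64")
    for area, names in RISK_AREAS.items():
        # partial per-area counts: missing indicators simply cannot add
        out[f"n_risks_{area}"] = (
            counts[list(names)].sum(axis=1, min_count=0).astype("Int64")
        )
    out["sum_score"] = counts.sum(axis=1, min_count=len(INDICATOR_NAMES))
    out["sum_score"] = out["sum_score"].astype("Int64")
    out["referral_flag"] = (
        (out["sum_score"] >= config.referral_threshold).astype("boolean")
    )
    out["pss4_sum"] = pss4_scores["total"].astype("Int64")
    return out
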