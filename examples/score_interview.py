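"""Score a single prenatal interview into its risk profile.

Builds one respondent's raw answers, derives the 31 binary risk
indicators, and prints the per-area counts, the 0-31 sum score and the
referral flag (2 or more risks -> refer to psychosocial services).
"""

from kindex import KindexInterview, risk_profile

interview = KindexInterview(
    respondent_id="demo-001",
    age_years=20,                 # at or below 21 -> age risk
    gestational_week=29,
    mother_foreign_born=False, father_foreign_born=True,  # migration risk
    cohabiting_with_father=True,
    financial_worry=True,         # financial risk
    rooms=2, persons=4,           # housing index 0.5 -> crowded-housing risk
    pregnancy_planned=True,
    joy_mother=9, worries_mother=4, joy_father=8, worries_father=2,
    pss4_items=(2, 3, 3, 1),      # raw answers; recoded sum stays below 12
    physical_symptoms=True,       # medical risk area
    complications=False, medical_risk=False,
    childhood_physical_abuse=False, childhood_sexual_abuse=False,
    ipv_increase_8w=False, ipv_vociferous_8w=False,
    ipv_physical_8w=False, ipv_ever=False,
    smoke_mother=False, alcohol_mother=False, drugs_mother=False,
    smoke_father=True,            # substance risk
    alcohol_father=False, drugs_father=False,
    psych_diagnosis_ever=False, psych_inpatient_ever=False,
    psychotropic_ever=False, sought_help_ever=False,
    interview_unit="outpatient", interviewer_profession="midwife",
)

profile = risk_profile(interview)
print(f"respondent        : {profile.respondent_id}")
for area, count in profile.area_counts.items():
    if count:
        print(f"  {area:<16}: {count} risk(s)")
print(f"sum score         : {profile.sum_score} / 31")
print(f"referral flag     : {profile.referral_flag}  (threshold: 2+ risks)")
# The sum score counts distinct dichotomized risk conditions; the referral
# flag mirrors the screening rule used to route women to support services.
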