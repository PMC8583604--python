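"""Default study design: a two-visit T2DM monitoring cohort.

Encodes the design of an Italian primary-care monitoring study: 124
subjects with type 2 diabetes followed under a regional care pathway
(PDTA), 33 of whom were additionally enrolled in a specialised diabetes
centre's care plan (CAD).  Each subject has a baseline and a one-year
follow-up visit (median 370 days apart) at which 17 clinical and
behavioural outcomes are recorded: 15 continuous measurements and two
lifestyle indicators derived from categorical records (smoking status
and physical-activity level).

The per-outcome calibration targets (median, IQR, follow-up shift,
per-visit non-missing counts) are the module-level constants below and
feed :func:`twovisit.cohort.default_cohort_config`.
"""

from __future__ import annotations

GROUP_A = "PDTA"
GROUP_B = "PDTA_CAD"
GROUP_LABELS = (GROUP_A, GROUP_B)

VISIT_BASELINE = "baseline"
VISIT_FOLLOWUP = "followup"

N_GROUP_A = 91
N_GROUP_B = 33
N_TOTAL = N_GROUP_A + N_GROUP_B

#: Follow-up interval in days: median (q1, q3).
FOLLOWUP_DAYS = (370.0, 315.0, 403.0)

#: Age in years: median (q1, q3).
AGE_YEARS = (71.5, 66.1, 77.2)

#: Proportion of male subjects.
MALE_PROPORTION = 0.61

#: Diabetes treatment mix.
TREATMENT_PROPS = {"oral_hypoglycemic": 0.90, "insulin": 0.03, "none": 0.07}

# Continuous outcomes, cohort-wide calibration:
# (column, units, family, base_median, base_q1, base_q3, fup_median,
#  n_nonmissing_baseline, n_nonmissing_followup)
CONTINUOUS_OUTCOMES = [
    ("glycated_hemoglobin", "mmol/mol", "lognormal", 52.0, 46.0, 59.0, 51.0, 124, 123),
    ("microalbuminuria", "mg/die", "lognormal", 8.3, 3.1, 21.9, 7.9, 111, 107),
    ("creatinine_clearance", "mL/min", "normal", 85.7, 68.8, 102.8, 83.9, 120, 119),
    ("total_cholesterol", "mg/dL", "normal", 178.0, 152.0, 212.0, 172.0, 120, 121),
    ("ldl_cholesterol", "mg/dL", "normal", 96.5, 76.0, 125.5, 91.5, 124, 120),
    ("hdl_cholesterol", "mg/dL", "normal", 53.5, 43.0, 63.0, 52.5, 120, 120),
    ("triglycerides", "mg/dL", "lognormal", 105.5, 78.2, 151.0, 106.0, 118, 118),
    ("weight", "kg", "normal", 80.0, 70.0, 90.0, 80.0, 124, 124),
    ("bmi", "kg/m^2", "normal", 28.7, 25.8, 31.2, 28.4, 124, 124),
    ("waist_circumference", "cm", "normal", 106.0, 97.0, 112.0, 105.0, 111, 117),
    ("cigarettes_per_day", "n/day", "lognormal", 20.0, 15.0, 30.0, 20.0, 57, 57),
    ("alcohol", "g/day", "normal", 0.0, 0.0, 12.0, 0.0, 124, 124),
    ("systolic_blood_pressure", "mmHg", "normal", 148.0, 140.0, 160.0, 145.0, 124, 124),
    ("diastolic_blood_pressure", "mmHg", "normal", 80.0, 71.5, 90.0, 76.0, 124, 124),
    ("heart_rate", "bpm", "normal", 73.0, 66.0, 80.0, 73.0, 119, 124),
]

# Categorical outcomes:
# (column, categories, baseline_probs, followup_probs, n_base, n_fup)
CATEGORICAL_OUTCOMES = [
    (
        "smoke_habits",
        ("current", "never", "former"),
        (16 / 122, 65 / 122, 41 / 122),
        (14 / 123, 66 / 123, 43 / 123),
        122,
        123,
    ),
    (
        "physical_activity",
        ("none", "light", "moderate", "intense"),
        (44 / 124, 67 / 124, 9 / 124, 4 / 124),
        (58 / 124, 54 / 124, 10 / 124, 2 / 124),
        124,
        124,
    ),
]

#: The 17 outcomes entering the longitudinal analysis, in report order.
#: Each entry maps the report label to the cohort column holding the
#: analysed values; the two lifestyle indicators are 0/1 columns derived
#: from the categorical records (see :func:`twovisit.pipeline.derive_indicators`).
ANALYSIS_OUTCOMES = [
    ("Glycated haemoglobin", "glycated_hemoglobin"),
    ("Microalbuminuria", "microalbuminuria"),
    ("Creatinine", "creatinine_clearance"),
    ("Total cholesterol", "total_cholesterol"),
    ("Low density lipoprotein", "ldl_cholesterol"),
    ("High density lipoprotein", "hdl_cholesterol"),
    ("Triglycerides", "triglycerides"),
    ("Weight", "weight"),
    ("Body mass index", "bmi"),
    ("Waist circumference", "waist_circumference"),
    ("Number of cigarettes", "cigarettes_per_day"),
    ("Alcohol", "alcohol"),
    ("Systolic blood pressure", "systolic_blood_pressure"),
    ("Diastolic blood pressure", "diastolic_blood_pressure"),
    ("Heart rate", "heart_rate"),
    ("Phisical Activity(Moderate-Intense)", "physical_activity_moderate_intense"),
    ("Smoker(Yes)", "smoker_yes"),
]
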