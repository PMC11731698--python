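"""Reference descriptive statistics of the ADA T2D community corpus.

Published summary counts of the American Diabetes Association (ADA) type 2
diabetes support community (2014–2021): yearly activity, the self-reported
behavior-persona distribution of the 529 signature users, and per-theme
dataset sizes of the exposure-model subset.  These anchor the synthetic
generator's default marginals and serve as worked-arithmetic inputs (each
printed share must recompute from its count pair under half-up rounding).

Note the persona counts famously sum to 531 over 529 users on each axis —
the printed shares nevertheless recompute exactly against n=529; the
generator normalizes the proportions instead.
"""

from __future__ import annotations

from .records import DiagnosisStatus, LifestyleStatus, MedicationStatus
from .vocab import Theme

YEARS = tuple(range(2014, 2022))

#: Yearly (messages, unique topics, unique users) of the full corpus.
YEARLY_MESSAGES = dict(zip(YEARS, (14104, 18311, 16859, 10940, 6379, 3805, 2202, 922)))
YEARLY_TOPICS = dict(zip(YEARS, (1337, 1776, 1588, 1028, 746, 587, 501, 234)))
YEARLY_USERS = dict(zip(YEARS, (597, 767, 677, 458, 336, 242, 206, 129)))
TOTAL_MESSAGES = 73543
TOTAL_TOPICS = 7619
TOTAL_USERS = 2374

#: Exposure-model subset: messages by the users with self-reported signatures.
AEM_MESSAGES = 56993
AEM_TOPICS = 7232
AEM_USERS = 529

#: Per-theme (messages, topics, users) of the exposure-model subset.
THEME_MESSAGES = {
    Theme.SOCIAL_SUPPORT: 56952,
    Theme.READINESS_REGULATORS: 40233,
    Theme.PHARMACOTHERAPY: 20722,
    Theme.OBSTACLES: 8204,
    Theme.PATIENT_REPORTED_OUTCOMES: 19230,
    Theme.PROGRESS: 18205,
}
THEME_TOPICS = {
    Theme.SOCIAL_SUPPORT: 7232,
    Theme.READINESS_REGULATORS: 6726,
    Theme.PHARMACOTHERAPY: 4333,
    Theme.OBSTACLES: 2635,
    Theme.PATIENT_REPORTED_OUTCOMES: 3033,
    Theme.PROGRESS: 2869,
}
THEME_USERS = {
    Theme.SOCIAL_SUPPORT: 529,
    Theme.READINESS_REGULATORS: 505,
    Theme.PHARMACOTHERAPY: 471,
    Theme.OBSTACLES: 360,
    Theme.PATIENT_REPORTED_OUTCOMES: 391,
    Theme.PROGRESS: 378,
}

#: Persona distribution of the 529 signature users.
PERSONA_MEDICATION = {
    MedicationStatus.ORAL_ONLY: 237,
    MedicationStatus.INJECTABLE_ONLY: 63,
    MedicationStatus.BOTH: 77,
    MedicationStatus.NO_MEDICATIONS: 52,
    MedicationStatus.NO_INFORMATION: 102,
}
PERSONA_DIAGNOSIS = {
    DiagnosisStatus.PRE_EXISTING: 428,
    DiagnosisStatus.NEWLY_DIAGNOSED: 4,
    DiagnosisStatus.NO_INFORMATION: 99,
}
PERSONA_LIFESTYLE = {
    LifestyleStatus.YES: 153,
    LifestyleStatus.NO: 378,
}

#: (label, numerator, denominator, printed share %) — every self-contained
#: printed count/share pair from the community's descriptive tables and
#: results narrative.  Each printed share must equal
#: ``percent(numerator, denominator)`` exactly.
PRINTED_SHARES: list[tuple[str, int, int, float]] = (
    [
        (f"messages_{y}", YEARLY_MESSAGES[y], TOTAL_MESSAGES, p)
        for y, p in zip(YEARS, (19.2, 24.9, 22.9, 14.9, 8.7, 5.2, 3.0, 1.3))
    ]
    + [
        (f"topics_{y}", YEARLY_TOPICS[y], TOTAL_TOPICS, p)
        for y, p in zip(YEARS, (17.5, 23.3, 20.8, 13.5, 9.8, 7.7, 6.6, 3.1))
    ]
    + [
        (f"users_{y}", YEARLY_USERS[y], TOTAL_USERS, p)
        for y, p in zip(YEARS, (25.1, 32.3, 28.5, 19.3, 14.2, 10.2, 8.7, 5.4))
    ]
    + [
        ("persona_oral_only", 237, 529, 44.8),
        ("persona_injectable_only", 63, 529, 11.9),
        ("persona_both", 77, 529, 14.6),
        ("persona_no_medications", 52, 529, 9.8),
        ("persona_med_no_information", 102, 529, 19.3),
        ("persona_pre_existing", 428, 529, 80.9),
        ("persona_newly_diagnosed", 4, 529, 0.8),
        ("persona_dx_no_information", 99, 529, 18.7),
        ("persona_lifestyle_yes", 153, 529, 28.9),
        ("persona_lifestyle_no", 378, 529, 71.5),
        ("signature_users_of_community", 529, 2374, 22.3),
    ]
    + [
        ("aem_messages_social_support", 56952, 56993, 99.9),
        ("aem_messages_readiness_regulators", 40233, 56993, 70.6),
        ("aem_messages_pharmacotherapy", 20722, 56993, 36.4),
        ("aem_messages_obstacles", 8204, 56993, 14.4),
        ("aem_messages_patient_reported_outcomes", 19230, 56993, 33.7),
        ("aem_messages_progress", 18205, 56993, 31.9),
        ("aem_topics_social_support", 7232, 7232, 100.0),
        ("aem_topics_readiness_regulators", 6726, 7232, 93.0),
        ("aem_topics_pharmacotherapy", 4333, 7232, 59.9),
        ("aem_topics_obstacles", 2635, 7232, 36.4),
        ("aem_topics_patient_reported_outcomes", 3033, 7232, 41.9),
        ("aem_topics_progress", 2869, 7232, 39.7),
        ("aem_users_social_support", 529, 529, 100.0),
        ("aem_users_readiness_regulators", 505, 529, 95.5),
        ("aem_users_pharmacotherapy", 471, 529, 89.0),
        ("aem_users_obstacles", 360, 529, 68.1),
        ("aem_users_patient_reported_outcomes", 391, 529, 73.9),
        ("aem_users_progress", 378, 529, 71.5),
    ]
    + [
        # labeled-subset (n=1501) prevalence from the results narrative
        ("labeled_theme_social_support", 1128, 1501, 75.1),
        ("labeled_theme_teachable_moments", 357, 1501, 23.8),
        ("labeled_theme_pharmacotherapy", 310, 1501, 20.7),
        ("labeled_theme_obstacles", 262, 1501, 17.5),
        ("labeled_theme_patient_reported_outcomes", 232, 1501, 15.5),
        ("labeled_bct_feedback_and_monitoring", 659, 1501, 43.9),
        ("labeled_bct_social_support", 565, 1501, 37.6),
        ("labeled_bct_shaping_knowledge", 518, 1501, 34.5),
        ("labeled_bct_antecedents", 420, 1501, 28.0),
        ("labeled_bct_regulation", 323, 1501, 21.5),
        ("labeled_bct_natural_consequences", 294, 1501, 19.6),
        ("labeled_bct_goals_and_planning", 246, 1501, 16.4),
        ("labeled_bct_comparison_of_outcomes", 185, 1501, 12.3),
        ("labeled_sa_assertion", 845, 1501, 56.3),
        ("labeled_sa_statement", 555, 1501, 37.0),
        ("labeled_sa_directive", 392, 1501, 26.1),
        ("labeled_sa_question", 304, 1501, 20.3),
        ("labeled_sa_stance", 260, 1501, 17.3),
    ]
)

#: The community's canonical worked signature and its persona classification.
WORKED_SIGNATURE = (
    "Diagnosed: February 2017, I went diet controlled with type 2 diabetes. "
    "Meds: metformin 500 mg twice a day"
)
WORKED_SIGNATURE_PERSONA = (
    MedicationStatus.ORAL_ONLY,
    DiagnosisStatus.PRE_EXISTING,
    LifestyleStatus.YES,
)
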