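"""Rule-based extraction of self-management personas from forum signatures.

Community users often state their regimen in a forum signature, e.g.::

    Diagnosed: February 2017, I went diet controlled with type 2 diabetes.
    Meds: metformin 500 mg twice a day

Extraction is lexicon driven and total: absence of evidence maps to
``no_information`` (medication, diagnosis) or ``no`` (lifestyle), never an
error.  Rules:

* medication — oral and injectable lexicon hits co-occurring give ``both``;
  a medication hit overrides any explicit no-medication phrase; a
  no-medication phrase alone ("no meds", "diet controlled") gives
  ``no_medications``.
* diagnosis — the earliest 4-digit year adjacent to a diagnosis cue
  ("diagnosed", "dx", "since") decides newly diagnosed (>= cutoff year,
  default 2018) versus pre-existing; bare years without a cue are ignored so
  that dosages and glucose readings are never read as years.
* lifestyle — ``yes`` iff any lifestyle lexicon hit ("diet controlled"
  counts as both no-medication evidence and a lifestyle change).
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .records import DiagnosisStatus, LifestyleStatus, MedicationStatus, UserPersona

ORAL_MEDICATIONS = ("metformin", "glipizide")
INJECTABLE_MEDICATIONS = ("novolog", "lantus")
LIFESTYLE_TERMS = (
    "low-carb",
    "low-carbohydrate",
    "low carb",
    "low carbohydrate",
    "mediterranean",
    "treadmill",
    "walking",
    "diet",
)
NO_MEDICATION_PHRASES = ("no meds", "diet controlled", "no medications")
DIAGNOSIS_CUES = ("diagnosed", "diagnosis", "dx", "since")

#: Earliest plausible self-reported diagnosis year.
_MIN_YEAR = 1940
_MAX_YEAR = 2100
#: Characters after a cue within which a 4-digit year is taken as adjacent.
_CUE_WINDOW = 40

_YEAR_RE = re.compile(r"\b(19[4-9]\d|20\d\d)\b")


def _contains_word(text: str, term: str) -> bool:
    return re.search(r"(?<!\w)" + re.escape(term) + r"(?!\w)", text) is not None


def _diagnosis_year(text: str) -> Optional[int]:
    """Earliest 4-digit year adjacent to a diagnosis cue, or None."""
    years: list[int] = []
    for cue in DIAGNOSIS_CUES:
        for m in re.finditer(r"(?<!\w)" + re.escape(cue) + r"(?!\w)", text):
            window = text[m.end() : m.end() + _CUE_WINDOW]
            hit = _YEAR_RE.search(window)
            if hit:
                years.append(int(hit.group()))
    valid = [y for y in years if _MIN_YEAR <= y <= _MAX_YEAR]
    return min(valid) if valid else None


def extract_persona(
    signature_text: Optional[str],
    user_id: str,
    cutoff_year: int = 2018,
    *,
    oral_lexicon: Iterable[str] = ORAL_MEDICATIONS,
    injectable_lexicon: Iterable[str] = INJECTABLE_MEDICATIONS,
    lifestyle_lexicon: Iterable[str] = LIFESTYLE_TERMS,
    no_medication_phrases: Iterable[str] = NO_MEDICATION_PHRASES,
) -> UserPersona:
    """Classify one signature into a :class:`UserPersona`.

    Deterministic, idempotent, and insensitive to sentence order: every rule
    is a global predicate over the lowercased text.
    """
    text = (signature_text or "").lower()

    oral = any(_contains_word(text, t) for t in oral_lexicon)
    injectable = any(_contains_word(text, t) for t in injectable_lexicon)
    no_meds = any(p in text for p in no_medication_phrases)

    if oral and injectable:
        medication = MedicationStatus.BOTH
    elif oral:
        medication = MedicationStatus.ORAL_ONLY
    elif injectable:
        medication = MedicationStatus.INJECTABLE_ONLY
    elif no_meds:
        medication = MedicationStatus.NO_MEDICATIONS
    else:
        medication = MedicationStatus.NO_INFORMATION

    year = _diagnosis_year(text)
    if year is None:
        diagnosis = DiagnosisStatus.NO_INFORMATION
    elif year >= cutoff_year:
        diagnosis = DiagnosisStatus.NEWLY_DIAGNOSED
    else:
        diagnosis = DiagnosisStatus.PRE_EXISTING

    lifestyle = (
        LifestyleStatus.YES
        if any(_contains_word(text, t) for t in lifestyle_lexicon)
        else LifestyleStatus.NO
    )

    return UserPersona(
        user_id=user_id,
        medication_status=medication,
        diagnosis_status=diagnosis,
        lifestyle_status=lifestyle,
        signature_text=signature_text,
    )
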