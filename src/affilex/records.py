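"""Core record types: forum messages and user behavior personas."""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

from .vocab import Bct, SpeechAct, Theme


@dataclasses.dataclass(frozen=True)
class MessageRecord:
    """One forum post with its user, topic, year, and multi-label tags.

    ``themes`` and ``speech_acts`` may be empty: unlabeled messages stay in
    corpus summaries and engagement counts but never enter a network.
    """

    message_id: str
    user_id: str
    topic_id: str
    year: int
    text: Optional[str] = None
    themes: frozenset[Theme] = frozenset()
    speech_acts: frozenset[SpeechAct] = frozenset()
    bcts: frozenset[Bct] = frozenset()


class MedicationStatus(str, enum.Enum):
    ORAL_ONLY = "oral_only"
    INJECTABLE_ONLY = "injectable_only"
    BOTH = "both"
    NO_MEDICATIONS = "no_medications"
    NO_INFORMATION = "no_information"


class DiagnosisStatus(str, enum.Enum):
    PRE_EXISTING = "pre_existing"
    NEWLY_DIAGNOSED = "newly_diagnosed"
    NO_INFORMATION = "no_information"


class LifestyleStatus(str, enum.Enum):
    YES = "yes"
    NO = "no"


@dataclasses.dataclass(frozen=True)
class UserPersona:
    """Diabetes self-management persona parsed from a signature string.

    One value per axis; a user with no signature gets
    (no_information, no_information, no).
    """

    user_id: str
    medication_status: MedicationStatus = MedicationStatus.NO_INFORMATION
    diagnosis_status: DiagnosisStatus = DiagnosisStatus.NO_INFORMATION
    lifestyle_status: LifestyleStatus = LifestyleStatus.NO
    signature_text: Optional[str] = None
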