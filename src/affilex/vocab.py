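"""Closed label vocabularies for communication themes, speech acts, and BCTs.

The unit of analysis is a forum message carrying multi-label tags along three
dimensions: communication theme (what the message is about), speech act (the
pragmatic form of the utterance), and optionally a behavior change technique.
Speech acts partition into two communication styles: one-directional
"push-in" delivery versus engagement-seeking "interactive turn-taking".
"""

from __future__ import annotations

import enum


class Theme(str, enum.Enum):
    """The six communication themes used in the affiliation exposure analysis."""

    SOCIAL_SUPPORT = "social_support"
    READINESS_REGULATORS = "readiness_regulators"
    PHARMACOTHERAPY = "pharmacotherapy"
    OBSTACLES = "obstacles"
    PATIENT_REPORTED_OUTCOMES = "patient_reported_outcomes"
    PROGRESS = "progress"

    @classmethod
    def parse(cls, token: str) -> "Theme":
        return _parse(cls, token, "theme")


class SpeechAct(str, enum.Enum):
    """The eight analyzed speech-act categories (the k = 1..8 event mode)."""

    ASSERTION = "assertion"
    STATEMENT = "statement"
    DIRECTIVE = "directive"
    QUESTION = "question"
    EMOTION = "emotion"
    STANCE = "stance"
    DECLARATIVE = "declarative"
    EXPRESSIVE = "expressive"

    @classmethod
    def parse(cls, token: str) -> "SpeechAct":
        return _parse(cls, token, "speech act")


class Bct(str, enum.Enum):
    """Behavior change technique taxonomy groups tagged on messages."""

    FEEDBACK_AND_MONITORING = "feedback_and_monitoring"
    SOCIAL_SUPPORT = "social_support"
    SHAPING_KNOWLEDGE = "shaping_knowledge"
    ANTECEDENTS = "antecedents"
    REGULATION = "regulation"
    NATURAL_CONSEQUENCES = "natural_consequences"
    GOALS_AND_PLANNING = "goals_and_planning"
    COMPARISON_OF_OUTCOMES = "comparison_of_outcomes"

    @classmethod
    def parse(cls, token: str) -> "Bct":
        return _parse(cls, token, "BCT")


#: Push-in style: the sender pushes information at the receiver.
PUSH_IN = frozenset(
    {
        SpeechAct.ASSERTION,
        SpeechAct.STANCE,
        SpeechAct.DECLARATIVE,
        SpeechAct.DIRECTIVE,
        SpeechAct.STATEMENT,
    }
)

#: Interactive turn-taking style: the sender pulls peers into an exchange.
INTERACTIVE = frozenset(
    {SpeechAct.QUESTION, SpeechAct.EXPRESSIVE, SpeechAct.EMOTION}
)

COMMUNICATION_STYLES = {"push_in": PUSH_IN, "interactive_turn_taking": INTERACTIVE}

assert PUSH_IN.isdisjoint(INTERACTIVE)
assert PUSH_IN | INTERACTIVE == frozenset(SpeechAct)


def _parse(cls, token: str, kind: str):
    from .errors import VocabularyError

    key = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return cls(key)
    except ValueError:
        raise VocabularyError(
            f"unknown {kind} token {token!r}; allowed: "
            + ", ".join(v.value for v in cls)
        ) from None


def speech_act_order(subset=None) -> list[SpeechAct]:
    """Speech acts in declaration order, optionally restricted to a subset.

    Column order of every affiliation matrix is fixed by this ordering.
    """
    acts = list(SpeechAct)
    if subset is None:
        return acts
    subset = frozenset(subset)
    return [a for a in acts if a in subset]
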