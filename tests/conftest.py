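import numpy as np
import pytest

from affilex import MessageRecord
from affilex.vocab import Bct, SpeechAct, Theme


def msg(mid, user, topic="t1", year=2014, themes=(), acts=(), bcts=()):
    """Terse MessageRecord builder for hand-made corpora."""
    return MessageRecord(
        message_id=mid,
        user_id=user,
        topic_id=topic,
        year=year,
        themes=frozenset(Theme(t) for t in themes),
        speech_acts=frozenset(SpeechAct(a) for a in acts),
        bcts=frozenset(Bct(b) for b in bcts),
    )


@pytest.fixture
def toy_corpus():
    """Three users in the obstacles theme plus off-theme noise."""
    return [
        msg("m1", "u1", themes=["obstacles"], acts=["assertion"]),
        msg("m2", "u2", themes=["social_support"], acts=["question"]),
        msg("m3", "u3", themes=["obstacles"], acts=["assertion", "stance"]),
        msg("m4", "u1", themes=["obstacles"], acts=["assertion"]),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
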