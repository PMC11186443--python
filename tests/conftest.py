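from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from turnload.corpus import TaggedToken, Turn, select_turns

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_turn(conv: str, tid: str, speaker: str, pairs: list[tuple[str, str]]) -> Turn:
    return Turn(
        conversation_id=conv, turn_id=tid, speaker_id=speaker,
        tokens=tuple(TaggedToken(f, t) for f, t in pairs),
    )


@pytest.fixture
def tiny_turns() -> list[Turn]:
    """Three hand-built turns exercising classes, hapaxes and pro-forms."""
    return [
        make_turn("c1", "t1", "s1",
                  [("well", "RR"), ("i", "PPIS1"), ("like", "VV0"),
                   ("the", "AT"), ("house", "NN1")]),
        make_turn("c1", "t2", "s2",
                  [("oh", "UH"), ("that", "DD1"), ("is", "VBZ"),
                   ("nice", "JJ")]),
        make_turn("c2", "t1", "s3",
                  [("i", "PPIS1"), ("like", "VV0"), ("cats", "NN2")]),
    ]


@pytest.fixture
def tiny_subset(tiny_turns):
    return select_turns(tiny_turns, 3, 25)


def vertical_frame(turns: list[Turn]) -> pd.DataFrame:
    rows = []
    for t in turns:
        for i, tok in enumerate(t.tokens, start=1):
            rows.append((t.conversation_id, t.turn_id, t.speaker_id,
                         "speaker", i, tok.form, tok.tag))
    return pd.DataFrame(rows, columns=[
        "conversation_id", "turn_id", "speaker_id", "role", "index",
        "form", "tag"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240605)
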