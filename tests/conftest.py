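import numpy as np
import pytest

from conflictdyn import (
    BehaviorGenParams,
    EmotionGenParams,
    SessionRecord,
    StudyGenConfig,
    StudyTable,
    generate_study,
)


@pytest.fixture(scope="session")
def small_gen_config() -> StudyGenConfig:
    """A scaled-down study (3 + 3 dyads, 10-minute sessions) for fast tests."""
    return StudyGenConfig(
        n_intractable_dyads=3,
        n_tractable_dyads=3,
        intractable_behavior=BehaviorGenParams(session_length=600),
        tractable_behavior=BehaviorGenParams(session_length=600),
        intractable_emotion=EmotionGenParams(session_length=600),
        tractable_emotion=EmotionGenParams(session_length=600),
        missing_person_rate=0.0,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_gen_config) -> StudyTable:
    return generate_study(small_gen_config)


@pytest.fixture()
def mixed_study() -> StudyTable:
    """Hand-built study with absent streams and a lone person in one dyad."""
    rng = np.random.default_rng(5)
    behavior = rng.integers(1, 4, size=30)
    emotion = rng.integers(0, 1124, size=30)
    return StudyTable(
        records=[
            SessionRecord("d01", 1, "intractable", behavior.copy(), emotion.copy()),
            SessionRecord("d01", 2, "intractable", behavior.copy(), None),
            SessionRecord("d02", 1, "tractable", None, emotion.copy()),
        ],
        provenance="fixture",
    )
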