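import numpy as np
import pytest

from pecktrack.data import (
    DisplayGeometry,
    PeckEvent,
    Session,
    Trial,
    select_pool,
)
from pecktrack.simulate import GeneratorConfig, generate_session, make_archetype


def make_trial(
    trial_index: int,
    stimulus_class: str = "X",
    outcome: str = "correct",
    pecks=None,
    trial_type: str = "known",
) -> Trial:
    """Hand-built trial with sane defaults for unit tests."""
    if pecks is None:
        pecks = [PeckEvent(x=2.5, y=2.5, peck_index=i) for i in range(1, 6)]
    choice = (
        stimulus_class
        if outcome == "correct"
        else ("none" if outcome in ("aborted", "no_choice") else ("Y" if stimulus_class == "X" else "X"))
    )
    return Trial(
        trial_index=trial_index,
        phase="transfer_test",
        trial_type=trial_type,
        stimulus_id=f"{stimulus_class}01",
        stimulus_class=stimulus_class,
        choice=choice,
        outcome=outcome,
        reinforcement="differential",
        pecks=pecks,
    )


@pytest.fixture
def geometry() -> DisplayGeometry:
    return DisplayGeometry()


@pytest.fixture
def simple_session(geometry) -> Session:
    """10 correct class-X trials of 5 pecks each."""
    return Session(
        subject_id="p1",
        session_id="s1",
        geometry=geometry,
        trials=[make_trial(i) for i in range(1, 11)],
    )


@pytest.fixture(scope="session")
def two_class_session():
    return generate_session(make_archetype("two_class"), GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def two_class_correct_pool(two_class_session):
    return select_pool(two_class_session, outcomes={"correct"})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
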