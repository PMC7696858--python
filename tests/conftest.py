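import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_records():
    """A handful of events in one 3-animal pen: A attacks B twice, B once back."""
    from agonet.ingest import ObservationRecord

    return [
        ObservationRecord("p1", "s1", "head_knock", "A", "B"),
        ObservationRecord("p1", "s1", "bite", "A", "B"),
        ObservationRecord("p1", "s2", "head_knock", "B", "A"),
    ]


@pytest.fixture
def toy_roster():
    from agonet.ingest import PenRoster

    return PenRoster(pen_id="p1", animals=("A", "B", "C"), sex_group="gilts")
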