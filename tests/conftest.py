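from datetime import datetime, timedelta

import pytest

from rtlsval import Session, netluky_layout

EPOCH = datetime(2023, 1, 19, 9, 0, 0)


def make_session(duration: float, label: str = "", start: datetime = EPOCH) -> Session:
    return Session(start=start, end=start + timedelta(seconds=duration), period_label=label)


@pytest.fixture(scope="session")
def layout():
    return netluky_layout()


@pytest.fixture
def session600():
    return make_session(600.0)
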