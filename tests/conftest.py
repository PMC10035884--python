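import warnings

import numpy as np
import pytest

from fmtheta import protocol
from fmtheta.types import EEGRecord, SignalSegment, SubjectParams

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")


@pytest.fixture
def alt_params() -> SubjectParams:
    return SubjectParams(
        subject_id="ALT01", group="ALT", up_gain=2.0, down_gain=0.5,
        tet50_ms=750.0, tet90_ms=1100.0, commission_prob=0.25,
    )


@pytest.fixture
def inc_params() -> SubjectParams:
    return SubjectParams(subject_id="INC01", group="INC", down_gain=1.0)


@pytest.fixture
def alt_session(alt_params):
    goals = protocol.assign_block_goals(alt_params.group, seed=3)
    return protocol.build_session_timeline(1, goals)


@pytest.fixture
def zero_record() -> EEGRecord:
    return EEGRecord(segment=SignalSegment(np.zeros(2048 * 10), 2048.0))


def make_enemy_run(tet_ms: float, n: int):
    """All-enemy single-block schedule at a constant exposure time."""
    from fmtheta.types import Condition, Identity, TargetEvent, TargetSchedule

    events = []
    onset = 0.0
    for i in range(n):
        onset += 1000.0
        events.append(
            TargetEvent(index=i, lane="center", distance="mid",
                        identity=Identity.ENEMY, onset_ms=onset, tet_ms=tet_ms)
        )
        onset += tet_ms
    return TargetSchedule(condition=Condition.FTP, blocks=[events])


def make_friendly_run(tet_ms: float, n: int):
    from fmtheta.types import Condition, Identity, TargetEvent, TargetSchedule

    events = []
    onset = 0.0
    for i in range(n):
        onset += 1000.0
        events.append(
            TargetEvent(index=i, lane="center", distance="mid",
                        identity=Identity.FRIENDLY, onset_ms=onset, tet_ms=tet_ms)
        )
        onset += tet_ms
    return TargetSchedule(condition=Condition.FTP, blocks=[events])
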