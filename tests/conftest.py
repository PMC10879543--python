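import numpy as np
import pytest
from hypothesis import settings

from dyadkit.ethogram_io import (CallRecord, EventRecord, SessionMeta,
                                 build_session)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_meta(session_id="s1", pnd=10, **kw) -> SessionMeta:
    defaults = dict(session_id=session_id, family_id="F0",
                    caregiver_id="F0-mother", caregiver_role="mother",
                    infant_id="F0-i0", infant_sex="M", pnd=pnd,
                    rearing="family", assay="retrieval",
                    nominal_duration=600.0, birth_id="F0:b0")
    defaults.update(kw)
    return SessionMeta(**defaults)


def ev(behavior, onset, offset, actor="caregiver", sid="s1") -> EventRecord:
    return EventRecord(sid, actor, behavior, onset, offset)


@pytest.fixture
def reference_session():
    """Hand-built session: retrieval 30 s, transport 30-50, holding 50-100,
    rejection 100-102, dismount 103, alone to the 630-s window end."""
    events = [
        ev("retrieval", 30.0, 30.2),
        ev("carry_contact", 30.0, 103.0, actor="infant"),
        ev("locomotion", 30.0, 50.0),
        ev("rejection", 100.0, 102.0),
        ev("dismount", 103.0, 103.2, actor="infant"),
    ]
    return build_session(make_meta(), events)


@pytest.fixture
def carried_session():
    """Session with 580 s of carrying, one 2-s rejection, retrieval at 30 s."""
    events = [
        ev("retrieval", 30.0, 30.2),
        ev("carry_contact", 30.0, 610.0, actor="infant"),
        ev("rejection", 100.0, 102.0),
    ]
    return build_session(make_meta(session_id="s2"), events)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
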