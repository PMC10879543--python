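"""Partition of a session into the five mutually exclusive social contexts.

From the infant's viewpoint a retrieval-assay session decomposes into:

* ``Alone_BeforeRET`` -- not yet carried, before the first retrieval;
* ``Holding``         -- carried, caregiver stationary;
* ``Transport``       -- carried, caregiver locomoting;
* ``During_Rejection``-- from the start of a rejection bout until
  ``offset_s`` (default 9.4 s) after its end, the window in which infant
  behavior is still under the direct influence of the rejection;
* ``Alone_AfterRET``  -- not carried, after the first retrieval.

The five labels tile the analysis window exactly.  Precedence when
definitions overlap: ``During_Rejection`` > ``Transport``/``Holding`` >
``Alone_AfterRET``.  Segmentation is done in integer ticks of the 0.2-s
coding grid so the partition property holds with exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ethogram_io import BIN_WIDTH, SessionData, to_ticks

ALONE_BEFORE = "Alone_BeforeRET"
HOLDING = "Holding"
TRANSPORT = "Transport"
DURING_REJECTION = "During_Rejection"
ALONE_AFTER = "Alone_AfterRET"

CONTEXTS = (ALONE_BEFORE, HOLDING, TRANSPORT, DURING_REJECTION, ALONE_AFTER)

#: Contexts in which the infant is on the caregiver's body.
CARRIED_CONTEXTS = (HOLDING, TRANSPORT)
ALONE_CONTEXTS = (ALONE_BEFORE, ALONE_AFTER)

#: Default post-rejection influence window (s); the rounded breakpoint of the
#: rejection-to-dismount log-survivorship fit.
DEFAULT_OFFSET_S = 9.4


@dataclass
class ContextTimeline:
    """Ordered, contiguous, exhaustive labeling of the analysis window."""

    session_id: str
    segments: list[tuple[float, float, str]]   # (start_s, end_s, label)
    offset_s: float
    window: tuple[float, float]

    def duration(self, label: str) -> float:
        return sum(e - s for s, e, lab in self.segments if lab == label)


class SegmentationError(ValueError):
    pass


def segment_contexts(session: SessionData,
                     offset_s: float = DEFAULT_OFFSET_S) -> ContextTimeline:
    """Label every instant of the analysis window with its social context.

    Works on the 0.2-s tick grid: each tick gets the highest-precedence
    label whose definition covers it, and runs of equal labels are merged
    into half-open segments.
    """
    w_ticks = to_ticks(session.window_end)
    if w_ticks <= 0:
        raise SegmentationError(
            f"session {session.meta.session_id}: empty analysis window")
    off_ticks = round(float(offset_s) / BIN_WIDTH)
    if off_ticks < 0:
        raise SegmentationError("offset_s must be >= 0")

    # per-tick labels, filled lowest precedence first
    lab = np.empty(w_ticks, dtype="<U16")
    if session.retrieval_time is None:
        lab[:] = ALONE_BEFORE
    else:
        ret = to_ticks(session.retrieval_time)
        lab[:ret] = ALONE_BEFORE
        lab[ret:] = ALONE_AFTER

        for e in session.events:
            if e.behavior == "carry_contact":
                a, b = to_ticks(e.onset), min(to_ticks(e.offset), w_ticks)
                lab[a:b] = HOLDING
        for e in session.events:
            if e.behavior != "locomotion":
                continue
            a, b = to_ticks(e.onset), min(to_ticks(e.offset), w_ticks)
            seg = lab[a:b]
            seg[seg == HOLDING] = TRANSPORT
        for e in session.events:
            if e.behavior != "rejection":
                continue
            a = to_ticks(e.onset)
            b = min(to_ticks(e.offset) + off_ticks, w_ticks)
            lab[a:b] = DURING_REJECTION

    segments: list[tuple[float, float, str]] = []
    start = 0
    for i in range(1, w_ticks + 1):
        if i == w_ticks or lab[i] != lab[start]:
            segments.append((round(start * BIN_WIDTH, 1),
                             round(i * BIN_WIDTH, 1), str(lab[start])))
            start = i
    return ContextTimeline(session_id=session.meta.session_id,
                           segments=segments, offset_s=offset_s,
                           window=(0.0, round(w_ticks * BIN_WIDTH, 1)))


@dataclass
class ContextDurations:
    durations: dict[str, float]     # s per context
    proportions: dict[str, float]   # fraction of window
    window_s: float


def context_durations(timeline: ContextTimeline) -> ContextDurations:
    """Total duration and window proportion of each of the five contexts."""
    window_s = timeline.window[1] - timeline.window[0]
    durations = {c: 0.0 for c in CONTEXTS}
    for s, e, labl in timeline.segments:
        durations[labl] += e - s
    proportions = {c: durations[c] / window_s for c in CONTEXTS}
    return ContextDurations(durations=durations, proportions=proportions,
                            window_s=window_s)


def locate_transitions(timeline: ContextTimeline, from_label: str,
                       to_label: str,
                       window_s: float = 10.0) -> list[tuple[float, bool]]:
    """Boundaries where ``from_label`` ends and ``to_label`` begins.

    Returns ``(time, has_full_windows)`` pairs; ``has_full_windows`` is True
    iff both the pre-window ``[t-window_s, t)`` and the post-window
    ``[t, t+window_s)`` lie inside the analysis window.
    """
    if from_label == to_label:
        raise ValueError("from_label and to_label must differ")
    w0, w1 = timeline.window
    out: list[tuple[float, bool]] = []
    segs = timeline.segments
    for (s0, e0, l0), (s1, e1, l1) in zip(segs, segs[1:]):
        if l0 == from_label and l1 == to_label:
            t = e0
            full = (t - window_s >= w0) and (t + window_s <= w1)
            out.append((t, full))
    return out


def timeline_to_frame(timeline: ContextTimeline):
    """Timeline as a DataFrame for CSV export."""
    import pandas as pd
    return pd.DataFrame(
        [{"session_id": timeline.session_id, "start_s": s, "end_s": e,
          "context": labl} for s, e, labl in timeline.segments])
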