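"""Per-session caregiver parenting parameters and infant attachment metrics.

Caregiver side, three parameters summarize (allo)parenting style:

* ``RET_Latency`` -- time to first retrieval (inversely, the caregiver's
  *sensitivity* to infant distress); censored at the window end when no
  retrieval occurred;
* ``%Rejection`` -- rejection-bout duration as a percentage of carrying
  time (inversely, *tolerance* to carrying);
* ``%Carry`` -- carrying duration as a percentage of session length (net
  care *quantity*).

Infant side, atypical-attachment indicators: avoidant behaviors (voluntary
dismounts plus refusals to cling on contact) and calling while being
carried, plus per-context call frequencies and call-type usage.  Dyad-level
aggregation supports the distance comparison between the two littermate
infants of one caregiver (DI_SC) and the same infant with two caregivers
(SI_DC) in min-max-normalized metric space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .context_segmentation import (ALONE_AFTER, ALONE_BEFORE, ALONE_CONTEXTS,
                                   CARRIED_CONTEXTS, CONTEXTS,
                                   DURING_REJECTION, ContextTimeline,
                                   locate_transitions)
from .ethogram_io import EventRecord, SessionData

#: Call types reported per context; rarer types collapse into "other".
REPORTED_CALL_TYPES = ("phee", "twitter", "tsik", "trill", "cry", "other")

#: Age (postnatal days) below which avoidant behavior counts as premature.
PREMATURE_PND_CUT = 28

#: Minimum duration (s) of a caregiver contact bout that can count as a
#: cling refusal when the infant shows no cling onset within it.
MIN_REFUSAL_CONTACT_S = 1.0


# ---------------------------------------------------------------------------
# caregiver parameters
# ---------------------------------------------------------------------------

@dataclass
class ParentingParams:
    session_id: str
    ret_latency_s: float
    censored: bool                      # True when no retrieval occurred
    pct_carry: float                    # % of window
    pct_rejection: Optional[float]      # % of carried time; None if never carried


def _union_duration(intervals: Iterable[tuple[float, float]]) -> float:
    ivs = sorted(intervals)
    total, cur_end = 0.0, -math.inf
    cur_start = None
    for a, b in ivs:
        if cur_start is None or a > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def parenting_params(session: SessionData, timeline: ContextTimeline,
                     rejection_denominator: str = "carried"
                     ) -> ParentingParams:
    """Compute RET_Latency, %Carry, %Rejection for one session.

    Carrying and rejection durations are unions of the coded bouts (the
    context timeline is not used for them because ``During_Rejection``
    overrides the carried contexts while the infant is typically still on
    the carrier).  ``rejection_denominator``: ``"carried"`` (default;
    rejecting time / carrying time, the family-reunion convention),
    ``"session"``, or ``"bouts"`` (rejection bout count / carrying bout
    count).
    """
    window_s = session.window_end
    carried = _union_duration((e.onset, e.offset) for e in session.events
                              if e.behavior == "carry_contact")
    rej_ivs = [(e.onset, e.offset) for e in session.events
               if e.behavior == "rejection"]
    rejected = _union_duration(rej_ivs)

    if session.retrieval_time is None:
        latency, censored = window_s, True
    else:
        latency, censored = session.retrieval_time, False

    pct_carry = 100.0 * carried / window_s
    if rejection_denominator == "carried":
        pct_rej = 100.0 * rejected / carried if carried > 0 else None
    elif rejection_denominator == "session":
        pct_rej = 100.0 * rejected / window_s
    elif rejection_denominator == "bouts":
        n_carry = sum(1 for e in session.events
                      if e.behavior == "carry_contact")
        pct_rej = 100.0 * len(rej_ivs) / n_carry if n_carry else None
    else:
        raise ValueError(
            f"unknown rejection_denominator {rejection_denominator!r}")
    return ParentingParams(session_id=session.meta.session_id,
                           ret_latency_s=latency, censored=censored,
                           pct_carry=pct_carry, pct_rejection=pct_rej)


# ---------------------------------------------------------------------------
# infant metrics
# ---------------------------------------------------------------------------

@dataclass
class InfantMetrics:
    session_id: str
    avoidance_count: int
    voluntary_dismounts: int
    cling_refusals: int
    calls_carried_per_min: Optional[float]
    calls_alone_per_min: Optional[float]
    calls_rejection_per_min: Optional[float]
    context_call_freq: dict[str, Optional[float]]     # calls/min per context
    context_type_props: dict[str, Optional[dict[str, float]]]
    premature: bool


def _context_at(timeline: ContextTimeline, t: float) -> Optional[str]:
    for s, e, lab in timeline.segments:
        if s <= t < e:
            return lab
    return None


def _reported_type(call_type: str) -> str:
    return call_type if call_type in REPORTED_CALL_TYPES else "other"


def count_cling_refusals(session: SessionData) -> int:
    """Refusals to cling when contacted.

    If the coder used an explicit ``refusal`` code, those events are
    trusted and counted directly.  Otherwise a caregiver ``contact`` bout
    of at least 1 s containing no infant ``cling`` onset is a refusal
    (fleeting touches shorter than 1 s are ignored as ambiguous).
    """
    explicit = [e for e in session.events if e.behavior == "refusal"]
    if explicit:
        return len(explicit)
    cling_onsets = [e.onset for e in session.events
                    if e.behavior == "cling" and e.actor == "infant"]
    n = 0
    for e in session.events:
        if e.behavior != "contact" or e.actor != "caregiver":
            continue
        if e.duration() < MIN_REFUSAL_CONTACT_S:
            continue
        if not any(e.onset <= t < e.offset for t in cling_onsets):
            n += 1
    return n


def infant_metrics(session: SessionData, timeline: ContextTimeline,
                   dismount_labels: Sequence[str]) -> InfantMetrics:
    """Infant attachment metrics for one segmented session.

    ``dismount_labels`` are the forced/voluntary labels of this session's
    dismounts in event order.  A call belongs to the context at its onset;
    calls while carried exclude ``During_Rejection`` (contexts are
    exclusive; rejection-period calls are reported separately).  A context
    with zero duration has no defined frequency (None, not 0).
    """
    dismounts = [e for e in session.events if e.behavior == "dismount"]
    if len(dismounts) != len(dismount_labels):
        raise ValueError("dismount_labels must align with the session's "
                         f"dismounts ({len(dismounts)} events, "
                         f"{len(dismount_labels)} labels)")
    voluntary = sum(1 for lab in dismount_labels if lab == "voluntary")
    refusals = count_cling_refusals(session)

    ctx_dur = {c: timeline.duration(c) for c in CONTEXTS}
    ctx_calls: dict[str, list[str]] = {c: [] for c in CONTEXTS}
    for call in session.calls:
        if call.caller != "infant":
            continue
        ctx = _context_at(timeline, call.onset)
        if ctx is not None:
            ctx_calls[ctx].append(_reported_type(call.call_type))

    def freq(contexts: Sequence[str]) -> Optional[float]:
        dur = sum(ctx_dur[c] for c in contexts)
        if dur <= 0:
            return None
        return sum(len(ctx_calls[c]) for c in contexts) / (dur / 60.0)

    context_call_freq = {c: freq([c]) for c in CONTEXTS}
    context_type_props: dict[str, Optional[dict[str, float]]] = {}
    for c in CONTEXTS:
        types = ctx_calls[c]
        if not types:
            context_type_props[c] = None
        else:
            context_type_props[c] = {
                t: types.count(t) / len(types) for t in REPORTED_CALL_TYPES}

    return InfantMetrics(
        session_id=session.meta.session_id,
        avoidance_count=voluntary + refusals,
        voluntary_dismounts=voluntary,
        cling_refusals=refusals,
        calls_carried_per_min=freq(CARRIED_CONTEXTS),
        calls_alone_per_min=freq(ALONE_CONTEXTS),
        calls_rejection_per_min=freq([DURING_REJECTION]),
        context_call_freq=context_call_freq,
        context_type_props=context_type_props,
        premature=session.meta.pnd < PREMATURE_PND_CUT)


# ---------------------------------------------------------------------------
# transition call ratios
# ---------------------------------------------------------------------------

@dataclass
class TransitionCallStats:
    pairs: list[tuple[int, int]]        # (before, after) counts, eligible only
    ratios: list[float]                 # after/before where before > 0
    n_excluded_zero_before: int
    mean_ratio: Optional[float]


def transition_call_ratio(sessions: Sequence[tuple[SessionData,
                                                   ContextTimeline]],
                          from_label: str, to_label: str,
                          window_s: float = 10.0) -> TransitionCallStats:
    """Infant call counts 10 s before vs after each context shift.

    Only transitions with both full windows inside the analysis window are
    eligible.  Transitions with zero calls before are excluded from the
    ratio (undefined) but counted; the paired counts are returned for a
    signed-rank test.
    """
    pairs: list[tuple[int, int]] = []
    for session, timeline in sessions:
        infant_onsets = [c.onset for c in session.calls
                         if c.caller == "infant"]
        for t, full in locate_transitions(timeline, from_label, to_label,
                                          window_s):
            if not full:
                continue
            before = sum(1 for o in infant_onsets if t - window_s <= o < t)
            after = sum(1 for o in infant_onsets if t <= o < t + window_s)
            pairs.append((before, after))
    ratios = [a / b for b, a in pairs if b > 0]
    n_zero = sum(1 for b, _ in pairs if b == 0)
    mean_ratio = float(np.mean(ratios)) if ratios else None
    return TransitionCallStats(pairs=pairs, ratios=ratios,
                               n_excluded_zero_before=n_zero,
                               mean_ratio=mean_ratio)


# ---------------------------------------------------------------------------
# dyad aggregation and the DI_SC / SI_DC distance comparison
# ---------------------------------------------------------------------------

@dataclass
class SessionSummary:
    meta_session_id: str
    caregiver_id: str
    infant_id: str
    birth_id: str
    pnd: int
    params: ParentingParams
    metrics: InfantMetrics


@dataclass
class DyadSummary:
    caregiver_id: str
    infant_id: str
    birth_id: str
    n_sessions: int
    ret_latency_s: Optional[float]      # mean over non-censored sessions
    pct_carry: float
    pct_rejection: Optional[float]      # mean over sessions with carrying
    avoidance_count: float
    calls_carried_per_min: Optional[float]
    sessions: list[SessionSummary] = field(default_factory=list)

    def session_rows(self) -> list[dict]:
        rows = []
        for s in self.sessions:
            rows.append({
                "session_id": s.meta_session_id,
                "caregiver_id": self.caregiver_id,
                "infant_id": self.infant_id,
                "birth_id": self.birth_id,
                "pnd": s.pnd,
                "RET_Latency": s.params.ret_latency_s,
                "censored": int(s.params.censored),
                "pct_Carry": s.params.pct_carry,
                "pct_Rejection": s.params.pct_rejection,
                "avoidance_count": s.metrics.avoidance_count,
                "voluntary_dismounts": s.metrics.voluntary_dismounts,
                "cling_refusals": s.metrics.cling_refusals,
                "calls_carried_per_min": s.metrics.calls_carried_per_min,
                "calls_alone_per_min": s.metrics.calls_alone_per_min,
            })
        return rows

    def dyad_row(self) -> dict:
        return {
            "caregiver_id": self.caregiver_id,
            "infant_id": self.infant_id,
            "birth_id": self.birth_id,
            "n_sessions": self.n_sessions,
            "RET_Latency": self.ret_latency_s,
            "pct_Carry": self.pct_carry,
            "pct_Rejection": self.pct_rejection,
            "avoidance_count": self.avoidance_count,
            "calls_carried_per_min": self.calls_carried_per_min,
        }


def summarize_dyads(summaries: Sequence[SessionSummary]) -> list[DyadSummary]:
    """Average session summaries within each (caregiver, infant, birth) dyad.

    Censored retrieval latencies are excluded from the latency mean (they
    still enter rank-based statistics at session level); %Rejection is
    averaged only over sessions where the infant was carried at all.
    """
    def mean_or_none(vals: list) -> Optional[float]:
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    out = []
    keyfun = lambda s: (s.caregiver_id, s.infant_id, s.birth_id)
    for key, group in itertools.groupby(sorted(summaries, key=keyfun), keyfun):
        g = list(group)
        out.append(DyadSummary(
            caregiver_id=key[0], infant_id=key[1], birth_id=key[2],
            n_sessions=len(g),
            ret_latency_s=mean_or_none(
                [s.params.ret_latency_s for s in g if not s.params.censored]),
            pct_carry=float(np.mean([s.params.pct_carry for s in g])),
            pct_rejection=mean_or_none([s.params.pct_rejection for s in g]),
            avoidance_count=float(np.mean(
                [s.metrics.avoidance_count for s in g])),
            calls_carried_per_min=mean_or_none(
                [s.metrics.calls_carried_per_min for s in g]),
            sessions=g))
    return out


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Affine rescale to [0, 1]: (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("minmax_normalize: need at least 2 values")
    rng = x.max() - x.min()
    if rng == 0:
        raise ValueError("minmax_normalize: constant input (zero range)")
    return (x - x.min()) / rng


@dataclass
class DistancePairs:
    di_sc: list[float]      # same caregiver, two littermate infants
    si_dc: list[float]      # same infant, two caregivers


def dyad_distance_pairs(summaries: Sequence[DyadSummary]) -> DistancePairs:
    """Distances between dyad points in normalized attachment-metric space.

    Each dyad is the 2-D point (avoidance count, calls while carried),
    min-max normalized over all usable dyads.  DI_SC pairs two littermate
    infants sharing one caregiver and birth; SI_DC pairs two caregivers of
    the same infant.  Dyads missing either metric are excluded.
    """
    usable = [d for d in summaries if d.calls_carried_per_min is not None]
    if len(usable) < 2:
        raise ValueError("dyad_distance_pairs: need >= 2 complete dyads")
    av = minmax_normalize([d.avoidance_count for d in usable])
    ca = minmax_normalize([d.calls_carried_per_min for d in usable])
    pts = {(d.caregiver_id, d.infant_id, d.birth_id): (av[i], ca[i])
           for i, d in enumerate(usable)}

    def dist(k1, k2) -> float:
        (x1, y1), (x2, y2) = pts[k1], pts[k2]
        return math.hypot(x1 - x2, y1 - y2)

    di_sc: list[float] = []
    by_cg_birth: dict[tuple, list] = {}
    for d in usable:
        by_cg_birth.setdefault((d.caregiver_id, d.birth_id), []).append(
            (d.caregiver_id, d.infant_id, d.birth_id))
    for ks in by_cg_birth.values():
        for k1, k2 in itertools.combinations(sorted(ks), 2):
            di_sc.append(dist(k1, k2))

    si_dc: list[float] = []
    by_infant: dict[str, list] = {}
    for d in usable:
        by_infant.setdefault(d.infant_id, []).append(
            (d.caregiver_id, d.infant_id, d.birth_id))
    for ks in by_infant.values():
        for k1, k2 in itertools.combinations(sorted(ks), 2):
            si_dc.append(dist(k1, k2))

    if not di_sc or not si_dc:
        raise ValueError("dyad_distance_pairs: need at least one pair of "
                         "each kind (DI_SC and SI_DC)")
    return DistancePairs(di_sc=di_sc, si_dc=si_dc)


# ---------------------------------------------------------------------------
# family-reunion measures
# ---------------------------------------------------------------------------

def one_zero_aggregate(events: Sequence[EventRecord], bin_s: float = 10.0,
                       span: Optional[tuple[float, float]] = None
                       ) -> pd.DataFrame:
    """One-zero sampling: per 10-s bin, 1 iff the behavior occurred at all.

    Returns a DataFrame indexed by bin start with one 0/1 column per
    behavior present in ``events``.
    """
    if span is None:
        end = max((e.offset for e in events), default=0.0)
        span = (0.0, math.ceil(end / bin_s) * bin_s if end > 0 else bin_s)
    start, end = span
    n_bins = int(math.ceil((end - start) / bin_s))
    behaviors = sorted({e.behavior for e in events})
    data = np.zeros((n_bins, len(behaviors)), dtype=int)
    for e in events:
        j = behaviors.index(e.behavior)
        first = max(0, int(math.floor((e.onset - start) / bin_s)))
        last = min(n_bins - 1, int(math.floor((e.offset - start) / bin_s)))
        # half-open events: an offset exactly on a bin edge does not mark
        # the next bin
        if e.offset == start + (last) * bin_s:
            last -= 1
        data[first:last + 1, j] = 1
    index = [start + i * bin_s for i in range(n_bins)]
    return pd.DataFrame(data, index=index, columns=behaviors)


def classify_transfers(carrier_sequence: Sequence[Optional[str]]
                       ) -> list[dict]:
    """Classify carrier-to-carrier transfers as direct or nondirect.

    ``carrier_sequence`` is the per-bin carrier identity (None when the
    infant is not carried).  A transfer is a change of carrier; direct iff
    no not-carried bin intervenes, nondirect when the infant spent at
    least one bin alone between the two carriers.
    """
    out: list[dict] = []
    prev_carrier: Optional[str] = None
    gap = 0
    for i, c in enumerate(carrier_sequence):
        if c is None:
            if prev_carrier is not None:
                gap += 1
            continue
        if prev_carrier is not None and c != prev_carrier:
            out.append({"bin": i, "from": prev_carrier, "to": c,
                        "kind": "direct" if gap == 0 else "nondirect"})
        prev_carrier = c
        gap = 0
    return out
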