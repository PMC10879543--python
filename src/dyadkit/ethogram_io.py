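"""Reading, validation and writing of behavioral event streams and call tables.

Behavior of a caregiver-infant dyad is coded as intervals on a 0.2-s grid
(the temporal resolution of the frame-by-frame coding).  This module ingests
three kinds of files:

* **event CSV** -- one row per coded behavior bout with columns
  ``session_id, actor, behavior, onset_s, offset_s``;
* **call tables** -- either a CSV (``session_id, caller, call_type,
  onset_s, offset_s``) or a PRAAT TextGrid with one interval tier per
  caller;
* **metadata CSV** -- one row per session.

Times are stored internally as continuous seconds and intervals are
half-open ``[onset, offset)``; the 0.2-s bin is an *ingestion* grid onto
which raw times are snapped, not the internal representation.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger("dyadkit")

#: Coding grid width in seconds.
BIN_WIDTH = 0.2

#: Behavior codes the pipeline interprets.  The coding vocabulary of manual
#: ethograms drifts between labs; unknown codes are preserved with a warning
#: rather than rejected, and the set can be extended at run time.
KNOWN_BEHAVIORS = {
    "carry_contact",   # infant on the caregiver's body (carrying bout)
    "locomotion",      # caregiver walking/running/jumping
    "rejection",       # rolling, pushing, biting directed at the carried infant
    "contact",         # caregiver in physical contact without carrying
    "cling",           # infant grasps the caregiver
    "dismount",        # infant leaves the carrier's body
    "retrieval",       # all infant limbs contact the caregiver: carrying starts
    "refusal",         # explicitly coded refusal to cling
    "in_basket",       # caregiver manipulates the (empty or infant) basket
    "attack",
    "breastfeeding",
}

#: Closed call-type vocabulary.
CALL_TYPES = (
    "phee", "twitter", "tsik", "trill", "chatter", "chirp", "cry",
    "combination", "other",
)

#: Common annotation aliases; the infant distress call is variously
#: transcribed "cry", "ngä" or "nga".
_CALL_ALIASES = {
    "ngä": "cry", "nga": "cry", "ngae": "cry",
    "tsik-egg": "tsik", "phee-cry": "combination",
}

_CALLERS = ("infant", "caregiver", "unspecified")
_CALLER_ALIASES = {"unclear": "unspecified", "unknown": "unspecified",
                   "ambiguous": "unspecified"}


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class RecordError(ValueError):
    """A single row violates a record invariant."""


class ValidationError(ValueError):
    """Session-level consistency check failed."""


# ---------------------------------------------------------------------------
# grid arithmetic
# ---------------------------------------------------------------------------

def snap_to_grid(t: float, bin_width: float = BIN_WIDTH) -> float:
    """Snap a time to the coding grid.

    Round-half-even to one decimal first, then to the nearest multiple of
    ``bin_width`` -- deterministic across platforms.
    """
    t1 = round(float(t), 1)
    k = round(t1 / bin_width)
    return round(k * bin_width, 1)


def to_ticks(t: float, bin_width: float = BIN_WIDTH) -> int:
    """Integer tick index of a grid-snapped time (exact arithmetic helper)."""
    return round(snap_to_grid(t, bin_width) / bin_width)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EventRecord:
    """One coded behavior bout, half-open interval ``[onset, offset)``."""

    session_id: str
    actor: str          # {"caregiver", "infant"}
    behavior: str
    onset: float        # s from shutter opening
    offset: float       # s

    def duration(self) -> float:
        return self.offset - self.onset

    def overlaps(self, start: float, end: float) -> bool:
        return self.onset < end and self.offset > start


@dataclass
class CallRecord:
    """One annotated vocalization."""

    session_id: str
    caller: str         # {"infant", "caregiver", "unspecified"}
    call_type: str
    onset: float
    offset: float

    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SessionMeta:
    session_id: str
    family_id: str
    caregiver_id: str
    caregiver_role: str     # {"mother", "father", "sibling", "unfamiliar"}
    infant_id: str
    infant_sex: str
    pnd: int                # postnatal day
    rearing: str            # {"family", "artificial"}
    assay: str              # {"retrieval", "reunion", "isolation"}
    nominal_duration: float = 600.0
    birth_id: str = ""      # shared by littermates; enables twin pairing

    def __post_init__(self) -> None:
        if self.pnd < 0:
            raise RecordError(f"pnd must be >= 0, got {self.pnd}")
        if self.nominal_duration not in (300.0, 600.0, 300, 600):
            raise RecordError(
                f"nominal_duration must be 300 or 600 s, got {self.nominal_duration}")
        if not self.birth_id:
            self.birth_id = f"{self.family_id}:b0"


@dataclass
class SessionData:
    """A validated session: metadata + events + calls + analysis window."""

    meta: SessionMeta
    events: list[EventRecord]
    calls: list[CallRecord]
    retrieval_time: Optional[float] = None
    window_end: float = 0.0

    @property
    def window(self) -> tuple[float, float]:
        return (0.0, self.window_end)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["session_id", "actor", "behavior", "onset_s", "offset_s"]
_CALL_COLUMNS = ["session_id", "caller", "call_type", "onset_s", "offset_s"]


def read_event_stream(path: str | Path,
                      bin_width: float = BIN_WIDTH) -> list[EventRecord]:
    """Read a behavior-event CSV and snap times to the coding grid.

    Returns records sorted by onset.  Unknown behavior codes are preserved
    with a warning.  A row whose snapped offset does not exceed its snapped
    onset raises :class:`RecordError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"session_id": str})
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: no event rows (header only)", path)
        return []

    records: list[EventRecord] = []
    unknown: set[str] = set()
    for i, row in df.iterrows():
        onset = snap_to_grid(row["onset_s"], bin_width)
        offset = snap_to_grid(row["offset_s"], bin_width)
        if onset < 0:
            raise RecordError(f"{path} row {i}: negative onset {onset}")
        if offset <= onset:
            raise RecordError(
                f"{path} row {i}: offset {offset} <= onset {onset}")
        behavior = str(row["behavior"]).strip()
        if behavior not in KNOWN_BEHAVIORS:
            unknown.add(behavior)
        records.append(EventRecord(
            session_id=str(row["session_id"]),
            actor=str(row["actor"]).strip().lower(),
            behavior=behavior,
            onset=onset, offset=offset))
    if unknown:
        logger.warning("%s: unknown behavior code(s) preserved: %s",
                       path, sorted(unknown))
    records.sort(key=lambda r: (r.onset, r.offset, r.behavior))
    return records


def _normalize_call(label: str) -> tuple[str, bool]:
    """Map a raw annotation label into the closed call-type vocabulary.

    Returns ``(call_type, known)``.
    """
    lab = label.strip().lower()
    lab = _CALL_ALIASES.get(lab, lab)
    if lab in CALL_TYPES:
        return lab, True
    return "other", False


def _normalize_caller(raw: str) -> str:
    c = str(raw).strip().lower()
    c = _CALLER_ALIASES.get(c, c)
    if c not in _CALLERS:
        logger.warning("unknown caller %r mapped to 'unspecified'", raw)
        c = "unspecified"
    return c


def read_call_table(path: str | Path, dialect: Optional[str] = None,
                    session_id: Optional[str] = None) -> list[CallRecord]:
    """Read call annotations from a CSV or a PRAAT TextGrid.

    ``dialect`` is inferred from the file suffix when omitted.  For
    TextGrids, tier names give the caller and ``session_id`` defaults to the
    file stem; empty-label intervals are dropped.  Unknown call labels are
    kept with ``call_type='other'`` and a warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "textgrid" if path.suffix.lower() == ".textgrid" else "csv"
    if dialect == "csv":
        return _read_call_csv(path)
    if dialect == "textgrid":
        return _read_call_textgrid(path, session_id or path.stem)
    raise FormatError(f"unknown call-table dialect {dialect!r}")


def _read_call_csv(path: Path) -> list[CallRecord]:
    df = pd.read_csv(path, dtype={"session_id": str})
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records: list[CallRecord] = []
    for i, row in df.iterrows():
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if offset < onset:
            raise RecordError(f"{path} row {i}: offset {offset} < onset {onset}")
        call_type, known = _normalize_call(str(row["call_type"]))
        if not known:
            logger.warning("%s row %s: unknown call label %r kept as 'other'",
                           path, i, row["call_type"])
        records.append(CallRecord(
            session_id=str(row["session_id"]),
            caller=_normalize_caller(row["caller"]),
            call_type=call_type, onset=onset, offset=offset))
    records.sort(key=lambda r: r.onset)
    return records


# -- minimal TextGrid interval-tier reader ----------------------------------
# Handles the standard "ooTextFile" long and short formats well enough for
# interval tiers; point tiers are skipped.

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_STR_RE = re.compile(r'"((?:[^"]|"")*)"')


def _read_call_textgrid(path: Path, session_id: str) -> list[CallRecord]:
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise FormatError(f"{path}: not a PRAAT TextGrid")
    # long-format index decorations like "item [2]:" / "intervals [1]:"
    # would otherwise tokenize as numbers
    text = re.sub(r"\[\s*\d*\s*\]", "", text)
    # Tokenize: quoted strings and bare numbers, in file order.  Both the
    # long and the short format reduce to the same token stream.
    tokens: list[str | float] = []
    for m in re.finditer(r'"(?:[^"]|"")*"|-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?',
                         text):
        tok = m.group(0)
        if tok.startswith('"'):
            tokens.append(tok[1:-1].replace('""', '"'))
        else:
            tokens.append(float(tok))
    records: list[CallRecord] = []
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i] == "IntervalTier":
            tier_name = str(tokens[i + 1])
            # xmin, xmax, n_intervals
            n_int = int(tokens[i + 4])
            j = i + 5
            caller = _normalize_caller(tier_name)
            for _ in range(n_int):
                xmin, xmax, label = tokens[j], tokens[j + 1], str(tokens[j + 2])
                j += 3
                if not label.strip():
                    continue
                call_type, known = _normalize_call(label)
                if not known:
                    logger.warning(
                        "%s tier %s: unknown call label %r kept as 'other'",
                        path, tier_name, label)
                records.append(CallRecord(
                    session_id=session_id, caller=caller,
                    call_type=call_type,
                    onset=float(xmin), offset=float(xmax)))
            i = j
        else:
            i += 1
    records.sort(key=lambda r: r.onset)
    return records


def read_metadata(path: str | Path) -> list[SessionMeta]:
    """Read the session metadata CSV (one row per session)."""
    df = pd.read_csv(path, dtype=str)
    required = ["session_id", "family_id", "caregiver_id", "caregiver_role",
                "infant_id", "infant_sex", "pnd", "rearing", "assay",
                "nominal_duration"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(SessionMeta(
            session_id=row["session_id"], family_id=row["family_id"],
            caregiver_id=row["caregiver_id"],
            caregiver_role=row["caregiver_role"],
            infant_id=row["infant_id"], infant_sex=row["infant_sex"],
            pnd=int(row["pnd"]), rearing=row["rearing"], assay=row["assay"],
            nominal_duration=float(row["nominal_duration"]),
            birth_id=row.get("birth_id", "") or ""))
    return metas


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def build_session(meta: SessionMeta, events: Sequence[EventRecord],
                  calls: Sequence[CallRecord] = ()) -> SessionData:
    """Assemble and validate a session.

    The analysis window is ``[0, retrieval_time + nominal_duration]`` when a
    retrieval occurred, else ``[0, nominal_duration]``; events and calls are
    truncated to the window.  Rejection can only happen to a carried infant,
    so a rejection bout overlapping no carrying bout (or preceding the first
    retrieval) is a validation error.
    """
    events = sorted(events, key=lambda r: (r.onset, r.offset))
    retrievals = [e for e in events if e.behavior == "retrieval"]
    retrieval_time = retrievals[0].onset if retrievals else None
    if retrieval_time is not None:
        window_end = snap_to_grid(retrieval_time + meta.nominal_duration)
    else:
        window_end = float(meta.nominal_duration)

    carry = [(e.onset, e.offset) for e in events if e.behavior == "carry_contact"]
    for e in events:
        if e.behavior != "rejection":
            continue
        if retrieval_time is None or e.onset < retrieval_time:
            raise ValidationError(
                f"session {meta.session_id}: rejection at {e.onset}s before "
                "first retrieval")
        if not any(e.onset < c1 and e.offset > c0 for c0, c1 in carry):
            raise ValidationError(
                f"session {meta.session_id}: rejection [{e.onset}, "
                f"{e.offset}) overlaps no carrying bout")

    kept_events = []
    for e in events:
        if e.onset >= window_end:
            continue
        kept_events.append(EventRecord(e.session_id, e.actor, e.behavior,
                                       e.onset, min(e.offset, window_end)))
    kept_calls = []
    for c in sorted(calls, key=lambda r: r.onset):
        if c.onset >= window_end:
            continue
        kept_calls.append(CallRecord(c.session_id, c.caller, c.call_type,
                                     c.onset, min(c.offset, window_end)))

    return SessionData(meta=meta, events=kept_events, calls=kept_calls,
                       retrieval_time=retrieval_time, window_end=window_end)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_events(records: Iterable[EventRecord], path: str | Path) -> None:
    rows = [{"session_id": r.session_id, "actor": r.actor,
             "behavior": r.behavior, "onset_s": r.onset, "offset_s": r.offset}
            for r in records]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def write_calls(records: Iterable[CallRecord], path: str | Path) -> None:
    rows = [{"session_id": r.session_id, "caller": r.caller,
             "call_type": r.call_type, "onset_s": r.onset,
             "offset_s": r.offset} for r in records]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, index=False)


def write_metadata(metas: Iterable[SessionMeta], path: str | Path) -> None:
    pd.DataFrame([asdict(m) for m in metas]).to_csv(path, index=False)


def write_summary(records: Sequence, path: str | Path) -> None:
    """Write per-session rows plus per-dyad aggregate rows to CSV.

    ``records`` are :class:`~dyadkit.attachment_metrics.DyadSummary`
    instances (duck-typed through ``session_rows()`` / ``dyad_row()``).
    Values round-trip through :func:`read_summary` to 6 decimals.
    """
    records = list(records)
    if not records:
        raise ValueError("write_summary: empty record list")
    rows: list[dict] = []
    seen: set[str] = set()
    for rec in records:
        for row in rec.session_rows():
            sid = row["session_id"]
            if sid in seen:
                raise ValueError(f"duplicate session_id {sid!r} in summaries")
            seen.add(sid)
            rows.append({"level": "session", **row})
        rows.append({"level": "dyad", "session_id": "", **rec.dyad_row()})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6f")


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"session_id": str, "level": str})
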