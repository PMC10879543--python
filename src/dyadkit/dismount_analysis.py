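"""Rejection-to-dismount intervals and forced/voluntary classification.

An infant leaving the carrier's body ("dismount") may be a direct
consequence of a preceding rejection bout (forced) or the infant's own
action (voluntary).  The two are separated empirically: the distribution of
intervals between the end of the most recent rejection and the subsequent
dismount shows a two-phase log-survivorship curve, and the breakpoint of a
continuity-constrained two-segment regression on that curve gives the
interval criterion.  Dismounts at or below the criterion are classified
forced; longer intervals, and dismounts with no preceding rejection, are
voluntary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .ethogram_io import SessionData

#: Interval criterion (s) used downstream for classification: the fitted
#: log-survivorship breakpoint rounded to the coding grid.
DEFAULT_THRESHOLD_S = 9.4


@dataclass
class DismountEvent:
    session_id: str
    time: float                      # s, dismount onset
    interval_s: Optional[float]      # s since end of last preceding rejection
    pnd: int


@dataclass
class BreakpointFit:
    """Two-segment continuous piecewise-linear fit to (t, ln S) points."""

    breakpoint_s: float
    slope_left: float
    slope_right: float
    intercept_left: float            # value of the fit at t = 0 (left line)
    intercept_right: float           # right line extrapolated to t = 0
    sse: float
    n_points: int
    degenerate: bool                 # True when one line fits (almost) as well


def extract_intervals(sessions: Iterable[SessionData]) -> list[DismountEvent]:
    """One record per dismount, with the time since the most recent
    rejection end in the same session (absent when no rejection preceded).
    """
    out: list[DismountEvent] = []
    for s in sessions:
        rejection_ends = sorted(e.offset for e in s.events
                                if e.behavior == "rejection")
        for e in s.events:
            if e.behavior != "dismount":
                continue
            prior = [r for r in rejection_ends if r <= e.onset]
            interval = round(e.onset - prior[-1], 1) if prior else None
            out.append(DismountEvent(session_id=s.meta.session_id,
                                     time=e.onset, interval_s=interval,
                                     pnd=s.meta.pnd))
    return out


def log_survivorship(intervals: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical log-survivor points for a sample of intervals.

    With the order statistics ``t_(1) <= ... <= t_(n)``, the survivor value
    at ``t_(i)`` is ``S = (n - i + 1)/n`` (the proportion of intervals
    >= ``t_(i)``); duplicated times collapse to the smallest S at that time.
    Returns ``(t, ln S)`` pairs, strictly increasing in t.
    """
    ts = sorted(float(t) for t in intervals)
    n = len(ts)
    if n == 0:
        raise ValueError("log_survivorship: empty interval list")
    if ts[0] <= 0:
        raise ValueError("log_survivorship: intervals must be positive")
    points: dict[float, float] = {}
    for i, t in enumerate(ts, start=1):
        s = (n - i + 1) / n
        points[t] = min(points.get(t, 1.0), s)
    return [(t, math.log(points[t])) for t in sorted(points)]


def survivor_weights(points: Sequence[tuple[float, float]],
                     n_sample: int) -> np.ndarray:
    """Inverse-variance weights for empirical log-survivor points.

    By the delta method / Greenwood's formula, Var(ln S_hat(t)) is
    approximately ``(1 - S) / (n S)``: points deep in the tail are far
    noisier than early ones.  Weighting by the reciprocal stabilizes the
    breakpoint fit.
    """
    s = np.exp([y for _, y in points])
    var = np.maximum((1.0 - s) / (n_sample * s), 1e-12)
    return 1.0 / var


def _two_segment_sse(t: np.ndarray, y: np.ndarray, c: float,
                     sw: np.ndarray) -> tuple[float, np.ndarray]:
    """(Weighted) least-squares SSE of a continuous two-segment line broken
    at c.

    Model: y = a + b1*min(t-c, 0) + b2*max(t-c, 0); coefficients (a, b1, b2);
    ``sw`` are square roots of the point weights.
    """
    X = np.column_stack([np.ones_like(t),
                         np.minimum(t - c, 0.0),
                         np.maximum(t - c, 0.0)])
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = (y - X @ coef) * sw
    return float(resid @ resid), coef


def fit_breakpoint(points: Sequence[tuple[float, float]],
                   min_side: int = 3,
                   weights: Optional[Sequence[float]] = None) -> BreakpointFit:
    """Grid search for the breakpoint of a two-segment log-survivorship fit.

    Candidate breakpoints are the observed times with at least ``min_side``
    points on each side (at or below vs strictly above); for each candidate
    a continuity-constrained two-segment least-squares line is fitted and
    the candidate with minimal total SSE wins, ties broken toward the
    smaller breakpoint.  ``weights`` (e.g. :func:`survivor_weights`) turn
    the objective into a weighted SSE.  The fit is flagged degenerate when
    the best two-segment SSE improves on the single-line SSE by less
    than 1%.
    """
    pts = sorted(points)
    if len(pts) < 2 * min_side:
        raise ValueError(f"fit_breakpoint: need >= {2 * min_side} points, "
                         f"got {len(pts)}")
    t = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if weights is None:
        sw = np.ones_like(t)
    else:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        if len(sw) != len(t):
            raise ValueError("weights must align with points")

    # single-line reference fit
    X1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(X1 * sw[:, None], y * sw, rcond=None)
    resid1 = (y - X1 @ coef1) * sw
    sse1 = float(resid1 @ resid1)

    best: Optional[tuple[float, float, np.ndarray]] = None
    for c in np.unique(t):
        n_left = int(np.sum(t <= c))
        n_right = int(np.sum(t > c))
        if n_left < min_side or n_right < min_side:
            continue
        sse, coef = _two_segment_sse(t, y, float(c), sw)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(c), coef)
    if best is None:
        raise ValueError("fit_breakpoint: no admissible breakpoint candidate")

    sse2, c, (a, b1, b2) = best
    improvement = (sse1 - sse2) / sse1 if sse1 > 0 else 0.0
    return BreakpointFit(
        breakpoint_s=c, slope_left=float(b1), slope_right=float(b2),
        intercept_left=float(a - b1 * c), intercept_right=float(a - b2 * c),
        sse=sse2, n_points=len(pts), degenerate=bool(improvement < 0.01))


def classify_dismounts(dismounts: Sequence[DismountEvent],
                       threshold_s: float = DEFAULT_THRESHOLD_S,
                       inclusive: bool = True) -> list[str]:
    """Label each dismount ``'forced'`` or ``'voluntary'``.

    No preceding rejection -> voluntary.  Interval <= threshold -> forced
    (``inclusive=False`` uses a strict ``<``; the boundary case is
    essentially a convention since observed intervals sit on the 0.2-s
    grid while the criterion does not).
    """
    if threshold_s <= 0:
        raise ValueError("threshold_s must be positive")
    labels = []
    for d in dismounts:
        if d.interval_s is None:
            labels.append("voluntary")
        elif (d.interval_s <= threshold_s if inclusive
              else d.interval_s < threshold_s):
            labels.append("forced")
        else:
            labels.append("voluntary")
    return labels


@dataclass
class VoluntaryShare:
    n_voluntary: int
    n_total: int
    pct: float                      # percentage, 1 decimal


def voluntary_proportions(dismounts: Sequence[DismountEvent],
                          labels: Sequence[str],
                          pnd_cut: int = 28) -> dict[str, VoluntaryShare]:
    """Voluntary-dismount share overall and split at ``pnd_cut`` days.

    Keys: ``'overall'``, ``'young'`` (pnd < cut), ``'old'`` (pnd >= cut).
    """
    if len(dismounts) != len(labels):
        raise ValueError("labels must align with dismounts")

    def share(sel: list[int]) -> VoluntaryShare:
        total = len(sel)
        vol = sum(1 for i in sel if labels[i] == "voluntary")
        pct = round(100.0 * vol / total, 1) if total else 0.0
        return VoluntaryShare(n_voluntary=vol, n_total=total, pct=pct)

    idx = range(len(dismounts))
    return {
        "overall": share(list(idx)),
        "young": share([i for i in idx if dismounts[i].pnd < pnd_cut]),
        "old": share([i for i in idx if dismounts[i].pnd >= pnd_cut]),
    }
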