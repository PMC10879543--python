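import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadkit.dismount_analysis import (DismountEvent, classify_dismounts,
                                       extract_intervals, fit_breakpoint,
                                       log_survivorship, survivor_weights,
                                       voluntary_proportions)
from dyadkit.ethogram_io import build_session

from conftest import ev, make_meta


def dm(interval, pnd=10):
    return DismountEvent("s", 0.0, interval, pnd)


class TestExtractIntervals:
    def _session(self, extra):
        events = [ev("retrieval", 10.0, 10.2),
                  ev("carry_contact", 10.0, 600.0, actor="infant")] + extra
        return build_session(make_meta(), events)

    def test_interval_from_most_recent_rejection(self):
        s = self._session([ev("rejection", 48.0, 50.0),
                           ev("rejection", 88.0, 90.0),
                           ev("dismount", 95.0, 95.2, actor="infant")])
        (d,) = extract_intervals([s])
        assert d.interval_s == pytest.approx(5.0)

    def test_short_interval(self):
        s = self._session([ev("rejection", 99.0, 100.0),
                           ev("dismount", 100.4, 100.6, actor="infant")])
        (d,) = extract_intervals([s])
        assert d.interval_s == pytest.approx(0.4)

    def test_no_prior_rejection_interval_absent(self):
        s = self._session([ev("dismount", 95.0, 95.2, actor="infant")])
        (d,) = extract_intervals([s])
        assert d.interval_s is None


class TestLogSurvivorship:
    def test_by_definition_on_1234(self):
        pts = log_survivorship([1, 2, 3, 4])
        assert [t for t, _ in pts] == [1, 2, 3, 4]
        assert [math.exp(y) for _, y in pts] == pytest.approx(
            [1.0, 0.75, 0.5, 0.25])

    def test_single_interval(self):
        assert log_survivorship([5.0]) == [(5.0, 0.0)]

    def test_duplicates_collapse_to_smallest_s(self):
        pts = log_survivorship([2, 2, 4])
        assert len(pts) == 2
        assert math.exp(pts[0][1]) == pytest.approx(2 / 3)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_survivorship([])
        with pytest.raises(ValueError):
            log_survivorship([0.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=1,
                    max_size=40))
    def test_lns_nonincreasing(self, intervals):
        ys = [y for _, y in log_survivorship(intervals)]
        assert all(a >= b - 1e-12 for a, b in zip(ys, ys[1:]))


def _brute_force_fit(points, weights=None):
    """Independent oracle: same objective, different parametrization
    (left line (a, b), right slope via the continuity constraint)."""
    t = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    best = None
    for c in np.unique(t):
        if (t <= c).sum() < 3 or (t > c).sum() < 3:
            continue
        # design: y = aL + bL*t for t<=c;  y = aL + bL*c + bR*(t-c) beyond
        left = t <= c
        X = np.zeros((len(t), 3))
        X[:, 0] = 1.0
        X[left, 1] = t[left]
        X[~left, 1] = c
        X[~left, 2] = t[~left] - c
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        sse = float((((y - X @ coef) * sw) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, c)
    return best[1]


class TestFitBreakpoint:
    def test_exact_two_line_recovery(self):
        t = np.arange(1.0, 11.0)
        y = np.where(t <= 5, -0.5 * t, -2.5 - 0.1 * (t - 5))
        fit = fit_breakpoint(list(zip(t, y)))
        assert fit.breakpoint_s == 5.0
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.slope_left == pytest.approx(-0.5)
        assert fit.slope_right == pytest.approx(-0.1)
        assert not fit.degenerate

    def test_single_line_flags_degenerate(self):
        t = np.arange(1.0, 11.0)
        fit = fit_breakpoint(list(zip(t, -0.3 * t)))
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_breakpoint([(1, 0), (2, -1), (3, -2), (4, -3), (5, -4)])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 31))
            t = np.sort(rng.uniform(0, 30, n))
            t = np.unique(np.round(t, 1))
            if len(t) < 8:
                continue
            y = -0.4 * np.minimum(t, 10) - 0.05 * np.maximum(t - 10, 0) \
                + rng.normal(0, 0.15, len(t))
            pts = list(zip(t, y))
            assert fit_breakpoint(pts).breakpoint_s == _brute_force_fit(pts)

    def test_weighted_fit_matches_weighted_oracle(self, rng):
        t = np.sort(np.unique(np.round(rng.uniform(0.5, 25, 25), 1)))
        y = -0.3 * np.minimum(t, 9) - 0.02 * np.maximum(t - 9, 0) \
            + rng.normal(0, 0.1, len(t))
        pts = list(zip(t, y))
        w = survivor_weights(pts, 60)
        assert fit_breakpoint(pts, weights=w).breakpoint_s == \
            _brute_force_fit(pts, weights=w)


class TestClassification:
    @pytest.mark.parametrize("interval,expected", [
        (0.4, "forced"),        # minimum observed interval
        (9.4, "forced"),        # boundary is inclusive by default
        (9.6, "voluntary"),
        (417.2, "voluntary"),   # maximum observed interval
        (None, "voluntary"),    # no preceding rejection
    ])
    def test_rule(self, interval, expected):
        assert classify_dismounts([dm(interval)]) == [expected]

    def test_strict_boundary_flag(self):
        assert classify_dismounts([dm(9.4)], inclusive=False) == ["voluntary"]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.one_of(st.none(),
                              st.floats(min_value=0.2, max_value=500)),
                    min_size=1, max_size=30),
           st.floats(min_value=1, max_value=50),
           st.floats(min_value=0, max_value=100))
    def test_threshold_monotonicity(self, intervals, thr, extra):
        events = [dm(i) for i in intervals]
        low = classify_dismounts(events, threshold_s=thr)
        high = classify_dismounts(events, threshold_s=thr + extra)
        # raising the threshold never converts forced -> voluntary
        for a, b in zip(low, high):
            assert not (a == "forced" and b == "voluntary")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.one_of(st.none(),
                              st.floats(min_value=0.2, max_value=500)),
                    min_size=1, max_size=40))
    def test_forced_fraction_conservation(self, intervals):
        events = [dm(i) for i in intervals]
        labels = classify_dismounts(events)
        n_forced = labels.count("forced")
        assert n_forced == sum(1 for i in intervals
                               if i is not None and i <= 9.4)


class TestVoluntaryProportions:
    def test_published_age_split(self):
        events = ([dm(1.0, pnd=10)] * 82 + [dm(None, pnd=10)] * 25
                  + [dm(1.0, pnd=30)] * 27 + [dm(None, pnd=30)] * 30)
        labels = classify_dismounts(events)
        shares = voluntary_proportions(events, labels)
        assert shares["young"].pct == 23.4
        assert shares["young"].n_total == 107
        assert shares["old"].pct == 52.6
        assert shares["overall"].pct == 33.5

    def test_zero_voluntary(self):
        events = [dm(1.0)] * 10
        shares = voluntary_proportions(events, classify_dismounts(events))
        assert shares["overall"].pct == 0.0
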