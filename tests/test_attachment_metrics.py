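import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadkit.attachment_metrics import (DyadSummary, SessionSummary,
                                        classify_transfers,
                                        dyad_distance_pairs, infant_metrics,
                                        minmax_normalize, one_zero_aggregate,
                                        parenting_params, summarize_dyads,
                                        transition_call_ratio)
from dyadkit.context_segmentation import segment_contexts
from dyadkit.ethogram_io import CallRecord, build_session

from conftest import ev, make_meta


class TestParentingParams:
    def test_reference_values(self, carried_session):
        tl = segment_contexts(carried_session)
        pp = parenting_params(carried_session, tl)
        assert pp.ret_latency_s == 30.0
        assert not pp.censored
        assert pp.pct_carry == pytest.approx(100 * 580 / 630, abs=0.01)
        assert pp.pct_rejection == pytest.approx(100 * 2 / 580, abs=0.001)

    def test_no_rejection_gives_zero(self):
        s = build_session(make_meta(), [
            ev("retrieval", 30.0, 30.2),
            ev("carry_contact", 30.0, 630.0, actor="infant")])
        pp = parenting_params(s, segment_contexts(s))
        assert pp.pct_rejection == 0.0

    def test_no_retrieval_censored(self):
        s = build_session(make_meta(), [])
        pp = parenting_params(s, segment_contexts(s))
        assert pp.censored
        assert pp.ret_latency_s == 600.0
        assert pp.pct_carry == 0.0
        assert pp.pct_rejection is None

    def test_invariant_under_time_translation(self):
        def session(shift):
            return build_session(make_meta(), [
                ev("retrieval", 30.0 + shift, 30.2 + shift),
                ev("carry_contact", 30.0 + shift, 610.0 + shift,
                   actor="infant"),
                ev("rejection", 100.0 + shift, 102.0 + shift)])
        vals = []
        for shift in (0.0, 20.0, 55.0):
            s = session(shift)
            pp = parenting_params(s, segment_contexts(s))
            vals.append(pp.pct_rejection)
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])


def call(ct, onset, sid="s1", caller="infant"):
    return CallRecord(sid, caller, ct, onset, onset + 0.3)


class TestInfantMetrics:
    def _session(self, calls, extra_events=()):
        events = [ev("retrieval", 30.0, 30.2),
                  ev("carry_contact", 30.0, 210.0, actor="infant"),
                  ev("dismount", 210.0, 210.2, actor="infant"),
                  *extra_events]
        return build_session(make_meta(), events, calls)

    def test_no_calls_zero_frequencies(self):
        s = self._session([])
        im = infant_metrics(s, segment_contexts(s), ["voluntary"])
        assert im.calls_carried_per_min == 0.0
        assert im.context_type_props["Holding"] is None

    def test_trill_frequency_and_proportion(self):
        calls = [call("trill", 40.0 + 10 * k) for k in range(6)]
        s = self._session(calls)
        im = infant_metrics(s, segment_contexts(s), ["voluntary"])
        # 6 calls in 180 s of holding -> 2.0 / min, all trill
        assert im.calls_carried_per_min == pytest.approx(2.0)
        assert im.context_type_props["Holding"]["trill"] == pytest.approx(1.0)

    def test_avoidance_is_voluntary_plus_refusal(self):
        # caregiver contact bout with no infant cling onset -> refusal
        s = self._session([], extra_events=[
            ev("contact", 300.0, 302.0)])
        im = infant_metrics(s, segment_contexts(s), ["voluntary"])
        assert im.cling_refusals == 1
        assert im.voluntary_dismounts == 1
        assert im.avoidance_count == 2

    def test_fleeting_contact_not_a_refusal(self):
        s = self._session([], extra_events=[ev("contact", 300.0, 300.6)])
        im = infant_metrics(s, segment_contexts(s), ["voluntary"])
        assert im.cling_refusals == 0

    def test_explicit_refusal_code_trusted(self):
        s = self._session([], extra_events=[
            ev("refusal", 300.0, 300.4, actor="infant")])
        im = infant_metrics(s, segment_contexts(s), ["voluntary"])
        assert im.cling_refusals == 1

    def test_misaligned_labels_rejected(self):
        s = self._session([])
        with pytest.raises(ValueError):
            infant_metrics(s, segment_contexts(s), [])

    def test_avoidance_monotone_in_injected_voluntary_dismounts(self):
        base = self._session([])
        im1 = infant_metrics(base, segment_contexts(base), ["voluntary"])
        more = build_session(make_meta(), [
            ev("retrieval", 30.0, 30.2),
            ev("carry_contact", 30.0, 210.0, actor="infant"),
            ev("dismount", 210.0, 210.2, actor="infant"),
            ev("carry_contact", 250.0, 400.0, actor="infant"),
            ev("dismount", 400.0, 400.2, actor="infant")])
        im2 = infant_metrics(more, segment_contexts(more),
                             ["voluntary", "voluntary"])
        assert im2.avoidance_count >= im1.avoidance_count


class TestTransitionCallRatio:
    def _pair(self, calls):
        s = build_session(make_meta(), [
            ev("retrieval", 30.0, 30.2),
            ev("carry_contact", 30.0, 630.0, actor="infant")], calls)
        return (s, segment_contexts(s))

    def test_equal_counts_ratio_one(self):
        calls = [call("phee", 22.0 + k) for k in range(4)] + \
                [call("trill", 31.0 + k) for k in range(4)]
        tr = transition_call_ratio([self._pair(calls)], "Alone_BeforeRET",
                                   "Holding")
        assert tr.pairs == [(4, 4)]
        assert tr.ratios == [pytest.approx(1.0)]

    def test_calls_stop_after_retrieval(self):
        calls = [call("phee", 20.0 + 0.8 * k) for k in range(10)]
        tr = transition_call_ratio([self._pair(calls)], "Alone_BeforeRET",
                                   "Holding")
        assert tr.pairs == [(10, 0)]
        assert tr.ratios == [0.0]

    def test_zero_before_excluded_and_flagged(self):
        calls = [call("trill", 35.0)]
        tr = transition_call_ratio([self._pair(calls)], "Alone_BeforeRET",
                                   "Holding")
        assert tr.ratios == []
        assert tr.n_excluded_zero_before == 1

    def test_no_eligible_transitions(self):
        tr = transition_call_ratio([self._pair([])], "Holding", "Transport")
        assert tr.pairs == []


class TestMinMax:
    def test_formula(self):
        assert list(minmax_normalize([2, 4, 6])) == pytest.approx([0, 0.5, 1])

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            minmax_normalize([3, 3, 3])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
    def test_bounds(self, values):
        if max(values) == min(values):
            return
        out = minmax_normalize(values)
        assert out.min() == 0.0 and out.max() == 1.0


def dyad(cg, inf, birth, av, cc):
    return DyadSummary(caregiver_id=cg, infant_id=inf, birth_id=birth,
                       n_sessions=1, ret_latency_s=10.0, pct_carry=50.0,
                       pct_rejection=1.0, avoidance_count=av,
                       calls_carried_per_min=cc, sessions=[])


class TestDistancePairs:
    def test_pythagorean_distance(self):
        # four dyads spanning the unit square; the littermate pair of
        # caregiver M sits at normalized (0,0) and (0.3, 0.4)
        summaries = [
            dyad("M", "i1", "b1", 0.0, 0.0),
            dyad("M", "i2", "b1", 3.0, 4.0),
            dyad("F", "i1", "b1", 10.0, 10.0),
            dyad("F", "i2", "b1", 10.0, 10.0),
        ]
        dp = dyad_distance_pairs(summaries)
        assert dp.di_sc[0] == pytest.approx(0.5)
        # F's littermates coincide -> zero distance
        assert dp.di_sc[1] == pytest.approx(0.0)
        assert len(dp.si_dc) == 2

    def test_order_invariance(self):
        s = [dyad("M", "i1", "b1", 0.0, 0.0), dyad("M", "i2", "b1", 1, 2),
             dyad("F", "i1", "b1", 2, 1), dyad("F", "i2", "b1", 3, 3)]
        d1 = dyad_distance_pairs(s)
        d2 = dyad_distance_pairs(list(reversed(s)))
        assert sorted(d1.di_sc) == pytest.approx(sorted(d2.di_sc))
        assert sorted(d1.si_dc) == pytest.approx(sorted(d2.si_dc))

    def test_affine_rescaling_invariance(self):
        s1 = [dyad("M", "i1", "b1", 0, 0), dyad("M", "i2", "b1", 1, 2),
              dyad("F", "i1", "b1", 2, 1), dyad("F", "i2", "b1", 3, 3)]
        s2 = [dyad(d.caregiver_id, d.infant_id, d.birth_id,
                   5 * d.avoidance_count + 2,
                   0.1 * d.calls_carried_per_min - 7) for d in s1]
        assert dyad_distance_pairs(s1).di_sc == \
            pytest.approx(dyad_distance_pairs(s2).di_sc)

    def test_missing_pairs_error(self):
        with pytest.raises(ValueError):
            dyad_distance_pairs([dyad("M", "i1", "b1", 0, 0),
                                 dyad("F", "i2", "b2", 1, 1)])


class TestOneZero:
    def test_overlap_rule(self):
        events = [ev("carried", 8.0, 31.0)]
        df = one_zero_aggregate(events, bin_s=10.0, span=(0.0, 40.0))
        assert list(df["carried"]) == [1, 1, 1, 1]

    def test_contained_event(self):
        events = [ev("carried", 12.0, 13.0)]
        df = one_zero_aggregate(events, bin_s=10.0, span=(0.0, 30.0))
        assert list(df["carried"]) == [0, 1, 0]

    def test_no_events_all_zero(self):
        df = one_zero_aggregate([ev("calling", 0.5, 0.6)], bin_s=10.0,
                                span=(0.0, 20.0))
        assert df["calling"].sum() == 1


class TestTransfers:
    @pytest.mark.parametrize("seq,expected", [
        (["M", "M", "F"], [("M", "F", "direct")]),
        (["M", None, "F"], [("M", "F", "nondirect")]),
        (["M", "M", "M"], []),
        (["M", None, "M", "F"], [("M", "F", "direct")]),
        (["M", "F", None, "S"], [("M", "F", "direct"),
                                 ("F", "S", "nondirect")]),
    ])
    def test_rules(self, seq, expected):
        out = [(t["from"], t["to"], t["kind"])
               for t in classify_transfers(seq)]
        assert out == expected


class TestDyadAggregation:
    def test_censored_latency_excluded_from_mean(self, carried_session):
        tl = segment_contexts(carried_session)
        pp = parenting_params(carried_session, tl)
        im = infant_metrics(carried_session, tl, [])
        s1 = SessionSummary("a", "cg", "i", "b", 10, pp, im)
        import dataclasses
        pp2 = dataclasses.replace(pp, session_id="b", ret_latency_s=630.0,
                                  censored=True)
        s2 = SessionSummary("b", "cg", "i", "b", 12, pp2, im)
        (d,) = summarize_dyads([s1, s2])
        assert d.n_sessions == 2
        assert d.ret_latency_s == pytest.approx(30.0)
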