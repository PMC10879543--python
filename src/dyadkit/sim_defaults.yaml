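# Default parameters of the dyadic-session simulator.
#
# Every rate is a hazard (per second) or a per-minute call rate; every
# duration is in seconds.  These defaults define the study conditions the
# simulator emulates; see docs/methods.md for the rationale behind each.

window_s: 600.0            # nominal observation length after first retrieval

# caregiver behavior -------------------------------------------------------
retrieval_rate_per_s: 0.015        # latency ~ Exp(rate * sensitivity)
re_retrieval_rate_per_s: 0.05      # after dismount; scaled by sensitivity
                                   # and carry_motivation
rejection_rate_per_s: 0.02         # during carrying; scaled by 1 - tolerance
rejection_bout_min_s: 0.4
rejection_bout_max_s: 3.0
contact_bout_s: 2.0                # caregiver contact preceding a retrieval

# dismount process ---------------------------------------------------------
change_point_s: 9.4                # two-phase interval law change point
forced_delay_scale_s: 5.156        # = 9.4 / ln(130/21): truncated-exp scale
                                   # of forced rejection-to-dismount delays
forced_dismount_prob: 0.84         # = 1 - exp(-9.4/5.156); rejection ends in
                                   # a forced dismount with this probability
voluntary_tail_scale_s: 112.0      # interval tail beyond the change point
voluntary_rate_per_s: 0.0025       # baseline voluntary-dismount hazard
voluntary_avoidance_gain: 4.0      # hazard multiplier 1 + gain * avoidance

# holding / transport dwell process ---------------------------------------
holding_dwell_s: 25.0
transport_dwell_s: 10.0

# infant responsiveness ----------------------------------------------------
refusal_gain: 2.0                  # P(refuse cling) = min(.9, gain * avoidance)

# infant calling: per-minute rates by social context ----------------------
call_rate_alone_before: 10.0
call_rate_alone_after: 8.0
call_rate_carried: 1.0
call_rate_rejection: 14.0
anxiety_rate_per_min: 6.0          # extra carried calls * anxiety_gain * (1-tol)

# call-type mixtures by context (must sum to 1) ---------------------------
call_mix:
  Alone_BeforeRET: {phee: 0.30, twitter: 0.40, tsik: 0.03, trill: 0.04, cry: 0.18, other: 0.05}
  Alone_AfterRET:  {phee: 0.25, twitter: 0.15, tsik: 0.06, trill: 0.04, cry: 0.45, other: 0.05}
  Holding:         {phee: 0.14, twitter: 0.08, tsik: 0.05, trill: 0.62, cry: 0.06, other: 0.05}
  Transport:       {phee: 0.14, twitter: 0.08, tsik: 0.05, trill: 0.62, cry: 0.06, other: 0.05}
  During_Rejection: {phee: 0.05, twitter: 0.03, tsik: 0.52, trill: 0.06, cry: 0.30, other: 0.04}
anxious_mix:       {phee: 0.00, twitter: 0.00, tsik: 0.50, trill: 0.00, cry: 0.50, other: 0.00}

# artificial-rearing condition --------------------------------------------
art_avoidance_boost: 0.35          # added to avoidance_base
art_alone_call_mult: 2.0           # alone-context rate multiplier past PND 30
art_alone_call_pnd: 30
art_direct_transfer_drop_pnd: 12   # direct-transfer propensity drops after
art_direct_transfer_prop: 0.35     # ... this PND (family-reared default 0.85)
direct_transfer_prop: 0.85

# family-reunion transfer process -----------------------------------------
reunion_bins: 60                   # 10-s one-zero bins per reunion session
transfer_prob_per_bin: 0.06        # chance the carrier changes at a bin
transfer_gap_max_bins: 3           # alone bins inserted on a nondirect transfer
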