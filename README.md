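# dyadkit

Microanalysis of caregiver–infant interaction event streams, built for
separation–reunion ("infant retrieval") assays of the kind used with
common-marmoset families, where mothers, fathers and older siblings all
carry infants and differ in caregiving style.  The package takes
subsecond behavioral coding (0.2-s bins) and call annotations, and turns
them into reproducible attachment measures:

* **Social-context segmentation.**  Each session is partitioned into five
  mutually exclusive, collectively exhaustive contexts from the infant's
  viewpoint: `Alone_BeforeRET`, `Holding` (carried, caregiver still),
  `Transport` (carried, caregiver locomoting), `During_Rejection` (from
  rejection onset to 9.4 s after its end), and `Alone_AfterRET`.
* **Forced vs voluntary dismounts.**  The empirical log-survivorship of
  rejection-to-dismount intervals,
  ln *S*(t) with *S*(t<sub>(i)</sub>) = (n − i + 1)/n, is fitted by a
  continuity-constrained two-segment regression; the breakpoint separates
  dismounts driven by the preceding rejection (interval ≤ criterion,
  default 9.4 s) from the infant's own contact breaking.
* **Parenting parameters.**  `RET_Latency` (time to first retrieval,
  inverse *sensitivity*), `%Rejection` (rejection time / carrying time,
  inverse *tolerance*) and `%Carry` (carrying time / session length, care
  *quantity*), per session and averaged per dyad.
* **Infant attachment metrics.**  Avoidant behaviors (voluntary dismounts
  + refusals to cling on contact), calls-while-being-carried, per-context
  call frequencies and call-type usage (phee, twitter, trill, tsik, cry),
  call-rate change ratios across context transitions, one-zero sampling
  and direct/nondirect carrier-transfer classification for family
  reunions, and the DI_SC / SI_DC dyad-distance comparison (same
  caregiver with two littermate infants vs same infant with two
  caregivers, in min–max-normalized metric space).
* **Statistics.**  Spearman/Pearson correlation matrices with Holm or
  Benjamini–Hochberg adjustment, exact and approximate Wilcoxon
  signed-rank and rank-sum tests, Cohen's κ, and a dyad-cluster
  permutation test that controls pseudoreplication where a mixed model
  would otherwise be used.
* **Synthetic cohorts.**  A generative simulator with latent caregiver
  styles (sensitivity, tolerance, carry motivation) and infant response
  rules (context-dependent calling, anxiety-scaled negative calls,
  avoidance, artificial-rearing effects) emits pipeline-ready files plus
  ground truth for end-to-end parameter-recovery testing.

## Worked example

```python
from dyadkit import (CaregiverStyle, InfantState, simulate_session,
                     segment_contexts, context_durations, parenting_params,
                     extract_intervals, classify_dismounts, infant_metrics)

style = CaregiverStyle(sensitivity=0.9, tolerance=0.2, carry_motivation=0.8)
session, truth = simulate_session(style, InfantState(pnd=10), seed=7)
timeline = segment_contexts(session)

cd = context_durations(timeline)
for ctx, d in cd.durations.items():
    print(f"  {ctx:<18} {d:7.1f} s  ({100 * cd.proportions[ctx]:.1f}%)")

pp = parenting_params(session, timeline)
print(f"RET_Latency = {pp.ret_latency_s:.1f} s, %Carry = {pp.pct_carry:.1f}, "
      f"%Rejection = {pp.pct_rejection:.2f}")

dismounts = extract_intervals([session])
labels = classify_dismounts(dismounts)
im = infant_metrics(session, timeline, labels)
print(f"{len(dismounts)} dismounts, {labels.count('forced')} forced; "
      f"calls carried = {im.calls_carried_per_min:.2f}/min")
```

prints

```
  Alone_BeforeRET       52.4 s  (8.0%)
  Holding              222.4 s  (34.1%)
  Transport            102.8 s  (15.8%)
  During_Rejection      79.4 s  (12.2%)
  Alone_AfterRET       195.4 s  (30.0%)
RET_Latency = 52.4 s, %Carry = 55.7, %Rejection = 3.74
8 dismounts, 7 forced; calls carried = 6.83/min
```

This low-tolerance caregiver retrieves quickly but rejects repeatedly:
over half the window is carrying, 12% of it under rejection influence,
and seven of eight dismounts fall within the 9.4-s criterion (the
generator's own labels agree).  The infant keeps calling while carried —
the anxious signaling a tolerant caregiver would switch off.

The same chain runs from the shell on coded CSV files:

```sh
dyadkit simulate --out cohort/ --seed 3 --families 7
dyadkit run-all --events cohort/events.csv --meta cohort/meta.csv \
        --calls cohort/calls.csv --out report/
dyadkit dismounts --events cohort/events.csv --meta cohort/meta.csv --fit
```

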