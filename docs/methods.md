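# Methods

This note documents the models, conventions and numerical choices behind
dyadkit, in the order the pipeline runs.

## Event ingestion and the coding grid

Behavior bouts are half-open intervals `[onset, offset)` in continuous
seconds.  Manual coding happens on a 0.2-s grid, so raw times are snapped
at ingestion: round-half-even to one decimal, then to the nearest
multiple of 0.2 s.  The grid is an ingestion convention only — all
downstream interval arithmetic is on continuous seconds, and the context
partition works on integer tick indices (time/0.2) so the tiling property
holds exactly, without float tolerance.  Unknown behavior or call labels
are warnings, not errors: manual ethogram vocabularies drift between
coders, and silently dropping records would bias bout counts.  The
infant distress call appears in annotations as `cry`, `ngä` or `nga` and
is normalized to `cry`; labels outside the closed call-type vocabulary
become `other`.

A session's analysis window is `[0, t_ret + 600 s]` when a first
retrieval occurred at `t_ret`, otherwise `[0, nominal duration]`
(600 s, or 300 s for short protocols).  Validation enforces that
rejection is only coded while the infant is carried — a rejection bout
overlapping no carrying bout, or preceding the first retrieval, is a
hard error rather than a warning because it indicates corrupted coding
that would silently distort the dismount-interval analysis.

## Social-context segmentation

Five labels tile the window: `Alone_BeforeRET` before the first
retrieval; carried time split into `Transport` (a caregiver locomotion
bout overlaps) and `Holding`; `During_Rejection` from each rejection
onset to 9.4 s after its end; `Alone_AfterRET` otherwise.  Precedence
when definitions overlap is `During_Rejection` > `Transport`/`Holding` >
`Alone_AfterRET`: the offset exists to capture infant behavior still
under the influence of the preceding rejection, so it keeps its label
even if the infant has already been dismounted inside the offset.
Overlapping rejection windows merge.  The offset interval is half-open,
`[r_start, r_end + 9.4)`, consistent with all other intervals.

## Dismount classification

The interval for each dismount is measured from the end of the most
recent preceding rejection in the same session (absent when none
preceded; attachment never crosses sessions).  The empirical log-survivor
function uses S(t₍ᵢ₎) = (n − i + 1)/n — the proportion of intervals at
least t₍ᵢ₎ — with duplicate times collapsed to the smallest S.

The two-phase structure is modeled by a continuity-constrained
two-segment regression on (t, ln S): y = a + b₁·min(t−c, 0) +
b₂·max(t−c, 0).  Candidate breakpoints c are the observed times with at
least three points on each side; each candidate's coefficients come from
linear least squares, the candidate with minimal SSE wins, and ties break
toward the smaller breakpoint.  The fit is flagged *degenerate* when the
two-segment SSE improves on the single-line SSE by less than 1% — a
single exponential phase has no meaningful breakpoint.  Because the
variance of ln Ŝ grows sharply in the tail (≈ (1−S)/(nS) by the delta
method), the analysis chain passes inverse-variance weights
(`survivor_weights`) into the fit; the unweighted contract remains the
default for the function itself.  In simulation at n = 130 the weighted
fit recovers a 9.4-s change point within ±2 s in ≈ 94–95% of replicates
vs ≈ 92% unweighted.

Classification uses the rounded criterion 9.4 s rather than a per-dataset
refit: interval ≤ 9.4 s → forced, longer or no preceding rejection →
voluntary.  The boundary is inclusive by construction of the
`During_Rejection` offset ("to 9.4 s after the end of rejection");
`inclusive=False` exposes the strict alternative, which matters only for
intervals exactly on the criterion.

## Parenting parameters and infant metrics

`%Carry` = carried duration / window length; `RET_Latency` is censored at
the window end when no retrieval occurred (censored latencies carry a
flag, enter rank-based statistics, and are excluded from dyad means).
`%Rejection` defaults to rejection-bout duration / carried duration,
matching the reunion-observation convention (rejecting bins / carrying
bins); per-session-duration and bout-count denominators are available as
configuration since the retrieval-assay convention is not fixed by a
single published definition.  Carrying and rejection durations come from
the coded bouts, not from the context timeline, because
`During_Rejection` overrides the carried contexts while the infant is
typically still on the carrier.

Avoidant behavior = voluntary dismounts + cling refusals.  A refusal is
an explicitly coded `refusal` event when present; otherwise a caregiver
`contact` bout of ≥ 1.0 s containing no infant `cling` onset.  The 1-s
floor makes the inferred definition robust to fleeting touches.  Calls
belong to the context at their onset; calls-while-carried cover
`Holding` ∪ `Transport` only (contexts are exclusive, rejection-period
calls are reported separately); a zero-duration context has an undefined
(absent) frequency rather than zero.  Call types are reported over
{phee, twitter, tsik, trill, cry, other}.  "Premature" avoidance is
flagged below postnatal day 28 (postnatal weeks 0–3).

Transition call ratios compare infant call counts in `[t−10, t)` vs
`[t, t+10)` around context shifts, using only transitions with both full
windows inside the session; zero-before transitions are excluded from
ratios but counted, and the paired counts feed the signed-rank test.

The dyad-distance comparison normalizes (avoidance count, calls while
carried) to [0, 1] by min–max over all complete dyads and measures
Euclidean distances between the two littermate dyads of one caregiver in
one birth (DI_SC) and between two caregiver dyads of one infant (SI_DC);
a rank-sum test compares the two sets of segment lengths.

## Statistics

Spearman correlation is the product–moment correlation of mid-ranks;
missing values are handled pairwise-complete; constant columns are
flagged and their pairs undefined.  Adjustment (Holm by default,
Benjamini–Hochberg as the alternative) applies jointly to the strict
upper triangle via statsmodels.

The Wilcoxon routines are implemented here with explicit conventions:
signed-rank drops zero differences, mid-ranks ties, enumerates the exact
null by convolution over doubled ranks up to n = 25, and otherwise uses
the normal approximation with tie-corrected variance and a 0.5 continuity
correction; rank-sum enumerates the exact Mann–Whitney null by the
largest-observation recurrence when the smaller sample has ≤ 8
observations and there are no cross-sample ties, otherwise the
tie-corrected normal approximation.  scipy's implementations serve as
independent oracles in the test suite, never as the implementation.
Cohen's κ uses marginal-product chance agreement and is undefined when
both raters use a single shared category.

Group contrasts that would be fitted with a mixed model (random effects
for infant and caregiver) are covered by a cluster permutation test:
group labels are permuted at the dyad level, keeping all sessions of a
dyad together, with the add-one p estimator (1 + #{|T*| ≥ |T|})/(1 +
n_perm).  This controls dyad pseudoreplication without a parametric
random-effects structure; tidy model matrices can be exported for
refitting in any mixed-model tool.

## Simulator

The generator defines the study conditions; its defaults live in
`src/dyadkit/sim_defaults.yaml`, not in code.  Caregiver style has three
independent axes drawn once per caregiver: sensitivity (retrieval hazard
scale), tolerance (1 − tolerance scales the rejection hazard during
carrying) and carry motivation (re-retrieval promptness after a
dismount).  Retrieval latency is exponential with rate 0.015·sensitivity
per second, censored at 600 s — latencies span seconds to hundreds of
seconds and a few percent of sessions end unretrieved, as in real
assays.  Carrying alternates Holding/Transport by a two-state
exponential dwell process (25 s / 10 s means).  Rejection bouts
(0.4–3 s) arrive at 0.02·(1 − tolerance) per second; each ends in a
forced dismount with probability 0.84 after a truncated-exponential
delay on (0, 9.4].

The rejection-to-dismount interval law is piecewise-constant-hazard: the
forced scale is 9.4/ln(130/21) ≈ 5.16 s, which makes the phase-1 mass
match the published 109:21 short:long composition exactly and makes
ln S exactly two-segment with the kink at 9.4 s; the voluntary tail
scale 112 s is pinned by the published maximum interval (417.2 s)
being a plausible maximum of 21 tail draws.  Voluntary dismounts arrive
at 0.0025·(1 + 4·avoidance) per second, which puts the voluntary share
of dismounts near one-third under the default cohort.

Infant calls are a marked Poisson process per context: 10/min before
retrieval (twitter/phee-weighted), 8/min alone afterwards (cry-weighted),
14/min during rejection (tsik-dominant), 1/min while carried
(trill-dominant) plus an anxiety term of 6·anxiety_gain·(1 − tolerance)
calls/min of tsik/cry while carried.  Mixtures are qualitative defaults
chosen to reproduce the published direction of context-dependent call
usage; no published numbers exist for them.  Artificial rearing raises
the avoidance baseline (+0.35), doubles alone-context calling from
postnatal day 30, and lowers the direct-transfer propensity after day 12.

Cohort style draws are *balanced*: the style set is redrawn until the
sample rank correlation between sensitivity and tolerance is ≤ 0.1.  At
30 caregivers a raw draw shows |rank r| > 0.15 in roughly 40% of cohorts,
which would misrepresent the independence of the two axes that the
conditions assert; the balanced draw stays random and reproducible.

All randomness flows from one seed; cohorts derive per-session
substreams by counter, so any session regenerates identically in
isolation.

### What the simulator does and does not emulate

It reproduces the bout/interval structure, context-dependent calling,
style-driven associations and rearing-condition contrasts that the
analyses measure.  It does not emulate: development within a session,
serial correlation of style across postnatal days beyond a constant
style, caregiver vocalizations, acoustic properties of calls, holding
position, or multi-infant competition.  Passing recovery tests therefore
shows the pipeline measures what the generating mechanism encodes — not
that real data satisfy the generator's parametric forms, which are
stated assumptions (exponential latencies and dwells, Poisson calling)
and swappable via configuration.

## Problem sizes and numerical checks

The acceptance study uses 200 replicates at n = 130 for breakpoint
recovery, 1,000 randomized sessions for the exact partition check, a
15-family (60-dyad) cohort for association signs, 30 dyads per side for
the tolerance contrast, 20 per side for the rearing contrast, and
1,000-replicate null simulations for test calibration — sizes chosen to
estimate each quantity with comfortable margin.  The null-simulation
sample sizes (19 for signed-rank, 50 per group for rank-sum) are the
sizes at which the tests' attainable two-sided levels sit closest to the
nominal 5% (0.0494 and 0.0496, computed exactly from the null
distributions); at other sizes the discrete tests are conservative and a
calibration check against 5% would be systematically biased.

Degenerate inputs are errors, not silent values: empty interval lists,
constant vectors under min–max normalization, all-zero difference sets,
zero-range correlation columns and empty summary lists all raise.  Ties
in the breakpoint grid search break toward the smaller breakpoint;
ties in ranks use mid-ranks throughout.

## Known limitations

* The 9.37-s breakpoint printed for the original dataset is not
  reproducible without those raw data; the package validates its
  estimator by simulation instead and uses the rounded 9.4-s criterion
  downstream.
* GLMM fitting with model selection and the ordinal holding-site model
  are out of scope; the cluster permutation test is a deliberate,
  verifiable substitute for the group contrasts.
* TextGrid support covers interval tiers in the standard long and short
  text formats; point tiers are skipped.
* `%Rejection` has no single published definition for the retrieval
  assay; the carried-time denominator is a documented choice exposed as
  configuration.
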