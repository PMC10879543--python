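"""Generative simulator of caregiver-infant retrieval and reunion sessions.

Latent caregiver style has three axes -- *sensitivity* (fast retrieval),
*tolerance* (few rejections) and *carry motivation* (persistent carrying)
-- held constant across an individual's sessions.  Infants respond with
context-dependent calling and with avoidance that scales the voluntary
dismount hazard and the probability of refusing to cling.  The simulator
emits event/call/metadata files in the pipeline's own formats together
with the ground truth (per-dismount forced/voluntary labels, the true
interval change point, every latent parameter), so the whole analysis
chain can be exercised end to end and checked for parameter recovery.

Generating mechanisms (defaults in ``sim_defaults.yaml``):

* retrieval latency ~ Exponential with rate proportional to sensitivity,
  censored at the window end;
* carrying alternates Holding/Transport through a two-state exponential
  dwell process;
* rejection bouts arrive during carrying with hazard proportional to
  ``1 - tolerance``; each bout forces a dismount with fixed probability
  after a short truncated-exponential delay (support (0, 9.4] s);
* voluntary dismounts arrive at a low long-scale hazard scaled up by the
  infant's avoidance; the superposition gives the rejection-to-dismount
  interval distribution its two-phase log-survivorship shape;
* infant calls are a marked Poisson process whose rate and type mixture
  depend on the social context (twitter/phee-weighted before retrieval,
  trill-dominant while carried, tsik-dominant during rejection,
  cry-weighted when alone afterwards); an anxiety term adds tsik/cry
  calls while carried in proportion to ``(1 - tolerance)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .context_segmentation import (ALONE_AFTER, ALONE_BEFORE, CARRIED_CONTEXTS,
                                   DURING_REJECTION, segment_contexts)
from .ethogram_io import (CallRecord, EventRecord, SessionData, SessionMeta,
                          build_session, snap_to_grid, write_calls,
                          write_events, write_metadata)

_MIX_TYPES = ("phee", "twitter", "tsik", "trill", "cry", "other")


class ConfigError(ValueError):
    pass


@dataclass
class CaregiverStyle:
    sensitivity: float        # (0, 1]; drives retrieval hazard
    tolerance: float          # [0, 1]; 1 - tolerance drives rejection hazard
    carry_motivation: float   # [0, 1]; re-retrieval promptness

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1):
            raise ConfigError(f"sensitivity must be in (0, 1], "
                              f"got {self.sensitivity}")
        for name in ("tolerance", "carry_motivation"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class InfantState:
    pnd: int
    rearing: str = "family"          # {"family", "artificial"}
    avoidance_base: float = 0.05     # [0, 1]
    anxiety_gain: float = 1.0        # scales negative calls under intolerance
    direct_transfer_prop: float = 0.85

    def __post_init__(self) -> None:
        if not (0 <= self.avoidance_base <= 1):
            raise ConfigError("avoidance_base must be in [0, 1]")
        if not (0 <= self.direct_transfer_prop <= 1):
            raise ConfigError("direct_transfer_prop must be in [0, 1]")


@dataclass
class SimConfig:
    """Simulator parameters; see ``sim_defaults.yaml`` for documentation."""

    window_s: float
    retrieval_rate_per_s: float
    re_retrieval_rate_per_s: float
    rejection_rate_per_s: float
    rejection_bout_min_s: float
    rejection_bout_max_s: float
    contact_bout_s: float
    change_point_s: float
    forced_delay_scale_s: float
    forced_dismount_prob: float
    voluntary_tail_scale_s: float
    voluntary_rate_per_s: float
    voluntary_avoidance_gain: float
    holding_dwell_s: float
    transport_dwell_s: float
    refusal_gain: float
    call_rate_alone_before: float
    call_rate_alone_after: float
    call_rate_carried: float
    call_rate_rejection: float
    anxiety_rate_per_min: float
    call_mix: dict
    anxious_mix: dict
    art_avoidance_boost: float
    art_alone_call_mult: float
    art_alone_call_pnd: int
    art_direct_transfer_drop_pnd: int
    art_direct_transfer_prop: float
    direct_transfer_prop: float
    reunion_bins: int
    transfer_prob_per_bin: float
    transfer_gap_max_bins: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if v < 0:
                    raise ConfigError(f"{f.name} must be >= 0, got {v}")
        for ctx, mix in {**self.call_mix, "anxious": self.anxious_mix}.items():
            tot = sum(mix.get(t, 0.0) for t in _MIX_TYPES)
            if abs(tot - 1.0) > 1e-6:
                raise ConfigError(
                    f"call mix for {ctx!r} sums to {tot}, expected 1")

    @classmethod
    def default(cls) -> "SimConfig":
        text = resources.files("dyadkit").joinpath(
            "sim_defaults.yaml").read_text(encoding="utf-8")
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load a config; unspecified keys fall back to the defaults."""
        base = dataclasses.asdict(cls.default())
        overrides = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(overrides) - set(base)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        base.update(overrides)
        return cls(**base)


@dataclass
class SessionTruth:
    """Latent state behind one simulated session."""

    style: CaregiverStyle
    infant: InfantState
    dismount_labels: list[str]        # forced/voluntary, in event order
    n_rejections: int
    censored: bool                    # no retrieval within the window
    change_point_s: float


@dataclass
class GroundTruth:
    styles: dict[str, CaregiverStyle]          # per caregiver
    infants: dict[str, InfantState]            # per infant
    session_truth: dict[str, SessionTruth]     # per session
    change_point_s: float


@dataclass
class CohortData:
    sessions: list[SessionData]
    truth: GroundTruth


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# interval law (standalone sampler for recovery studies)
# ---------------------------------------------------------------------------

def simulate_dismount_intervals(n: int, config: Optional[SimConfig] = None,
                                seed=0) -> list[float]:
    """Draw rejection-to-dismount intervals from the two-phase law.

    Piecewise-constant hazard: the interval is exponential with the forced
    scale; a draw that outlives the change point continues on the
    voluntary tail scale.  This yields an exactly two-segment
    log-survivorship with the kink at the configured change point.
    Intervals are snapped to the 0.2-s coding grid (minimum one bin).
    """
    cfg = config or SimConfig.default()
    rng = _rng(seed)
    out = []
    for _ in range(n):
        t = rng.exponential(cfg.forced_delay_scale_s)
        if t > cfg.change_point_s:
            t = cfg.change_point_s + rng.exponential(cfg.voluntary_tail_scale_s)
        out.append(max(0.2, snap_to_grid(t)))
    return out


def _trunc_exp(rng: np.random.Generator, scale: float, upper: float) -> float:
    """Exponential(scale) truncated to (0, upper]."""
    u = rng.random()
    return -scale * math.log1p(-u * (1.0 - math.exp(-upper / scale)))


def _sample_mix(rng: np.random.Generator, mix: dict) -> str:
    p = np.array([mix.get(t, 0.0) for t in _MIX_TYPES])
    return _MIX_TYPES[rng.choice(len(_MIX_TYPES), p=p / p.sum())]


# ---------------------------------------------------------------------------
# single-session generator
# ---------------------------------------------------------------------------

def simulate_art_condition(infant: InfantState,
                           config: Optional[SimConfig] = None) -> InfantState:
    """Apply the artificial-rearing response profile to an infant state.

    Family-reared infants are returned unchanged.  Artificially reared
    infants get a raised avoidance baseline and, past the configured
    postnatal day, a reduced propensity for direct carrier-to-carrier
    transfers (they dismount to stay alone first).  The age-dependent
    surge in alone-context calling is applied at call-generation time from
    the ``rearing`` tag.
    """
    cfg = config or SimConfig.default()
    if infant.rearing != "artificial":
        return infant
    out = replace(infant,
                  avoidance_base=min(1.0, infant.avoidance_base
                                     + cfg.art_avoidance_boost))
    if infant.pnd > cfg.art_direct_transfer_drop_pnd:
        out = replace(out,
                      direct_transfer_prop=cfg.art_direct_transfer_prop)
    return out


def _alone_call_mult(infant: InfantState, cfg: SimConfig) -> float:
    if (infant.rearing == "artificial"
            and infant.pnd >= cfg.art_alone_call_pnd):
        return cfg.art_alone_call_mult
    return 1.0


def simulate_session(style: CaregiverStyle, infant: InfantState,
                     config: Optional[SimConfig] = None, seed=0,
                     meta: Optional[SessionMeta] = None
                     ) -> tuple[SessionData, SessionTruth]:
    """Simulate one retrieval-assay session.

    Returns the validated :class:`SessionData` plus the generating truth.
    Identical seeds and inputs give identical output.
    """
    cfg = config or SimConfig.default()
    rng = _rng(seed)
    infant = simulate_art_condition(infant, cfg)
    if meta is None:
        meta = SessionMeta(
            session_id=f"sim-{seed}", family_id="simfam",
            caregiver_id="cg", caregiver_role="mother", infant_id="inf",
            infant_sex="F", pnd=infant.pnd, rearing=infant.rearing,
            assay="retrieval", nominal_duration=cfg.window_s)

    events: list[EventRecord] = []
    labels: list[str] = []
    n_rej = 0
    sid = meta.session_id

    def ev(actor: str, behavior: str, onset: float, offset: float) -> None:
        events.append(EventRecord(sid, actor, behavior,
                                  snap_to_grid(onset), snap_to_grid(offset)))

    latency = rng.exponential(1.0 / (cfg.retrieval_rate_per_s
                                     * style.sensitivity))
    censored = latency >= cfg.window_s
    if censored:
        window_end = cfg.window_s
    else:
        t_ret = max(0.4, snap_to_grid(latency))
        window_end = snap_to_grid(t_ret + cfg.window_s)
        ev("caregiver", "contact", max(0.0, t_ret - cfg.contact_bout_s),
           t_ret + 0.2)
        ev("infant", "cling", t_ret, t_ret + 0.2)
        ev("caregiver", "retrieval", t_ret, t_ret + 0.2)

        rej_rate = cfg.rejection_rate_per_s * (1.0 - style.tolerance)
        vol_rate = cfg.voluntary_rate_per_s * (
            1.0 + cfg.voluntary_avoidance_gain * infant.avoidance_base)
        cur = t_ret
        while cur is not None and cur < window_end - 0.2:
            ep_start = cur
            t = ep_start
            dismount_at: Optional[float] = None
            kind = ""
            while True:
                t_rej = (t + rng.exponential(1.0 / rej_rate)
                         if rej_rate > 0 else math.inf)
                t_vol = (t + rng.exponential(1.0 / vol_rate)
                         if vol_rate > 0 else math.inf)
                if min(t_rej, t_vol) >= window_end - 0.4:
                    break                     # carried until the window ends
                if t_vol <= t_rej:
                    dismount_at = max(snap_to_grid(t_vol), ep_start + 0.2)
                    kind = "voluntary"
                    break
                r_start = max(snap_to_grid(t_rej), ep_start + 0.2)
                dur = snap_to_grid(rng.uniform(cfg.rejection_bout_min_s,
                                               cfg.rejection_bout_max_s))
                r_end = min(snap_to_grid(r_start + max(0.2, dur)),
                            window_end - 0.4)
                if r_end <= r_start:
                    break
                ev("caregiver", "rejection", r_start, r_end)
                n_rej += 1
                if rng.random() < cfg.forced_dismount_prob:
                    delay = _trunc_exp(rng, cfg.forced_delay_scale_s,
                                       cfg.change_point_s)
                    dismount_at = max(snap_to_grid(r_end + delay),
                                      r_end + 0.2)
                    kind = "forced"
                    if dismount_at >= window_end - 0.2:
                        dismount_at = None   # window closed first
                    break
                t = r_end
            carry_end = dismount_at if dismount_at is not None else window_end
            ev("infant", "carry_contact", ep_start, carry_end)
            _emit_locomotion(ev, rng, cfg, ep_start, carry_end)
            if dismount_at is None:
                break
            ev("infant", "dismount", dismount_at, dismount_at + 0.2)
            labels.append(kind)

            # alone: caregiver attempts contact; infant may refuse to cling
            re_rate = (cfg.re_retrieval_rate_per_s * style.sensitivity
                       * max(style.carry_motivation, 0.05))
            a = dismount_at + 0.2 + rng.exponential(1.0 / re_rate)
            cur = None
            p_refuse = min(0.9, cfg.refusal_gain * infant.avoidance_base)
            while a + cfg.contact_bout_s + 0.4 < window_end:
                a = snap_to_grid(a)
                ev("caregiver", "contact", a, a + cfg.contact_bout_s + 0.2)
                if rng.random() < p_refuse:
                    a = (a + cfg.contact_bout_s
                         + rng.exponential(1.0 / re_rate))
                    continue
                t_re = snap_to_grid(a + cfg.contact_bout_s)
                ev("infant", "cling", t_re, t_re + 0.2)
                ev("caregiver", "retrieval", t_re, t_re + 0.2)
                cur = t_re
                break

    skeleton = build_session(meta, events, [])
    calls = _emit_calls(rng, cfg, style, infant, skeleton)
    session = build_session(meta, events, calls)
    truth = SessionTruth(style=style, infant=infant, dismount_labels=labels,
                         n_rejections=n_rej, censored=censored,
                         change_point_s=cfg.change_point_s)
    return session, truth


def _emit_locomotion(ev, rng: np.random.Generator, cfg: SimConfig,
                     start: float, end: float) -> None:
    """Two-state Holding/Transport dwell process over a carrying episode."""
    t = start
    moving = bool(rng.random() < 0.5)
    while t < end - 0.2:
        dwell = rng.exponential(cfg.transport_dwell_s if moving
                                else cfg.holding_dwell_s)
        t_next = min(snap_to_grid(t + max(0.2, dwell)), end)
        if moving and t_next > t:
            ev("caregiver", "locomotion", t, t_next)
        t = t_next
        moving = not moving


def _emit_calls(rng: np.random.Generator, cfg: SimConfig,
                style: CaregiverStyle, infant: InfantState,
                session: SessionData) -> list[CallRecord]:
    """Context-dependent marked Poisson call emission."""
    timeline = segment_contexts(session, offset_s=cfg.change_point_s)
    alone_mult = _alone_call_mult(infant, cfg)
    anxiety = infant.anxiety_gain * (1.0 - style.tolerance)
    calls: list[CallRecord] = []
    for s, e, ctx in timeline.segments:
        dur_min = (e - s) / 60.0
        if dur_min <= 0:
            continue
        if ctx == ALONE_BEFORE:
            rate, mix = cfg.call_rate_alone_before * alone_mult, \
                cfg.call_mix[ctx]
        elif ctx == ALONE_AFTER:
            rate, mix = cfg.call_rate_alone_after * alone_mult, \
                cfg.call_mix[ctx]
        elif ctx == DURING_REJECTION:
            rate, mix = cfg.call_rate_rejection, cfg.call_mix[ctx]
        else:                                   # Holding / Transport
            rate, mix = cfg.call_rate_carried, cfg.call_mix[ctx]
        for _ in range(rng.poisson(rate * dur_min)):
            onset = rng.uniform(s, e)
            calls.append(CallRecord(session.meta.session_id, "infant",
                                    _sample_mix(rng, mix), round(onset, 1),
                                    round(min(onset + 0.4, e), 1)))
        if ctx in CARRIED_CONTEXTS and anxiety > 0:
            extra = rng.poisson(cfg.anxiety_rate_per_min * anxiety * dur_min)
            for _ in range(extra):
                onset = rng.uniform(s, e)
                calls.append(CallRecord(
                    session.meta.session_id, "infant",
                    _sample_mix(rng, cfg.anxious_mix), round(onset, 1),
                    round(min(onset + 0.4, e), 1)))
    calls.sort(key=lambda c: c.onset)
    return calls


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

_ROLES = ("mother", "father", "sibling")


def draw_style(rng: np.random.Generator) -> CaregiverStyle:
    """Population distribution of caregiver styles: broad, independent axes."""
    return CaregiverStyle(
        sensitivity=float(rng.uniform(0.15, 1.0)),
        tolerance=float(rng.uniform(0.05, 1.0)),
        carry_motivation=float(rng.uniform(0.3, 1.0)))


def draw_style_set(rng: np.random.Generator, n: int,
                   max_abs_r: float = 0.1, max_tries: int = 500
                   ) -> list[CaregiverStyle]:
    """Draw ``n`` caregiver styles with balanced (near-orthogonal) axes.

    Sensitivity and tolerance are independent in the population, but a
    small sample often shows a sizable chance correlation between them
    (sd of the rank correlation is about ``1/sqrt(n)``).  To make a cohort
    representative of that independence, the set is redrawn until the
    sample rank correlation between sensitivity and tolerance is below
    ``max_abs_r`` -- a balanced design draw, still random and fully
    reproducible from the generator state.
    """
    from scipy.stats import spearmanr
    last = None
    for _ in range(max_tries):
        styles = [draw_style(rng) for _ in range(n)]
        last = styles
        if n < 5:
            return styles
        r = spearmanr([s.sensitivity for s in styles],
                      [s.tolerance for s in styles]).statistic
        if abs(r) <= max_abs_r:
            return styles
    return last  # pragma: no cover - vanishingly unlikely


def simulate_cohort(n_families: int = 7, infants_per_birth: int = 2,
                    caregivers_per_family: int = 2,
                    pnd_schedule: Sequence[int] = (5, 12, 19, 26),
                    config: Optional[SimConfig] = None, seed: int = 0,
                    art_infants: int = 0) -> CohortData:
    """Simulate a multi-family cohort of retrieval-assay sessions.

    Styles are drawn once per caregiver and reused across infants and
    sessions; littermates share a birth id (enabling the same-caregiver
    littermate pairing).  ``art_infants`` marks that many infants per
    family as artificially reared.  All randomness derives from ``seed``
    through per-session counter substreams, so cohorts reproduce exactly
    and piecewise.
    """
    if min(n_families, infants_per_birth, caregivers_per_family) < 1:
        raise ConfigError("cohort counts must be >= 1")
    cfg = config or SimConfig.default()
    root = np.random.default_rng([seed, 0])
    styles: dict[str, CaregiverStyle] = {}
    infants: dict[str, InfantState] = {}
    session_truth: dict[str, SessionTruth] = {}
    sessions: list[SessionData] = []
    all_styles = draw_style_set(root, n_families * caregivers_per_family)
    counter = 0
    for fi in range(n_families):
        fam = f"F{fi:02d}"
        birth = f"{fam}:b0"
        cg_ids = []
        for ci in range(caregivers_per_family):
            cg = f"{fam}-{_ROLES[ci % len(_ROLES)]}{ci // len(_ROLES)}"
            styles[cg] = all_styles[fi * caregivers_per_family + ci]
            cg_ids.append(cg)
        for ii in range(infants_per_birth):
            inf_id = f"{fam}-i{ii}"
            rearing = "artificial" if ii < art_infants else "family"
            infants[inf_id] = InfantState(
                pnd=0, rearing=rearing,
                avoidance_base=float(root.uniform(0.02, 0.15)),
                anxiety_gain=float(root.uniform(0.6, 1.4)))
        for inf_idx in range(infants_per_birth):
            inf_id = f"{fam}-i{inf_idx}"
            for cg in cg_ids:
                for pnd in pnd_schedule:
                    counter += 1
                    sid = f"{fam}-{cg.split('-', 1)[1]}-{inf_id.split('-', 1)[1]}-p{pnd:03d}"
                    meta = SessionMeta(
                        session_id=sid, family_id=fam, caregiver_id=cg,
                        caregiver_role=cg.split("-", 1)[1].rstrip("0123456789"),
                        infant_id=inf_id,
                        infant_sex="F" if inf_idx % 2 else "M",
                        pnd=pnd, rearing=infants[inf_id].rearing,
                        assay="retrieval", nominal_duration=cfg.window_s,
                        birth_id=birth)
                    state = replace(infants[inf_id], pnd=pnd)
                    srng = np.random.default_rng([seed, counter])
                    sess, truth = simulate_session(styles[cg], state, cfg,
                                                   seed=srng, meta=meta)
                    sessions.append(sess)
                    session_truth[sid] = truth
    gt = GroundTruth(styles=styles, infants=infants,
                     session_truth=session_truth,
                     change_point_s=cfg.change_point_s)
    return CohortData(sessions=sessions, truth=gt)


def simulate_reunion_carriers(infant: InfantState,
                              config: Optional[SimConfig] = None,
                              seed=0, n_caregivers: int = 3
                              ) -> list[Optional[str]]:
    """Per-bin carrier identity over a family-reunion observation.

    Carrier changes arrive per 10-s bin with a fixed probability; a change
    is a direct transfer with the infant's ``direct_transfer_prop``,
    otherwise the infant stays alone for a few bins first (nondirect).
    """
    cfg = config or SimConfig.default()
    rng = _rng(seed)
    infant = simulate_art_condition(infant, cfg)
    carers = [f"C{i}" for i in range(n_caregivers)]
    seq: list[Optional[str]] = []
    cur = carers[int(rng.integers(n_caregivers))]
    i = 0
    while i < cfg.reunion_bins:
        seq.append(cur)
        i += 1
        if rng.random() < cfg.transfer_prob_per_bin:
            nxt = carers[int(rng.integers(n_caregivers))]
            while nxt == cur:
                nxt = carers[int(rng.integers(n_caregivers))]
            if rng.random() >= infant.direct_transfer_prop:
                gap = int(rng.integers(1, cfg.transfer_gap_max_bins + 1))
                for _ in range(min(gap, cfg.reunion_bins - i)):
                    seq.append(None)
                    i += 1
            cur = nxt
    return seq[: cfg.reunion_bins]


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, calls.csv, meta.csv and truth.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("events", "calls", "meta")}
    write_events([e for s in cohort.sessions for e in s.events],
                 paths["events"])
    write_calls([c for s in cohort.sessions for c in s.calls],
                paths["calls"])
    write_metadata([s.meta for s in cohort.sessions], paths["meta"])
    truth_path = out / "truth.json"
    truth = {
        "change_point_s": cohort.truth.change_point_s,
        "styles": {k: dataclasses.asdict(v)
                   for k, v in cohort.truth.styles.items()},
        "infants": {k: dataclasses.asdict(v)
                    for k, v in cohort.truth.infants.items()},
        "sessions": {
            k: {"dismount_labels": v.dismount_labels,
                "n_rejections": v.n_rejections, "censored": v.censored}
            for k, v in cohort.truth.session_truth.items()},
    }
    truth_path.write_text(json.dumps(truth, indent=1), encoding="utf-8")
    paths["truth"] = truth_path
    return paths
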