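"""Markov cohort engine: health states, annual transitions, cycle stepping,
and discounted cost/QALY accrual.

The model tracks expected state occupancy of an atrial-fibrillation cohort
over annual cycles.  Within a cycle each live person experiences at most one
index event -- an ischemic stroke or a major hemorrhage (intracranial or
extracranial), each split into fatal and non-fatal variants -- or, for
event-free decliners on aspirin, a conversion to warfarin.  Event
probabilities depend on the current therapy; destinations implement the care
rules: stroke survivors start warfarin, major-bleed survivors stop it.

Cycle accounting follows a "destination-state" convention: the event year is
charged the pre-event therapy's drug cost and valued at the destination
state's utility.  Structural conventions that annual-cycle models leave open
(discount timing, whether follow-up costs start in the event year, whether
bleed survivors return to the well state) are governed by
:class:`~afcea.params.ModelSwitches`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelSwitches, ParameterSet, TherapyRates

__all__ = [
    "HealthState",
    "EventType",
    "TransitionModel",
    "CohortTrace",
    "discount_factor",
    "build_transition_model",
    "step_cohort",
    "run_cohort",
]


class HealthState(enum.IntEnum):
    """Markov health states.  Therapy is implied by the label; the post-ICH
    and post-bleed states are on aspirin because a major bleed ends warfarin
    therapy, and post-stroke-on-warfarin reflects conversion after stroke."""

    WELL_ASPIRIN = 0
    WELL_WARFARIN = 1
    POST_STROKE_WARFARIN = 2
    POST_STROKE_ASPIRIN = 3
    POST_ICH = 4
    POST_BLEED = 5
    RECURRENT_STROKE = 6
    DEAD = 7


N_STATES = len(HealthState)

#: therapy whose event process applies in each live state
STATE_THERAPY: dict[HealthState, str] = {
    HealthState.WELL_ASPIRIN: "aspirin",
    HealthState.WELL_WARFARIN: "warfarin",
    HealthState.POST_STROKE_WARFARIN: "warfarin",
    HealthState.POST_STROKE_ASPIRIN: "aspirin",
    HealthState.POST_ICH: "aspirin",
    HealthState.POST_BLEED: "aspirin",
    HealthState.RECURRENT_STROKE: "warfarin",
    HealthState.DEAD: "aspirin",  # irrelevant: no costs accrue when dead
}


class EventType(enum.IntEnum):
    STROKE_FATAL = 0
    STROKE_NONFATAL = 1
    ICH_FATAL = 2
    ICH_NONFATAL = 3
    BLEED_FATAL = 4        # extracranial major bleed
    BLEED_NONFATAL = 5
    CONVERT = 6            # decliner starts warfarin (no clinical event)


N_EVENTS = len(EventType)


@dataclass
class TransitionModel:
    """Annual transition structure plus per-state/per-event accounting data.

    ``event_prob[s, e]`` is the probability that a person starting the cycle
    in state ``s`` experiences event ``e``; ``event_dest[s, e]`` the state
    they occupy next; ``event_cost[s, e]`` the one-time cost charged at the
    event.  ``stay_dest[s]`` is where the event-free remainder goes (self,
    except that post-bleed survivors may return to well-on-aspirin).
    """

    event_prob: np.ndarray          # (N_STATES, N_EVENTS)
    event_dest: np.ndarray          # (N_STATES, N_EVENTS) int
    event_cost: np.ndarray          # (N_STATES, N_EVENTS)
    stay_dest: np.ndarray           # (N_STATES,) int
    drug_cost: np.ndarray           # (N_STATES,) annual, by current therapy
    utility: np.ndarray             # (N_STATES,)
    monthly_cost: np.ndarray        # (N_STATES,) 12 x monthly follow-up cost
    transition_matrix: np.ndarray = field(init=False)  # (N_STATES, N_STATES)

    def __post_init__(self) -> None:
        P = np.zeros((N_STATES, N_STATES))
        stay = 1.0 - self.event_prob.sum(axis=1)
        if np.any(stay < -1e-12):
            raise ValueError("event probabilities exceed 1 in at least one state")
        for s in range(N_STATES):
            P[s, self.stay_dest[s]] += max(stay[s], 0.0)
            for e in range(N_EVENTS):
                P[s, self.event_dest[s, e]] += self.event_prob[s, e]
        self.transition_matrix = P
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows do not sum to 1")


def discount_factor(rate: float, cycle_index: int) -> float:
    """Discount factor (1+rate)^-cycle_index; cycle 0 is the first year."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float((1.0 + rate) ** (-cycle_index))


def _split_bleed(p_bleed: float, r: TherapyRates) -> tuple[float, float, float, float]:
    """(ich_fatal, ich_nonfatal, ecb_fatal, ecb_nonfatal) probabilities."""
    p_ich = p_bleed * r.frac_ich
    p_ecb = p_bleed * (1.0 - r.frac_ich)
    return (
        p_ich * r.frac_fatal_ich,
        p_ich * (1.0 - r.frac_fatal_ich),
        p_ecb * r.frac_fatal_bleed_excl_ich,
        p_ecb * (1.0 - r.frac_fatal_bleed_excl_ich),
    )


def build_transition_model(
    rates: tuple[TherapyRates, TherapyRates],
    conversion: float,
    params: ParameterSet,
) -> TransitionModel:
    """Assemble the annual transition model for one sub-cohort.

    ``conversion`` is the annual probability that an event-free decliner on
    aspirin (state WELL_ASPIRIN) starts warfarin; it reflects the sub-cohort's
    test status and is therefore supplied per sub-cohort rather than read
    from ``params``.
    """
    if not 0.0 <= conversion <= 1.0:
        raise ValueError(f"conversion probability {conversion} outside [0, 1]")
    aspirin, warfarin = rates
    if aspirin.therapy != "aspirin" or warfarin.therapy != "warfarin":
        raise ValueError("rates must be the (aspirin, warfarin) pair, in order")

    costs = params.effective_costs()
    utils = params.effective_utilities()
    sw = params.switches

    S, E = HealthState, EventType
    ep = np.zeros((N_STATES, N_EVENTS))
    dest = np.tile(np.arange(N_STATES), (N_EVENTS, 1)).T  # placeholder: self
    ecost = np.zeros((N_STATES, N_EVENTS))
    stay_dest = np.arange(N_STATES)

    stroke_once = {
        "aspirin": costs["cost_stroke_once_aspirin"],
        "warfarin": costs["cost_stroke_once_warfarin"],
    }

    # destination of a non-fatal event, per source state
    nonfatal_stroke_dest = {
        S.WELL_ASPIRIN: S.POST_STROKE_WARFARIN,   # convert-after-stroke rule
        S.WELL_WARFARIN: S.POST_STROKE_WARFARIN,
        S.POST_STROKE_WARFARIN: S.RECURRENT_STROKE,
        S.POST_STROKE_ASPIRIN: S.RECURRENT_STROKE,
        S.POST_ICH: S.POST_ICH,                   # permanent ICH disability
        S.POST_BLEED: S.POST_STROKE_WARFARIN,
        S.RECURRENT_STROKE: S.RECURRENT_STROKE,
    }
    nonfatal_ecb_dest = {
        S.WELL_ASPIRIN: S.WELL_ASPIRIN,           # no therapy to discontinue
        S.WELL_WARFARIN: S.POST_BLEED,            # warfarin discontinued
        S.POST_STROKE_WARFARIN: S.POST_STROKE_ASPIRIN,
        S.POST_STROKE_ASPIRIN: S.POST_STROKE_ASPIRIN,
        S.POST_ICH: S.POST_ICH,
        S.POST_BLEED: S.WELL_ASPIRIN,
        S.RECURRENT_STROKE: S.RECURRENT_STROKE,
    }
    nonfatal_ich_dest = {
        s: (S.RECURRENT_STROKE if s is S.RECURRENT_STROKE else S.POST_ICH)
        for s in nonfatal_stroke_dest
    }

    for s in HealthState:
        if s is S.DEAD:
            continue
        th = STATE_THERAPY[s]
        r = warfarin if th == "warfarin" else aspirin
        if r.p_stroke + r.p_bleed > 1.0:
            raise ValueError(f"p_stroke + p_bleed > 1 in state {s.name}")

        ep[s, E.STROKE_FATAL] = r.p_stroke * r.frac_fatal_stroke
        ep[s, E.STROKE_NONFATAL] = r.p_stroke * (1.0 - r.frac_fatal_stroke)
        (
            ep[s, E.ICH_FATAL],
            ep[s, E.ICH_NONFATAL],
            ep[s, E.BLEED_FATAL],
            ep[s, E.BLEED_NONFATAL],
        ) = _split_bleed(r.p_bleed, r)

        for fatal_e in (E.STROKE_FATAL, E.ICH_FATAL, E.BLEED_FATAL):
            dest[s, fatal_e] = S.DEAD
        dest[s, E.STROKE_NONFATAL] = nonfatal_stroke_dest[s]
        dest[s, E.ICH_NONFATAL] = nonfatal_ich_dest[s]
        dest[s, E.BLEED_NONFATAL] = nonfatal_ecb_dest[s]

        ecost[s, E.STROKE_FATAL] = costs["cost_fatal_stroke_once"]
        ecost[s, E.STROKE_NONFATAL] = stroke_once[th]
        # only fatal ischemic stroke has a printed fatal cost; fatal bleeds
        # are charged the corresponding non-fatal one-time cost
        ecost[s, E.ICH_FATAL] = costs["cost_ich_once"]
        ecost[s, E.ICH_NONFATAL] = costs["cost_ich_once"]
        ecost[s, E.BLEED_FATAL] = costs["cost_bleed_excl_ich_once"]
        ecost[s, E.BLEED_NONFATAL] = costs["cost_bleed_excl_ich_once"]

    # background conversion: event-free decliners on aspirin only
    residual = 1.0 - ep[S.WELL_ASPIRIN].sum()
    ep[S.WELL_ASPIRIN, E.CONVERT] = conversion * residual
    dest[S.WELL_ASPIRIN, E.CONVERT] = S.WELL_WARFARIN

    if sw.post_bleed_recovery:
        stay_dest[S.POST_BLEED] = S.WELL_ASPIRIN

    drug = np.array(
        [
            costs["cost_warfarin_annual"]
            if STATE_THERAPY[s] == "warfarin"
            else costs["cost_aspirin_annual"]
            for s in HealthState
        ]
    )
    drug[S.DEAD] = 0.0

    utility = np.array(
        [
            utils["u_well_aspirin"],
            utils["u_well_warfarin"],
            utils["u_stroke_warfarin"],
            utils["u_stroke_aspirin"],
            utils["u_ich"],
            utils["u_well_aspirin"],  # post-bleed year: no bleed utility printed
            utils["u_recurrent_stroke"],
            0.0,
        ]
    )

    monthly = np.zeros(N_STATES)
    monthly[S.POST_STROKE_WARFARIN] = 12.0 * costs["cost_stroke_monthly_warfarin"]
    monthly[S.POST_STROKE_ASPIRIN] = 12.0 * costs["cost_stroke_monthly_aspirin"]
    monthly[S.RECURRENT_STROKE] = 12.0 * costs["cost_stroke_monthly_warfarin"]
    monthly[S.POST_ICH] = 12.0 * costs["cost_ich_monthly"]

    return TransitionModel(
        event_prob=ep,
        event_dest=dest,
        event_cost=ecost,
        stay_dest=stay_dest,
        drug_cost=drug,
        utility=utility,
        monthly_cost=monthly,
    )


def step_cohort(
    state: np.ndarray, model: TransitionModel
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one cycle; return (next state vector, expected event counts)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state vector must have shape ({N_STATES},)")
    if np.any(state < 0):
        raise ValueError("state vector entries must be non-negative")
    nxt = state @ model.transition_matrix
    events = state @ model.event_prob
    return nxt, events


#: states whose occupants have no stroke history yet; strokes arising from
#: them are incident (first-ever) strokes, as opposed to recurrences
INCIDENT_SOURCE_STATES = (
    HealthState.WELL_ASPIRIN,
    HealthState.WELL_WARFARIN,
    HealthState.POST_ICH,
    HealthState.POST_BLEED,
)


@dataclass
class CohortTrace:
    """Per-cycle expected occupancy, discounted accruals, and event tallies.

    ``occupancy[t]`` is the state vector at the *start* of cycle ``t``
    (``occupancy[horizon]`` is the terminal distribution); ``events[t]``,
    ``cost[t]`` and ``qalys[t]`` accrue during cycle ``t`` and are already
    discounted.  ``events`` is resolved by source state so that incident
    events can be distinguished from recurrences.
    """

    occupancy: np.ndarray   # (horizon+1, N_STATES)
    cost: np.ndarray        # (horizon,)
    qalys: np.ndarray       # (horizon,)
    events: np.ndarray      # (horizon, N_STATES, N_EVENTS), undiscounted

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def total_events(self) -> np.ndarray:
        """Expected event counts over the horizon, by event type."""
        return self.events.sum(axis=(0, 1))

    def event_total(self, event: EventType) -> float:
        return float(self.total_events[event])

    @property
    def incident_strokes(self) -> float:
        """First-ever strokes: stroke events arising from states without a
        stroke history (excludes recurrences among stroke survivors)."""
        idx = list(INCIDENT_SOURCE_STATES)
        ev = self.events[:, idx, :]
        return float(
            ev[:, :, EventType.STROKE_FATAL].sum()
            + ev[:, :, EventType.STROKE_NONFATAL].sum()
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per cycle x state with occupancy, plus
        per-cycle discounted cost/QALY columns repeated for convenience."""
        horizon = self.cost.shape[0]
        rows = []
        for t in range(horizon + 1):
            for s in HealthState:
                rows.append(
                    {
                        "cycle": t,
                        "state": s.name,
                        "occupancy": self.occupancy[t, s],
                        "discounted_cost": self.cost[t] if t < horizon else np.nan,
                        "discounted_qalys": self.qalys[t] if t < horizon else np.nan,
                    }
                )
        frame = pd.DataFrame(rows)
        totals = pd.DataFrame(
            [
                {
                    "cycle": -1,
                    "state": "TOTAL",
                    "occupancy": np.nan,
                    "discounted_cost": self.total_cost,
                    "discounted_qalys": self.total_qalys,
                }
            ]
        )
        return pd.concat([frame, totals], ignore_index=True)


def run_cohort(
    initial: np.ndarray, model: TransitionModel, params: ParameterSet
) -> CohortTrace:
    """Iterate the cohort over the model horizon, accruing discounted costs
    and QALYs.

    Per cycle the cohort accrues: the pre-event therapy's annual drug cost;
    one-time costs on incident events; 12 x monthly follow-up cost per
    person-year in the post-stroke, recurrent-stroke and post-ICH states
    (from the event year or the following year, per the structural switch);
    and utility at the destination state's weight.  Everything is discounted
    at the cycle's discount factor; the dead accrue nothing.
    """
    sw: ModelSwitches = params.switches
    horizon = params.horizon_cycles
    state = np.asarray(initial, dtype=float).copy()

    occupancy = np.zeros((horizon + 1, N_STATES))
    cost = np.zeros(horizon)
    qalys = np.zeros(horizon)
    events = np.zeros((horizon, N_STATES, N_EVENTS))
    occupancy[0] = state

    followup_weight = {"start": 0.0, "mid": 0.5, "end": 1.0}[sw.followup_accrual]
    stay_prob = 1.0 - model.event_prob.sum(axis=1)
    for t in range(horizon):
        df = discount_factor(params.discount_rate, t + sw.discount_from)
        nxt, _ = step_cohort(state, model)

        drug = float(state @ model.drug_cost)
        one_time = float(np.einsum("s,se,se->", state, model.event_prob, model.event_cost))
        # follow-up cost stream on start-of-cycle, end-of-cycle, or mid-cycle
        # occupancy of the states that carry a monthly cost
        occ_m = (1.0 - followup_weight) * state + followup_weight * nxt
        monthly = float(occ_m @ model.monthly_cost)
        # utility of the destination state, per transition mass
        u_dest = model.utility[model.event_dest]          # (S, E)
        u_events = float(np.einsum("s,se,se->", state, model.event_prob, u_dest))
        u_stay = float((state * stay_prob) @ model.utility[model.stay_dest])

        cost[t] = df * (drug + one_time + monthly)
        qalys[t] = df * (u_events + u_stay)
        events[t] = state[:, None] * model.event_prob
        state = nxt
        occupancy[t + 1] = state

    return CohortTrace(occupancy=occupancy, cost=cost, qalys=qalys, events=events)
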