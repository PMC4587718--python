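"""Individual-level microsimulation of the annual event process.

Each simulated patient follows the exact categorical event process encoded
in the cohort engine's transition model -- one draw per cycle over
{fatal/non-fatal stroke, fatal/non-fatal ICH, fatal/non-fatal extracranial
bleed, conversion, event-free} -- and accrues the same discounted costs and
utilities.  The cohort model is the expectation of this process, so
microsimulation means converge to cohort totals; the simulator therefore
serves as a brute-force validation oracle, and doubles as a generator of
synthetic patient-level trajectory data.

Each patient owns an independent RNG stream keyed by (seed, patient id), so
enlarging the cohort never perturbs the trajectories of earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    EventType,
    HealthState,
    INCIDENT_SOURCE_STATES,
    N_EVENTS,
    TransitionModel,
    build_transition_model,
    discount_factor,
)
from .params import ParameterSet, derive_therapy_rates
from .strategies import ArmResult, ArmSpec
from .cea import compute_icer  # noqa: F401  (re-exported convenience)

__all__ = [
    "CycleRecord",
    "PatientHistory",
    "MicrosimResult",
    "simulate_patient",
    "simulate_cohort",
    "trajectories_frame",
]


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    state: HealthState          # state at the start of the cycle
    event: EventType | None     # index event during the cycle, if any
    next_state: HealthState
    cost: float                 # discounted cost accrued this cycle
    utility: float              # discounted QALYs accrued this cycle


@dataclass
class PatientHistory:
    patient_id: int
    subcohort_index: int
    records: list[CycleRecord] = field(default_factory=list)
    test_cost: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.test_cost + sum(r.cost for r in self.records)

    @property
    def total_qalys(self) -> float:
        return sum(r.utility for r in self.records)

    @property
    def death_cycle(self) -> int | None:
        for r in self.records:
            if r.next_state is HealthState.DEAD:
                return r.cycle
        return None

    def event_counts(self) -> np.ndarray:
        counts = np.zeros(N_EVENTS)
        for r in self.records:
            if r.event is not None:
                counts[r.event] += 1
        return counts


def _arm_models(arm: ArmSpec, params: ParameterSet) -> list[TransitionModel]:
    rates = derive_therapy_rates(params)
    return [build_transition_model(rates, sc.conversion, params) for sc in arm.subcohorts]


def _subcohort_weights(arm: ArmSpec) -> np.ndarray:
    counts = np.array([sc.count for sc in arm.subcohorts], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("arm has no persons")
    return counts / total


def _accrue_cycle(
    state: int,
    event: int | None,
    nxt: int,
    t: int,
    model: TransitionModel,
    params: ParameterSet,
) -> tuple[float, float]:
    """Discounted (cost, utility) of one realised patient-cycle, mirroring
    the cohort engine's accounting exactly."""
    sw = params.switches
    df = discount_factor(params.discount_rate, t + sw.discount_from)
    w = {"start": 0.0, "mid": 0.5, "end": 1.0}[sw.followup_accrual]
    cost = model.drug_cost[state]
    if event is not None:
        cost += model.event_cost[state, event]
    cost += (1.0 - w) * model.monthly_cost[state] + w * model.monthly_cost[nxt]
    utility = model.utility[nxt]
    return df * cost, df * utility


def simulate_patient(
    arm: ArmSpec,
    params: ParameterSet,
    rng: np.random.Generator,
    patient_id: int = 0,
) -> PatientHistory:
    """Simulate one patient: draw sub-cohort membership from the arm's
    split, then one categorical event draw per cycle."""
    weights = _subcohort_weights(arm)
    models = _arm_models(arm, params)
    k = int(rng.choice(len(weights), p=weights))
    model = models[k]
    state = int(arm.subcohorts[k].initial_state)
    hist = PatientHistory(
        patient_id=patient_id,
        subcohort_index=k,
        test_cost=arm.test_cost_per_person,
    )
    for t in range(params.horizon_cycles):
        if state == HealthState.DEAD:
            hist.records.append(
                CycleRecord(t, HealthState.DEAD, None, HealthState.DEAD, 0.0, 0.0)
            )
            continue
        probs = model.event_prob[state]
        u = rng.random()
        cum = np.cumsum(probs)
        idx = int(np.searchsorted(cum, u, side="right"))
        if idx < N_EVENTS:
            event: int | None = idx
            nxt = int(model.event_dest[state, idx])
        else:
            event = None
            nxt = int(model.stay_dest[state])
        cost, utility = _accrue_cycle(state, event, nxt, t, model, params)
        hist.records.append(
            CycleRecord(
                t,
                HealthState(state),
                EventType(event) if event is not None else None,
                HealthState(nxt),
                cost,
                utility,
            )
        )
        state = nxt
    return hist


@dataclass
class MicrosimResult:
    """Cohort-scale aggregates of a microsimulation with Monte-Carlo
    standard errors (also cohort scale)."""

    arm_label: str
    n_patients: int
    cohort_size: float
    cost: float
    cost_se: float
    qalys: float
    qalys_se: float
    events: np.ndarray        # (N_EVENTS,) expected counts, cohort scale
    events_se: np.ndarray
    incident_strokes: float
    seed: int

    def to_arm_result(self) -> ArmResult:
        """View as an :class:`ArmResult` for CEA arithmetic."""
        return ArmResult(
            label=self.arm_label, cost=self.cost, qalys=self.qalys, events=self.events
        )


def simulate_cohort(
    n: int, seed: int, arm: ArmSpec, params: ParameterSet
) -> MicrosimResult:
    """Simulate ``n`` independent patients and scale means to the cohort.

    Vectorised over patients, but each patient's uniforms come from an RNG
    stream keyed by (seed, patient id), so results for patient ``i`` are
    identical whatever ``n`` is, and match :func:`simulate_patient` run with
    the same stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    horizon = params.horizon_cycles
    # one stream per patient: first uniform picks the sub-cohort, the rest
    # drive the per-cycle categorical draws
    U = np.empty((n, horizon + 1))
    for i in range(n):
        U[i] = np.random.default_rng((seed, i)).random(horizon + 1)

    weights = _subcohort_weights(arm)
    models = _arm_models(arm, params)
    cum_w = np.cumsum(weights)
    sub = np.searchsorted(cum_w, U[:, 0], side="right").clip(max=len(weights) - 1)

    state = np.array([int(arm.subcohorts[k].initial_state) for k in sub])
    cost = np.full(n, arm.test_cost_per_person, dtype=float)
    qalys = np.zeros(n)
    events = np.zeros((n, N_EVENTS))
    incident = np.zeros(n)
    incident_sources = {int(s) for s in INCIDENT_SOURCE_STATES}
    sw = params.switches
    w_mid = {"start": 0.0, "mid": 0.5, "end": 1.0}[sw.followup_accrual]

    for t in range(horizon):
        df = discount_factor(params.discount_rate, t + sw.discount_from)
        u = U[:, t + 1]
        nxt = state.copy()
        for k, model in enumerate(models):
            for s in np.unique(state[sub == k]):
                mask = (sub == k) & (state == s)
                if s == HealthState.DEAD or not mask.any():
                    continue
                cum = np.cumsum(model.event_prob[s])
                idx = np.searchsorted(cum, u[mask], side="right")
                has_event = idx < N_EVENTS
                dest = np.where(
                    has_event,
                    model.event_dest[s, idx.clip(max=N_EVENTS - 1)],
                    model.stay_dest[s],
                )
                nxt[mask] = dest
                ev_rows = np.flatnonzero(mask)[has_event]
                ev_idx = idx[has_event]
                events[ev_rows, ev_idx] += 1
                if s in incident_sources:
                    stroke_mask = (ev_idx == EventType.STROKE_FATAL) | (
                        ev_idx == EventType.STROKE_NONFATAL
                    )
                    incident[ev_rows[stroke_mask]] += 1
                one_time = np.where(
                    has_event, model.event_cost[s, idx.clip(max=N_EVENTS - 1)], 0.0
                )
                monthly = (1.0 - w_mid) * model.monthly_cost[s] + w_mid * model.monthly_cost[
                    dest
                ]
                cost[mask] += df * (model.drug_cost[s] + one_time + monthly)
                qalys[mask] += df * model.utility[dest]
        state = nxt

    scale = params.cohort_size
    sqn = np.sqrt(n)
    return MicrosimResult(
        arm_label=arm.label,
        n_patients=n,
        cohort_size=scale,
        cost=float(cost.mean()) * scale,
        cost_se=float(cost.std(ddof=1) / sqn) * scale,
        qalys=float(qalys.mean()) * scale,
        qalys_se=float(qalys.std(ddof=1) / sqn) * scale,
        events=events.mean(axis=0) * scale,
        events_se=events.std(axis=0, ddof=1) / sqn * scale,
        incident_strokes=float(incident.mean()) * scale,
        seed=seed,
    )


def trajectories_frame(
    n: int, seed: int, arm: ArmSpec, params: ParameterSet
) -> pd.DataFrame:
    """Per-patient trajectory export: one row per patient-cycle."""
    rows = []
    for i in range(n):
        rng = np.random.default_rng((seed, i))
        hist = simulate_patient(arm, params, rng, patient_id=i)
        for r in hist.records:
            rows.append(
                {
                    "patient_id": i,
                    "subcohort": hist.subcohort_index,
                    "cycle": r.cycle,
                    "state": r.state.name,
                    "event": r.event.name if r.event is not None else "",
                    "next_state": r.next_state.name,
                    "discounted_cost": r.cost,
                    "discounted_qalys": r.utility,
                }
            )
    return pd.DataFrame(rows)
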