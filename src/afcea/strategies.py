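"""Care strategies: usual care (aspirin) versus the genetic-test strategy.

A strategy is an :class:`ArmSpec`: a split of the cohort into sub-cohorts
with their own starting state and background conversion probability, plus a
one-time per-person test cost.  In the test strategy, 40 % of patients test
positive; a fraction ``adherence`` of those start warfarin immediately,
the remaining positives convert at twice the background rate, and negatives
at half of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import (
    EventType,
    HealthState,
    N_EVENTS,
    N_STATES,
    CohortTrace,
    build_transition_model,
    run_cohort,
)
from .params import ParameterSet, derive_therapy_rates

__all__ = [
    "SubCohort",
    "ArmSpec",
    "ArmResult",
    "build_usual_care_arm",
    "build_test_arm",
    "evaluate_arm",
]


@dataclass(frozen=True)
class SubCohort:
    count: float
    initial_state: HealthState
    conversion: float  # annual probability a decliner starts warfarin

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("sub-cohort count must be >= 0")
        if not 0.0 <= self.conversion <= 1.0:
            raise ValueError("conversion probability outside [0, 1]")


@dataclass(frozen=True)
class ArmSpec:
    label: str  # "usual_care" | "test"
    subcohorts: tuple[SubCohort, ...]
    test_cost_per_person: float = 0.0

    @property
    def total_persons(self) -> float:
        return sum(sc.count for sc in self.subcohorts)


@dataclass
class ArmResult:
    """Discounted totals and cumulative event tallies for one strategy arm."""

    label: str
    cost: float
    qalys: float
    events: np.ndarray  # (N_EVENTS,) expected counts over the horizon
    traces: list[CohortTrace] = field(default_factory=list, repr=False)

    def event_total(self, event: EventType) -> float:
        return float(self.events[event])

    @property
    def strokes(self) -> float:
        """All ischemic strokes (fatal + non-fatal) over the horizon,
        including recurrences among stroke survivors."""
        return self.event_total(EventType.STROKE_FATAL) + self.event_total(
            EventType.STROKE_NONFATAL
        )

    @property
    def incident_strokes(self) -> float:
        """First-ever strokes over the horizon (excludes recurrences)."""
        return sum(tr.incident_strokes for tr in self.traces)

    @property
    def ich_bleeds(self) -> float:
        return self.event_total(EventType.ICH_FATAL) + self.event_total(
            EventType.ICH_NONFATAL
        )

    @property
    def extracranial_bleeds(self) -> float:
        return self.event_total(EventType.BLEED_FATAL) + self.event_total(
            EventType.BLEED_NONFATAL
        )

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "arm": self.label,
                "cost": self.cost,
                "qalys": self.qalys,
                "strokes": self.strokes,
                "incident_strokes": self.incident_strokes,
                "ich_bleeds": self.ich_bleeds,
                "extracranial_bleeds": self.extracranial_bleeds,
                "conversions": self.event_total(EventType.CONVERT),
            }
        )


def build_usual_care_arm(params: ParameterSet) -> ArmSpec:
    """All patients decline warfarin and take aspirin; they convert to
    warfarin at the background annual rate.  No test cost."""
    return ArmSpec(
        label="usual_care",
        subcohorts=(
            SubCohort(
                count=params.cohort_size,
                initial_state=HealthState.WELL_ASPIRIN,
                conversion=params.p_convert_base,
            ),
        ),
        test_cost_per_person=0.0,
    )


def build_test_arm(params: ParameterSet, adherence: float) -> ArmSpec:
    """Genetic-test strategy at a given test-positive adherence fraction.

    Test-positive adherers start warfarin at time zero; the remaining
    positives convert at ``p_convert_base * conv_mult_test_positive``;
    negatives at ``p_convert_base * conv_mult_test_negative``.  Every tested
    person (positive or negative) is charged the test cost once, at time
    zero, undiscounted.
    """
    if not 0.0 <= adherence <= 1.0:
        raise ValueError(f"adherence {adherence} outside [0, 1]")
    n = params.cohort_size
    n_pos = n * params.test_positive_fraction
    n_neg = n - n_pos
    n_adhere = n_pos * adherence
    conv_pos = min(1.0, params.p_convert_base * params.conv_mult_test_positive)
    conv_neg = min(1.0, params.p_convert_base * params.conv_mult_test_negative)
    return ArmSpec(
        label="test",
        subcohorts=(
            SubCohort(n_adhere, HealthState.WELL_WARFARIN, conversion=0.0),
            SubCohort(n_pos - n_adhere, HealthState.WELL_ASPIRIN, conv_pos),
            SubCohort(n_neg, HealthState.WELL_ASPIRIN, conv_neg),
        ),
        test_cost_per_person=params.cost_genetic_test,
    )


def evaluate_arm(arm: ArmSpec, params: ParameterSet) -> ArmResult:
    """Run the cohort engine for every sub-cohort and sum the results.

    The engine is linear in the initial state vector, so evaluating
    sub-cohorts separately and summing equals evaluating them jointly; each
    sub-cohort needs its own transition model only because its conversion
    probability differs.
    """
    rates = derive_therapy_rates(params)
    cost = arm.total_persons * arm.test_cost_per_person
    qalys = 0.0
    events = np.zeros(N_EVENTS)
    traces: list[CohortTrace] = []
    for sc in arm.subcohorts:
        model = build_transition_model(rates, sc.conversion, params)
        initial = np.zeros(N_STATES)
        initial[sc.initial_state] = sc.count
        trace = run_cohort(initial, model, params)
        cost += trace.total_cost
        qalys += trace.total_qalys
        events += trace.total_events
        traces.append(trace)
    return ArmResult(label=arm.label, cost=cost, qalys=qalys, events=events, traces=traces)
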