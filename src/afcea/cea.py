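"""Incremental cost-effectiveness arithmetic and adherence-threshold search.

The comparison is always pairwise: genetic-test strategy minus usual care.
Because the test arm's initial split is linear in the adherence fraction and
the cohort engine is linear in the initial state vector, incremental cost
and incremental QALYs are affine functions of adherence; threshold searches
therefore have unique roots.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .params import ParameterSet
from .strategies import ArmResult, build_test_arm, build_usual_care_arm, evaluate_arm

__all__ = [
    "CEAComparison",
    "compute_icer",
    "compare_at_adherence",
    "find_cost_effective_adherence",
    "find_breakeven_adherence",
    "adherence_sweep",
]

#: absolute tolerance of the adherence bisection searches
ADHERENCE_TOL = 1e-5


@dataclass(frozen=True)
class CEAComparison:
    """Incremental result of test vs usual care.

    ``icer`` is reported only when the ratio is meaningful (positive
    incremental QALYs at positive incremental cost, or the mirrored
    losing case); dominance is labelled instead of a ratio.
    """

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str  # test_dominates | usual_dominates | icer_defined | equivalent

    @property
    def cost_saving(self) -> float:
        """Positive when the test strategy saves money."""
        return -self.delta_cost


def compute_icer(test: ArmResult, usual: ArmResult, atol: float = 1e-9) -> CEAComparison:
    """Classify the pairwise comparison and compute the ICER where defined."""
    d_cost = test.cost - usual.cost
    d_qaly = test.qalys - usual.qalys
    if abs(d_cost) <= atol and abs(d_qaly) <= atol:
        return CEAComparison(d_cost, d_qaly, None, "equivalent")
    if d_cost <= 0 and d_qaly >= 0:
        return CEAComparison(d_cost, d_qaly, None, "test_dominates")
    if d_cost >= 0 and d_qaly <= 0:
        return CEAComparison(d_cost, d_qaly, None, "usual_dominates")
    return CEAComparison(d_cost, d_qaly, d_cost / d_qaly, "icer_defined")


def compare_at_adherence(params: ParameterSet, adherence: float) -> CEAComparison:
    """Evaluate both arms at the given test-positive adherence and compare."""
    usual = evaluate_arm(build_usual_care_arm(params), params)
    test = evaluate_arm(build_test_arm(params, adherence), params)
    return compute_icer(test, usual)


def _affine_deltas(params: ParameterSet):
    """Return (delta_cost(a), delta_qalys(a)) as affine callables, built from
    evaluations at adherence 0 and 1."""
    usual = evaluate_arm(build_usual_care_arm(params), params)
    lo = evaluate_arm(build_test_arm(params, 0.0), params)
    hi = evaluate_arm(build_test_arm(params, 1.0), params)
    c0, c1 = lo.cost - usual.cost, hi.cost - usual.cost
    q0, q1 = lo.qalys - usual.qalys, hi.qalys - usual.qalys
    return (lambda a: c0 + (c1 - c0) * a), (lambda a: q0 + (q1 - q0) * a)


def find_cost_effective_adherence(
    params: ParameterSet, wtp: float | None = None
) -> float | None:
    """Smallest adherence at which the test strategy is cost-effective.

    Cost-effective means ICER <= willingness-to-pay or outright dominance,
    i.e. net monetary benefit ``wtp * dQALY - dcost >= 0``.  Returns None
    when no adherence in [0, 1] qualifies.
    """
    if wtp is None:
        wtp = params.wtp_per_qaly
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    d_cost, d_qalys = _affine_deltas(params)

    def deficit(a: float) -> float:  # >0 while not cost-effective
        return d_cost(a) - wtp * d_qalys(a)

    if deficit(0.0) <= 0:
        return 0.0
    if deficit(1.0) > 0:
        return None
    return float(brentq(deficit, 0.0, 1.0, xtol=ADHERENCE_TOL))


def find_breakeven_adherence(params: ParameterSet) -> float | None:
    """Adherence at which the test strategy becomes cost-saving
    (incremental cost crosses zero); None when there is no crossing."""
    d_cost, _ = _affine_deltas(params)
    if d_cost(0.0) <= 0:
        return 0.0
    if d_cost(1.0) > 0:
        return None
    return float(brentq(d_cost, 0.0, 1.0, xtol=ADHERENCE_TOL))


def adherence_sweep(
    params: ParameterSet, adherences_pct: list[float]
) -> pd.DataFrame:
    """Evaluate the comparison over a list of adherence percentages.

    Returns one row per adherence with the signed cost saving (negative =
    net loss) and QALYs gained by the test strategy, cohort scale.
    """
    rows = []
    for pct in adherences_pct:
        cmp_ = compare_at_adherence(params, pct / 100.0)
        rows.append(
            {
                "adherence_pct": pct,
                "cost_saving": cmp_.cost_saving,
                "qalys_gained": cmp_.delta_qalys,
            }
        )
    return pd.DataFrame(rows, columns=["adherence_pct", "cost_saving", "qalys_gained"])
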