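"""Sensitivity analyses: one-way (tornado), stroke-risk stratification, and
the probabilistic sensitivity analysis (PSA).

Seven quantities are varied, matching the ranges declared in the parameter
set: the four epidemiological inputs (aspirin stroke rate, warfarin stroke
relative risk, warfarin bleed rate, aspirin bleed relative risk), the
genetic-test cost, and two grouped multipliers -- one scaling every drug and
event cost jointly (+-50 %), one scaling the utilities of the non-fatal
event states jointly (+-20 %).  The PSA draws each from a triangular
distribution with mode at the base case and support at the declared range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEAComparison, compare_at_adherence
from .params import ConfigurationError, ParameterSet

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "TORNADO_ADHERENCE",
    "PSA_ADHERENCE",
    "one_way_tornado",
    "chads2_sweep",
    "sample_triangular",
    "run_psa",
    "variance_contributions",
]

#: cost-neutral adherence at which one-way analyses are evaluated
TORNADO_ADHERENCE = 0.0525
#: adherence assumed for the probabilistic sensitivity analysis
PSA_ADHERENCE = 0.20


@dataclass(frozen=True)
class TornadoEntry:
    """One-way swing of a single parameter (or grouped multiplier)."""

    parameter: str
    low_input: float
    high_input: float
    at_low: CEAComparison
    at_high: CEAComparison

    @property
    def width(self) -> float | None:
        """|ICER(high) - ICER(low)| where both are defined, else None."""
        if self.at_low.icer is None or self.at_high.icer is None:
            return None
        return abs(self.at_high.icer - self.at_low.icer)


def one_way_tornado(
    params: ParameterSet, adherence: float = TORNADO_ADHERENCE
) -> list[TornadoEntry]:
    """Evaluate the comparison at the low and high bound of every ranged
    quantity, all else held at base."""
    entries = []
    for name in params.ranges:
        try:
            low, high = params.ranges[name]
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed range for {name!r}") from exc
        at_low = compare_at_adherence(params.replace(**{name: low}), adherence)
        at_high = compare_at_adherence(params.replace(**{name: high}), adherence)
        entries.append(TornadoEntry(name, low, high, at_low, at_high))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tabular export of a tornado analysis."""
    rows = []
    for e in entries:
        rows.append(
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "icer_low": e.at_low.icer,
                "label_low": e.at_low.label,
                "icer_high": e.at_high.icer,
                "label_high": e.at_high.label,
                "width": e.width,
            }
        )
    return pd.DataFrame(rows)


def chads2_sweep(
    params: ParameterSet,
    stroke_rate_grid: list[tuple[str, float]],
    adherence: float = PSA_ADHERENCE,
) -> pd.DataFrame:
    """Re-run the comparison with the aspirin stroke rate set per
    stroke-risk (CHADS2) level.

    ``stroke_rate_grid`` maps score labels to annual aspirin stroke rates
    (fractions).  Returns QALYs gained (cohort scale), incremental cost,
    and ICER/dominance per level.
    """
    rows = []
    for label, rate in stroke_rate_grid:
        if rate <= 0:
            raise ValueError(f"stroke rate for level {label!r} must be positive")
        # a stratum's rate may fall outside the base-case sensitivity range;
        # stretch the declared range so the scenario still validates
        ranges = dict(params.ranges)
        lo, hi = ranges.get("p_stroke_aspirin", (rate, rate))
        ranges["p_stroke_aspirin"] = (min(lo, rate), max(hi, rate))
        level = params.replace(p_stroke_aspirin=rate, ranges=ranges)
        cmp_ = compare_at_adherence(level, adherence)
        rows.append(
            {
                "level": label,
                "p_stroke_aspirin": rate,
                "qalys_gained": cmp_.delta_qalys,
                "delta_cost": cmp_.delta_cost,
                "icer": cmp_.icer,
                "label": cmp_.label,
            }
        )
    return pd.DataFrame(rows)


def sample_triangular(
    low: float, mode: float, high: float, rng: np.random.Generator, size=None
):
    """Draw from a triangular distribution on [low, high] with the given
    mode; degenerate supports return the point mass."""
    if not low <= mode <= high:
        raise ValueError(f"need low <= mode <= high, got {(low, mode, high)}")
    if low == high:
        return low if size is None else np.full(size, float(low))
    return rng.triangular(low, mode, high, size=size)


@dataclass
class PSAResult:
    """Draws and incremental outcomes of a probabilistic sensitivity run."""

    draws: pd.DataFrame         # one column per varied quantity
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    adherence: float
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    def quadrant_fractions(self) -> dict[str, float]:
        """Fractions of draws per cost-effectiveness-plane quadrant."""
        dc, dq = self.delta_cost, self.delta_qalys
        n = self.n_draws
        return {
            "cheaper_more_qalys": float(np.mean((dc < 0) & (dq > 0))),
            "costlier_more_qalys": float(np.mean((dc >= 0) & (dq > 0))),
            "cheaper_fewer_qalys": float(np.mean((dc < 0) & (dq <= 0))),
            "costlier_fewer_qalys": float(np.mean((dc >= 0) & (dq <= 0))),
        } if n else {}

    def to_frame(self) -> pd.DataFrame:
        out = self.draws.copy()
        out["delta_cost"] = self.delta_cost
        out["delta_qalys"] = self.delta_qalys
        return out


def run_psa(
    params: ParameterSet,
    n_draws: int = 10_000,
    adherence: float = PSA_ADHERENCE,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Each trial draws the seven varied quantities from their triangular
    distributions, evaluates both strategy arms, and records the
    incremental cost and QALYs.  Fully reproducible from ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    varied = list(params.ranges)
    draws = {
        name: sample_triangular(
            params.ranges[name][0],
            getattr(params, name),
            params.ranges[name][1],
            rng,
            size=n_draws,
        )
        for name in varied
    }
    d_cost = np.empty(n_draws)
    d_qalys = np.empty(n_draws)
    for i in range(n_draws):
        trial = params.replace(**{name: float(draws[name][i]) for name in varied})
        cmp_ = compare_at_adherence(trial, adherence)
        d_cost[i] = cmp_.delta_cost
        d_qalys[i] = cmp_.delta_qalys
    return PSAResult(
        draws=pd.DataFrame(draws),
        delta_cost=d_cost,
        delta_qalys=d_qalys,
        adherence=adherence,
        seed=seed,
    )


def variance_contributions(
    result: PSAResult, wtp: float | None = None, params: ParameterSet | None = None
) -> pd.Series:
    """Per-parameter shares of PSA outcome variability.

    The scalar outcome is incremental net monetary benefit,
    ``wtp * dQALY - dcost``.  Each share is the squared Pearson correlation
    between the parameter's draws and the outcome, normalised to sum to one
    over the varied parameters.
    """
    if result.n_draws < 2:
        raise ValueError("need at least 2 draws")
    if wtp is None:
        wtp = params.wtp_per_qaly if params is not None else 50_000.0
    outcome = wtp * result.delta_qalys - result.delta_cost
    if np.var(outcome) == 0:
        raise ValueError("PSA outcome has zero variance; shares undefined")
    r2 = {}
    for name in result.draws.columns:
        x = result.draws[name].to_numpy()
        if np.var(x) == 0:
            r2[name] = 0.0
        else:
            r2[name] = float(np.corrcoef(x, outcome)[0, 1] ** 2)
    shares = pd.Series(r2)
    return shares / shares.sum()
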