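"""Model parameters: definition, loading, validation, and derived therapy rates.

All probabilities are stored as annual fractions (0.045 means 4.5 %/year),
all costs in 2005 US dollars, all utilities on the 0--1 QALY-weight scale.
Human-edited configuration files may write probabilities as percent strings
("4.5%"); they are normalised to fractions on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ModelSwitches",
    "ParameterSet",
    "TherapyRates",
    "ConfigurationError",
    "load_parameters",
    "derive_therapy_rates",
    "DEFAULT_CONFIG_PATH",
]

DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "base_case.yaml"


class ConfigurationError(ValueError):
    """A configuration document is missing keys or contains invalid values."""


class ModelSwitches(BaseModel):
    """Structural accounting conventions of the cohort engine.

    These switches select among equally defensible cycle-accounting
    conventions that annual-cycle Markov models leave open; they are not
    clinical inputs.

    discount_from
        Exponent applied to the first model year: 0 discounts cycle t by
        (1+r)^-t (first year undiscounted), 1 by (1+r)^-(t+1).  The default
        of 1 treats accruals as falling at the end of each year.
    followup_accrual
        Occupancy basis for the 12 x monthly follow-up cost stream of the
        post-stroke, recurrent-stroke and post-ICH states: "start" charges
        states occupied at the start of a cycle (follow-up begins the year
        after the index event), "end" states occupied at its end (the full
        event year is charged on top of the one-time cost), "mid" the
        average of the two (events fall mid-year on average, so half the
        event year is charged).  Default "mid".
    post_bleed_recovery
        If True, survivors of an extracranial major bleed spend one cycle in
        the post-bleed state and then return to the well-on-aspirin state;
        if False they remain in the post-bleed state.
    """

    discount_from: int = Field(default=1, ge=0, le=1)
    followup_accrual: Literal["start", "mid", "end"] = "mid"
    post_bleed_recovery: bool = True

    model_config = {"frozen": True}


#: (low, high) sensitivity bounds for every quantity varied in one-way and
#: probabilistic sensitivity analyses. ``cost_multiplier`` scales every drug
#: and event cost jointly (+-50 %); ``utility_multiplier`` scales the
#: utilities of the non-fatal event states jointly (+-20 %).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "p_stroke_aspirin": (0.03, 0.06),
    "rr_stroke_warfarin": (0.37, 0.63),
    "p_bleed_warfarin": (0.02, 0.04),
    "rr_bleed_aspirin": (0.50, 0.70),
    "cost_genetic_test": (50.0, 200.0),
    "cost_multiplier": (0.5, 1.5),
    "utility_multiplier": (0.8, 1.2),
}


class ParameterSet(BaseModel):
    """Every model input: event probabilities, relative risks, fatality
    fractions, costs, utilities, structural constants, and sensitivity
    ranges."""

    # -- annual event probabilities and relative risks ------------------
    p_stroke_aspirin: float = Field(default=0.045, ge=0.0, le=1.0)
    rr_stroke_warfarin: float = Field(default=0.48, gt=0.0)
    p_bleed_warfarin: float = Field(default=0.025, ge=0.0, le=1.0)
    rr_bleed_aspirin: float = Field(default=0.59, gt=0.0)

    # -- event-severity fractions ---------------------------------------
    frac_ich: float = Field(default=0.2, ge=0.0, le=1.0)
    frac_fatal_stroke_warfarin: float = Field(default=0.082, ge=0.0, le=1.0)
    frac_fatal_stroke_aspirin: float = Field(default=0.179, ge=0.0, le=1.0)
    frac_fatal_ich: float = Field(default=0.364, ge=0.0, le=1.0)
    frac_fatal_bleed_excl_ich: float = Field(default=0.049, ge=0.0, le=1.0)

    # -- costs, 2005 USD -------------------------------------------------
    cost_warfarin_annual: float = Field(default=180.0, ge=0.0)
    cost_aspirin_annual: float = Field(default=10.0, ge=0.0)
    cost_fatal_stroke_once: float = Field(default=12130.0, ge=0.0)
    cost_stroke_once_warfarin: float = Field(default=9667.0, ge=0.0)
    cost_stroke_monthly_warfarin: float = Field(default=2652.0, ge=0.0)
    cost_stroke_once_aspirin: float = Field(default=9610.0, ge=0.0)
    cost_stroke_monthly_aspirin: float = Field(default=2168.0, ge=0.0)
    cost_ich_once: float = Field(default=31810.0, ge=0.0)
    cost_ich_monthly: float = Field(default=4690.0, ge=0.0)
    cost_bleed_excl_ich_once: float = Field(default=3620.0, ge=0.0)
    cost_genetic_test: float = Field(default=100.0, ge=0.0)

    # -- utilities --------------------------------------------------------
    u_well_warfarin: float = Field(default=0.987, ge=0.0, le=1.0)
    u_well_aspirin: float = Field(default=0.998, ge=0.0, le=1.0)
    u_stroke_warfarin: float = Field(default=0.476, ge=0.0, le=1.0)
    u_stroke_aspirin: float = Field(default=0.426, ge=0.0, le=1.0)
    u_ich: float = Field(default=0.4, ge=0.0, le=1.0)
    u_recurrent_stroke: float = Field(default=0.12, ge=0.0, le=1.0)
    u_dead: float = Field(default=0.0, ge=0.0, le=1.0)

    # -- structural constants ---------------------------------------------
    cohort_size: float = Field(default=1000.0, gt=0.0)
    horizon_cycles: int = Field(default=5, ge=1)
    discount_rate: float = Field(default=0.03, ge=0.0)
    test_positive_fraction: float = Field(default=0.40, ge=0.0, le=1.0)
    p_convert_base: float = Field(default=0.025, ge=0.0, le=1.0)
    conv_mult_test_positive: float = Field(default=2.0, ge=0.0)
    conv_mult_test_negative: float = Field(default=0.5, ge=0.0)
    wtp_per_qaly: float = Field(default=50000.0, gt=0.0)

    # -- grouped sensitivity multipliers (base case: no scaling) ----------
    cost_multiplier: float = Field(default=1.0, gt=0.0)
    utility_multiplier: float = Field(default=1.0, gt=0.0)

    # -- sensitivity ranges and structural switches -----------------------
    ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    switches: ModelSwitches = Field(default_factory=ModelSwitches)

    #: which fields came from the configuration document vs. built-in defaults
    provenance: dict[str, str] = Field(default_factory=dict, repr=False)

    model_config = {"validate_assignment": True}

    # ------------------------------------------------------------------
    @model_validator(mode="after")
    def _check_cross_field_invariants(self) -> "ParameterSet":
        errors: list[str] = []
        if not 0.0 <= self.p_stroke_aspirin * self.rr_stroke_warfarin <= 1.0:
            errors.append(
                "derived p_stroke_warfarin = p_stroke_aspirin * rr_stroke_warfarin "
                "outside [0, 1]"
            )
        if not 0.0 <= self.p_bleed_warfarin * self.rr_bleed_aspirin <= 1.0:
            errors.append(
                "derived p_bleed_aspirin = p_bleed_warfarin * rr_bleed_aspirin "
                "outside [0, 1]"
            )
        for name, (low, high) in self.ranges.items():
            base = getattr(self, name, None)
            if base is None:
                errors.append(f"range given for unknown parameter {name!r}")
            elif not low <= base <= high:
                errors.append(
                    f"range for {name!r} must satisfy low <= base <= high "
                    f"(got {low} <= {base} <= {high})"
                )
        if errors:
            raise ValueError("; ".join(errors))
        return self

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "ParameterSet":
        """Return a validated copy with the given fields replaced."""
        data = self.model_dump()
        data.update(overrides)
        return ParameterSet(**data)

    def effective_utilities(self) -> dict[str, float]:
        """Utilities after the grouped non-fatal-state multiplier, clipped
        to the unit interval.  Healthy-state utilities are never scaled."""
        m = self.utility_multiplier
        return {
            "u_well_warfarin": self.u_well_warfarin,
            "u_well_aspirin": self.u_well_aspirin,
            "u_stroke_warfarin": min(1.0, self.u_stroke_warfarin * m),
            "u_stroke_aspirin": min(1.0, self.u_stroke_aspirin * m),
            "u_ich": min(1.0, self.u_ich * m),
            "u_recurrent_stroke": min(1.0, self.u_recurrent_stroke * m),
            "u_dead": 0.0,
        }

    def effective_costs(self) -> dict[str, float]:
        """Drug and event costs after the grouped cost multiplier.  The
        genetic-test cost has its own sensitivity range and is not scaled."""
        m = self.cost_multiplier
        keys = (
            "cost_warfarin_annual",
            "cost_aspirin_annual",
            "cost_fatal_stroke_once",
            "cost_stroke_once_warfarin",
            "cost_stroke_monthly_warfarin",
            "cost_stroke_once_aspirin",
            "cost_stroke_monthly_aspirin",
            "cost_ich_once",
            "cost_ich_monthly",
            "cost_bleed_excl_ich_once",
        )
        out = {k: getattr(self, k) * m for k in keys}
        out["cost_genetic_test"] = self.cost_genetic_test
        return out


@dataclass(frozen=True)
class TherapyRates:
    """Annual event process of one antithrombotic therapy."""

    therapy: str  # "aspirin" | "warfarin"
    p_stroke: float
    frac_fatal_stroke: float
    p_bleed: float
    frac_ich: float
    frac_fatal_ich: float
    frac_fatal_bleed_excl_ich: float

    def __post_init__(self) -> None:
        for name in (
            "p_stroke",
            "frac_fatal_stroke",
            "p_bleed",
            "frac_ich",
            "frac_fatal_ich",
            "frac_fatal_bleed_excl_ich",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.therapy}: {name} = {v} outside [0, 1]")
        if self.p_stroke + self.p_bleed > 1.0:
            raise ValueError(
                f"{self.therapy}: p_stroke + p_bleed = "
                f"{self.p_stroke + self.p_bleed} exceeds 1"
            )


# ---------------------------------------------------------------------------
# loading

_STRUCTURAL_KEYS = {"ranges", "switches", "provenance"}


def _normalise_value(key: str, value: Any) -> Any:
    """Convert percent strings like '4.5%' to fractions."""
    if isinstance(value, str) and value.strip().endswith("%"):
        return float(value.strip().rstrip("%")) / 100.0
    return value


def load_parameters(source: str | Path | Mapping[str, Any] | None = None) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    ``source`` may be a YAML file path, an already-parsed mapping, or None
    (pure base case).  Keys absent from the document fall back to the
    built-in base-case defaults; the returned object's ``provenance``
    records, per field, whether it came from the config or a default.
    """
    if source is None:
        doc: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            doc = {}
        elif not isinstance(loaded, dict):
            raise ConfigurationError(
                f"configuration root must be a mapping, got {type(loaded).__name__}"
            )
        else:
            doc = loaded

    known = set(ParameterSet.model_fields)
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(
            "unknown configuration key(s): " + ", ".join(sorted(unknown))
        )

    cleaned = {
        k: (_normalise_value(k, v) if k not in _STRUCTURAL_KEYS else v)
        for k, v in doc.items()
    }
    if "ranges" in cleaned and cleaned["ranges"] is not None:
        base_ranges = dict(DEFAULT_RANGES)
        base_ranges.update(
            {k: tuple(v) for k, v in cleaned["ranges"].items()}  # type: ignore[union-attr]
        )
        cleaned["ranges"] = base_ranges

    try:
        params = ParameterSet(**cleaned)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc

    params.provenance = {
        name: ("config" if name in doc else "default")
        for name in ParameterSet.model_fields
        if name != "provenance"
    }
    return params


def derive_therapy_rates(params: ParameterSet) -> tuple[TherapyRates, TherapyRates]:
    """Derive the per-therapy annual event processes (aspirin, warfarin).

    Warfarin's stroke probability is the aspirin baseline scaled by the
    stroke relative risk; aspirin's major-bleed probability is the warfarin
    baseline scaled by the bleed relative risk.  Stroke fatality is
    therapy-specific; bleed fatality depends only on bleed type.
    """
    aspirin = TherapyRates(
        therapy="aspirin",
        p_stroke=params.p_stroke_aspirin,
        frac_fatal_stroke=params.frac_fatal_stroke_aspirin,
        p_bleed=params.p_bleed_warfarin * params.rr_bleed_aspirin,
        frac_ich=params.frac_ich,
        frac_fatal_ich=params.frac_fatal_ich,
        frac_fatal_bleed_excl_ich=params.frac_fatal_bleed_excl_ich,
    )
    warfarin = TherapyRates(
        therapy="warfarin",
        p_stroke=params.p_stroke_aspirin * params.rr_stroke_warfarin,
        frac_fatal_stroke=params.frac_fatal_stroke_warfarin,
        p_bleed=params.p_bleed_warfarin,
        frac_ich=params.frac_ich,
        frac_fatal_ich=params.frac_fatal_ich,
        frac_fatal_bleed_excl_ich=params.frac_fatal_bleed_excl_ich,
    )
    return aspirin, warfarin
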