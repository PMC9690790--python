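"""Indicator registry and derived-quantity transforms.

Sixteen indicators describe the soil, the crop and the amendment.  They fall
into three groups:

* group I — covered by a national standard and subject to a hard
  compliance limit (soil total heavy metal, heavy metal in the edible part,
  heavy metal in the amendment);
* group II — graded through farmland classification management
  (pH, SOM, CEC, available N/P/K, biomass, production, cost);
* group III — dynamic indicators without an external criterion, scored via
  derived quantities (available heavy metal via the reduction rate, plant
  heavy-metal burden via the bio-accumulation factor, amendment stability
  in years).

Transforms defined here convert raw measurements into the value a scoring
curve consumes: the bio-accumulation factor BAF = 100 * crop/soil (%), the
reduction rate alpha = 100 * (Xb - Xa)/Xb (%), and ratios to a local
reference (production, biomass, cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "Group",
    "IndicatorDefinition",
    "Measurement",
    "MeasurementError",
    "baf",
    "baf_class",
    "reduction_rate",
    "alpha_grade",
    "ratio_indicator",
]

Group = str  # "I", "II" or "III"

_TRANSFORMS = ("raw", "reduction_rate", "baf", "ratio_to_reference")
_CURVES = ("s_type", "inverse_s", "parabolic")


class MeasurementError(ValueError):
    """A measurement record violates the requirements of its indicator."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """Scoring configuration of one evaluation indicator.

    ``thresholds`` are the response-curve breakpoints in the units of the
    *transformed* value (so percent for BAF/alpha indicators, a dimensionless
    ratio for reference-relative ones).  S-type and inverse-S curves need
    L < H (L defaults to 0 where the published threshold table leaves it
    blank); the parabolic curve needs all four of L1 < L < H < H1.
    """

    name: str
    group: Group
    curve: str
    transform: str = "raw"
    units: str = ""
    L: Optional[float] = None
    H: Optional[float] = None
    L1: Optional[float] = None
    H1: Optional[float] = None
    reference_value: Optional[float] = None
    compliance_limit: Optional[float] = None
    assumption: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("I", "II", "III"):
            raise ValueError(f"{self.name}: group must be I, II or III")
        if self.curve not in _CURVES:
            raise ValueError(f"{self.name}: unknown curve {self.curve!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")
        if self.curve == "parabolic":
            pts = (self.L1, self.L, self.H, self.H1)
            if any(p is None for p in pts):
                raise ValueError(f"{self.name}: parabolic curve needs L1, L, H, H1")
            if not (pts[0] < pts[1] < pts[2] < pts[3]):  # type: ignore[operator]
                raise ValueError(
                    f"{self.name}: thresholds must satisfy L1 < L < H < H1, got {pts}"
                )
        else:
            if self.H is None:
                raise ValueError(f"{self.name}: curve needs an H threshold")
            L = 0.0 if self.L is None else self.L
            if not L < self.H:
                raise ValueError(f"{self.name}: need L < H, got L={L}, H={self.H}")
            if self.L is None:
                object.__setattr__(self, "L", 0.0)
        if self.reference_value is not None and self.reference_value <= 0:
            raise ValueError(f"{self.name}: reference value must be positive")

    def with_overrides(self, **kw) -> "IndicatorDefinition":
        return replace(self, **kw)


@dataclass(frozen=True)
class Measurement:
    """One measured indicator value for one treatment.

    ``value_before`` is required for reduction-rate indicators (the
    pre-stabilization concentration Xb, > 0); ``soil_total_hm`` for
    bio-accumulation indicators (total heavy metal in soil, mg/kg, > 0).
    ``censored_above`` marks values reported as "greater than" (e.g. an
    amendment stability of ">3" years), which score as lying just above the
    reported bound.
    """

    indicator: str
    treatment: str
    value: float
    value_before: Optional[float] = None
    soil_total_hm: Optional[float] = None
    metal: Optional[str] = None
    censored_above: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise MeasurementError(
                f"{self.indicator}/{self.treatment}: negative value {self.value!r}"
            )

    def require_for(self, d: IndicatorDefinition) -> None:
        """Check that the companion fields needed by *d*'s transform exist."""
        if d.transform == "reduction_rate":
            if self.value_before is None:
                raise MeasurementError(
                    f"{self.indicator}/{self.treatment}: reduction-rate indicator "
                    "needs a before value (value_before)"
                )
            if self.value_before <= 0:
                raise MeasurementError(
                    f"{self.indicator}/{self.treatment}: before value must be > 0"
                )
        elif d.transform == "baf":
            if self.soil_total_hm is None or self.soil_total_hm <= 0:
                raise MeasurementError(
                    f"{self.indicator}/{self.treatment}: bio-accumulation indicator "
                    "needs soil_total_hm > 0"
                )
        elif d.transform == "ratio_to_reference":
            if d.reference_value is None:
                raise MeasurementError(
                    f"{self.indicator}: ratio indicator has no reference value "
                    "configured"
                )


# ---------------------------------------------------------------------------
# Derived-quantity transforms
# ---------------------------------------------------------------------------

def baf(crop_hm: float, soil_hm: float) -> float:
    """Bio-accumulation factor: crop-to-soil heavy-metal ratio in percent.

    ``BAF = 100 * [X]crop / [X]soil`` with concentrations in mg/kg.
    """
    if soil_hm <= 0:
        raise ValueError(f"soil heavy-metal content must be > 0, got {soil_hm!r}")
    if crop_hm < 0:
        raise ValueError(f"crop heavy-metal content must be >= 0, got {crop_hm!r}")
    return 100.0 * crop_hm / soil_hm


def baf_class(value: float) -> str:
    """Uptake class of a bio-accumulation factor (percent).

    strong > 100%; moderate (10%, 100%]; weak (1%, 10%]; very weak <= 1%.
    """
    if value < 0:
        raise ValueError(f"BAF cannot be negative, got {value!r}")
    if value > 100:
        return "strong"
    if value > 10:
        return "moderate"
    if value > 1:
        return "weak"
    return "very_weak"


def reduction_rate(xb: float, xa: float) -> float:
    """Reduction rate of the available heavy metal, in percent.

    ``alpha = 100 * (Xb - Xa) / Xb`` where Xb and Xa are the available
    concentrations before and after stabilization.  A negative result means
    the available fraction increased; it is returned (with a warning) so
    downstream scoring can clamp it to zero rather than hiding the outcome.
    """
    if xb <= 0:
        raise ValueError(f"before-value Xb must be > 0, got {xb!r}")
    if xa < 0:
        raise ValueError(f"after-value Xa must be >= 0, got {xa!r}")
    alpha = 100.0 * (xb - xa) / xb
    if alpha < 0:
        warnings.warn(
            f"available heavy metal increased after treatment "
            f"(Xb={xb}, Xa={xa}, alpha={alpha:.1f}%)",
            stacklevel=2,
        )
    return alpha


def alpha_grade(alpha: float) -> str:
    """Equidistant grade of a reduction rate in [0, 100] percent.

    poor [0, 25); medium [25, 50); good [50, 75); excellent [75, 100].
    """
    if not 0 <= alpha <= 100:
        raise ValueError(f"reduction rate must lie in [0, 100]%, got {alpha!r}")
    if alpha >= 75:
        return "excellent"
    if alpha >= 50:
        return "good"
    if alpha >= 25:
        return "medium"
    return "poor"


def ratio_indicator(actual: float, reference: float) -> float:
    """Ratio of an observed quantity to its local reference.

    Production is actual/average-local production, biomass is crop weight
    over the average local crop weight, cost is cost over crop revenue.
    """
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    return actual / reference
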