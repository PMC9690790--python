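"""Standardized response-curve scoring: raw indicator value -> score in [0, 1].

Three piecewise-linear membership curves normalize indicators of different
units onto a common [0, 1] scale:

* "S" type      — 0 below L, linear ramp on [L, H], 1 above H
                  (more is better: SOM, CEC, available N/P/K, biomass,
                  production, stability, and the AHM reduction rate);
* inverse "S"   — 1 below L, falling ramp on [L, H], 0 above H
                  (less is better: heavy-metal burdens, cost);
* parabolic     — the midpoint type for pH: 0 outside [L1, H1], rising limb
                  on [L1, L), plateau of 1 on [L, H], falling limb on
                  (H, H1].

The rising limb of the parabolic curve is (x - L1)/(L - L1), the standard
midpoint-type membership that is continuous at L1 and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .indicators import IndicatorDefinition, Measurement, baf, ratio_indicator, reduction_rate

__all__ = [
    "IndicatorScore",
    "score_s_type",
    "score_inverse_s",
    "score_parabolic",
    "transform_value",
    "score_indicator",
]


@dataclass(frozen=True)
class IndicatorScore:
    """Scored measurement: raw value, post-transform value, score in [0, 1]."""

    indicator: str
    treatment: str
    raw_value: float
    transformed_value: float
    score: float
    curve: str
    compliant: Optional[bool] = None  # group-I compliance flag, None otherwise


def score_s_type(x: float, L: float, H: float) -> float:
    """Rising ramp: 0 for x < L, (x - L)/(H - L) on [L, H], 1 for x > H."""
    if L >= H:
        raise ValueError(f"S-type curve needs L < H, got L={L}, H={H}")
    if x < L:
        return 0.0
    if x > H:
        return 1.0
    return (x - L) / (H - L)


def score_inverse_s(x: float, L: float, H: float) -> float:
    """Falling ramp: 1 for x < L, (H - x)/(H - L) on [L, H], 0 for x > H."""
    if L >= H:
        raise ValueError(f"inverse-S curve needs L < H, got L={L}, H={H}")
    if x < L:
        return 1.0
    if x > H:
        return 0.0
    return (H - x) / (H - L)


def score_parabolic(x: float, L1: float, L: float, H: float, H1: float) -> float:
    """Midpoint type: plateau of 1 on [L, H], linear limbs to 0 at L1 and H1."""
    if not (L1 < L < H < H1):
        raise ValueError(
            f"parabolic curve needs L1 < L < H < H1, got ({L1}, {L}, {H}, {H1})"
        )
    if x < L1 or x > H1:
        return 0.0
    if x < L:
        return (x - L1) / (L - L1)
    if x <= H:
        return 1.0
    return (H1 - x) / (H1 - H)


def transform_value(d: IndicatorDefinition, m: Measurement) -> float:
    """Apply the indicator's transform to a measurement.

    Returns the value the scoring curve consumes: percent for
    reduction-rate and bio-accumulation indicators, a dimensionless ratio
    for reference-relative ones, the raw value otherwise.
    """
    m.require_for(d)
    if d.transform == "reduction_rate":
        return reduction_rate(m.value_before, m.value)  # type: ignore[arg-type]
    if d.transform == "baf":
        return baf(m.value, m.soil_total_hm)  # type: ignore[arg-type]
    if d.transform == "ratio_to_reference":
        return ratio_indicator(m.value, d.reference_value)  # type: ignore[arg-type]
    return m.value


def score_indicator(d: IndicatorDefinition, m: Measurement) -> IndicatorScore:
    """Transform a measurement and score it on the indicator's curve.

    A negative reduction rate (available heavy metal increased after
    treatment) scores 0.  Values reported as "greater than" a bound are
    scored just above that bound.  Group-I indicators additionally carry a
    pass/fail compliance flag against their standard limit; the flag never
    alters the score.
    """
    if m.indicator != d.name:
        raise ValueError(
            f"measurement is for {m.indicator!r}, definition for {d.name!r}"
        )
    x = transform_value(d, m)
    if m.censored_above:
        # ">v" lies just above the reported bound
        x = x * (1 + 1e-12) + 1e-9
    if d.transform == "reduction_rate" and x < 0:
        x = 0.0
    if d.curve == "s_type":
        s = score_s_type(x, d.L, d.H)  # type: ignore[arg-type]
    elif d.curve == "inverse_s":
        s = score_inverse_s(x, d.L, d.H)  # type: ignore[arg-type]
    else:
        s = score_parabolic(x, d.L1, d.L, d.H, d.H1)  # type: ignore[arg-type]
    compliant = None
    if d.compliance_limit is not None:
        compliant = bool(m.value <= d.compliance_limit)
    return IndicatorScore(
        indicator=d.name,
        treatment=m.treatment,
        raw_value=m.value,
        transformed_value=x,
        score=s,
        curve=d.curve,
        compliant=compliant,
    )
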