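"""Composite weighted score, equidistant grading and before/after verdict.

The composite score of a treatment is Si = sum_i w_i * X_i over the scored
indicators, with w_i the comprehensive AHP weight and X_i the normalized
score.  Indicators that were not measured contribute nothing; by default the
weights are *not* renormalized over the measured subset, so a sparsely
measured treatment is penalized for the missing information (this is the
convention of the published worked example).

Si is binned into five equidistant grades (I best), and the remediation
verdict is read off the grade-step improvement from the pre-stabilization
to the post-stabilization soil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .indicators import IndicatorDefinition, Measurement
from .scoring import IndicatorScore, score_indicator

__all__ = [
    "GRADES",
    "EvaluationResult",
    "ComparisonVerdict",
    "composite_score",
    "grade",
    "verdict",
    "evaluate_treatment",
    "compare_treatments",
]

#: Grades from best to worst; grade index I=1 .. V=5.
GRADES: tuple[str, ...] = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class EvaluationResult:
    """Full evaluation of one treatment."""

    treatment: str
    scores: dict[str, IndicatorScore]
    composite: float
    grade: str
    missing_indicators: tuple[str, ...] = ()
    compliance_violations: tuple[str, ...] = ()
    weights_renormalized: bool = False


@dataclass(frozen=True)
class ComparisonVerdict:
    """Before/after remediation verdict from the grade-step change.

    ``grade_steps`` is (index of the before grade) - (index of the after
    grade) with I=1 .. V=5, so a positive value is an improvement.
    """

    grade_before: str
    grade_after: str
    grade_steps: int
    verdict: str


def composite_score(
    scores: Mapping[str, float],
    weights: Mapping[str, float],
) -> tuple[float, list[str]]:
    """Weighted sum Si = sum w_i X_i and the list of unscored indicators.

    Every scored indicator must have a weight; weighted indicators without a
    score contribute 0 and are reported as missing.  Weights are used as
    given (no renormalization over the scored subset).
    """
    missing = sorted(set(weights) - set(scores))
    unweighted = sorted(set(scores) - set(weights))
    if unweighted:
        raise KeyError(f"scored indicators without a weight: {unweighted}")
    si = 0.0
    for name, x in scores.items():
        if not 0.0 <= x <= 1.0 + 1e-12:
            raise ValueError(f"score for {name!r} outside [0, 1]: {x!r}")
        si += weights[name] * x
    return si, missing


def grade(si: float) -> str:
    """Equidistant grade of a composite score.

    I (0.8, 1]; II (0.6, 0.8]; III (0.4, 0.6]; IV (0.2, 0.4]; V [0, 0.2].
    """
    if not 0.0 <= si <= 1.0 + 1e-9:
        raise ValueError(f"composite score must lie in [0, 1], got {si!r}")
    if si > 0.8:
        return "I"
    if si > 0.6:
        return "II"
    if si > 0.4:
        return "III"
    if si > 0.2:
        return "IV"
    return "V"


def verdict(grade_before: str, grade_after: str) -> ComparisonVerdict:
    """Remediation verdict from the grade change across stabilization.

    With grade indices I=1 .. V=5, S = index(before) - index(after):
    S > 1 excellent, S = 1 good, S = 0 qualified, S = -1 poor,
    S < -1 very poor.
    """
    for g in (grade_before, grade_after):
        if g not in GRADES:
            raise ValueError(f"unknown grade {g!r}")
    steps = GRADES.index(grade_before) - GRADES.index(grade_after)
    if steps > 1:
        label = "excellent"
    elif steps == 1:
        label = "good"
    elif steps == 0:
        label = "qualified"
    elif steps == -1:
        label = "poor"
    else:
        label = "very_poor"
    return ComparisonVerdict(
        grade_before=grade_before,
        grade_after=grade_after,
        grade_steps=steps,
        verdict=label,
    )


def evaluate_treatment(
    treatment: str,
    measurements: Sequence[Measurement],
    registry: Mapping[str, IndicatorDefinition],
    weights: Mapping[str, float],
    renormalize_missing: bool = False,
) -> EvaluationResult:
    """Score one treatment's measurements and aggregate them into Si.

    ``renormalize_missing=True`` rescales the weights of the measured
    indicators to sum to 1 — appropriate for complete designs, but it
    departs from the published worked example, which keeps the full-system
    weights.
    """
    scored: dict[str, IndicatorScore] = {}
    for m in measurements:
        if m.treatment != treatment:
            continue
        if m.indicator not in registry:
            raise KeyError(f"unknown indicator {m.indicator!r}")
        if m.indicator in scored:
            raise ValueError(
                f"duplicate measurement for ({m.indicator!r}, {treatment!r})"
            )
        scored[m.indicator] = score_indicator(registry[m.indicator], m)

    w = dict(weights)
    if renormalize_missing:
        present = {k: w[k] for k in scored if k in w}
        total = sum(present.values())
        if total <= 0:
            raise ValueError("no weighted indicator was measured")
        w = {k: v / total for k, v in present.items()}

    si, missing = composite_score({k: s.score for k, s in scored.items()}, w)
    violations = tuple(
        sorted(k for k, s in scored.items() if s.compliant is False)
    )
    return EvaluationResult(
        treatment=treatment,
        scores=scored,
        composite=si,
        grade=grade(si),
        missing_indicators=tuple(missing),
        compliance_violations=violations,
        weights_renormalized=renormalize_missing,
    )


def compare_treatments(
    before: EvaluationResult, after: EvaluationResult
) -> ComparisonVerdict:
    """Verdict for an (untreated, treated) pair of evaluations."""
    return verdict(before.grade, after.grade)
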