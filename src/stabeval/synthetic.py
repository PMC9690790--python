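"""Deterministic generators for judgment matrices, expert panels and studies.

These emulate the two data sources of a stabilization-effect evaluation:

* an expert questionnaire panel — judgment matrices built from a
  ground-truth weight vector with antisymmetric multiplicative log-normal
  noise on the ratio entries (the minimal noise model that preserves
  reciprocity exactly), optionally snapped to the Saaty 1-9 scale;
* a pot/field study — before/after measurement tables for the indicator
  registry, either from fixed true values or drawn uniformly from ranges.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .ahp import SAATY_VALUES, JudgmentMatrix, validate_judgment_matrix
from .indicators import IndicatorDefinition, Measurement
from .io import measurements_to_csv

__all__ = [
    "SyntheticPanelSpec",
    "SyntheticStudySpec",
    "make_consistent_matrix",
    "make_panel",
    "make_study",
    "make_study_measurements",
]

_LOG_SAATY = np.log(np.asarray(SAATY_VALUES))

#: A measurement value in a study spec: a number, a ">bound" string, or a
#: (low, high) range to sample uniformly.
StudyValue = Union[float, str, tuple[float, float]]


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Ground truth and noise model for a simulated expert panel."""

    truth: tuple[float, ...]
    n_experts: int = 20
    noise: float = 0.1
    saaty_round: bool = True
    seed: int = 0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.truth, dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("ground-truth weights must be positive and sum to 1")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if self.noise < 0:
            raise ValueError("noise magnitude must be nonnegative")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """True indicator values (or generative ranges) for a before/after study.

    ``treatments`` maps treatment label -> indicator -> value; the
    ``control`` treatment supplies the pre-stabilization concentration for
    reduction-rate indicators.  ``soil_total_hm`` is attached to every
    bio-accumulation indicator.
    """

    treatments: Mapping[str, Mapping[str, StudyValue]]
    control: str
    soil_total_hm: float
    metal: Optional[str] = "Cd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.treatments:
            raise ValueError(f"control treatment {self.control!r} not in treatments")
        if self.soil_total_hm <= 0:
            raise ValueError("soil_total_hm must be > 0")


def _saaty_snap(x: float) -> float:
    """Nearest Saaty value in log space (so 1/3 and 3 are treated alike)."""
    return float(SAATY_VALUES[int(np.argmin(np.abs(_LOG_SAATY - math.log(x))))])


def make_consistent_matrix(
    w: Sequence[float],
    noise: float = 0.0,
    saaty_round: bool = False,
    seed: int | np.random.Generator = 0,
    labels: tuple[str, ...] = (),
) -> JudgmentMatrix:
    """Judgment matrix from a ground-truth weight vector, plus optional noise.

    Entries are ``b_ij = (w_i / w_j) * exp(eps_ij)`` with ``eps`` an
    antisymmetric Gaussian draw of scale ``noise``; with ``saaty_round`` the
    upper triangle is snapped to the nearest Saaty value and the lower
    triangle set to the exact reciprocal, so reciprocity always holds to
    machine precision.  With zero noise and no rounding the matrix is
    perfectly consistent and the sum-product method recovers *w* exactly.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = w.size
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            b = (w[i] / w[j]) * math.exp(rng.normal(0.0, noise)) if noise > 0 else w[i] / w[j]
            if saaty_round:
                b = _saaty_snap(b)
            m[i, j] = b
            m[j, i] = 1.0 / b
    return validate_judgment_matrix(
        JudgmentMatrix(m, labels), strict=saaty_round
    )


def make_panel(spec: SyntheticPanelSpec) -> list[JudgmentMatrix]:
    """Independent expert judgment matrices around the spec's ground truth."""
    rng = np.random.default_rng(spec.seed)
    return [
        make_consistent_matrix(
            spec.truth,
            noise=spec.noise,
            saaty_round=spec.saaty_round,
            seed=rng,
            labels=spec.labels,
        )
        for _ in range(spec.n_experts)
    ]


def _resolve(value: StudyValue, rng: np.random.Generator) -> tuple[float, bool]:
    if isinstance(value, str):
        if not value.startswith(">"):
            raise ValueError(f"string study value must look like '>x', got {value!r}")
        return float(value[1:]), True
    if isinstance(value, tuple):
        lo, hi = value
        return float(rng.uniform(lo, hi)), False
    return float(value), False


def make_study_measurements(
    spec: SyntheticStudySpec,
    registry: Mapping[str, IndicatorDefinition],
) -> list[Measurement]:
    """Measurement records for every (treatment, indicator) pair in the spec.

    Records carry the companion fields their indicator's transform needs
    (the control concentration for reduction-rate indicators, the soil
    total for bio-accumulation ones), so they satisfy the measurement
    invariants by construction.
    """
    rng = np.random.default_rng(spec.seed)
    # resolve the control first: it supplies Xb for reduction-rate indicators
    resolved: dict[str, dict[str, tuple[float, bool]]] = {}
    order = [spec.control] + [t for t in spec.treatments if t != spec.control]
    for t in order:
        resolved[t] = {
            ind: _resolve(v, rng) for ind, v in spec.treatments[t].items()
        }
    records: list[Measurement] = []
    for t in order:
        for ind, (value, censored) in resolved[t].items():
            if ind not in registry:
                raise KeyError(f"unknown indicator {ind!r} in study spec")
            d = registry[ind]
            before = None
            soil = None
            metal = None
            if d.transform == "reduction_rate":
                if ind not in resolved[spec.control]:
                    raise ValueError(
                        f"{ind!r}: reduction-rate indicator missing from control"
                    )
                before = resolved[spec.control][ind][0]
                metal = spec.metal
            elif d.transform == "baf":
                soil = spec.soil_total_hm
                metal = spec.metal
            records.append(
                Measurement(
                    indicator=ind,
                    treatment=t,
                    value=value,
                    value_before=before,
                    soil_total_hm=soil,
                    metal=metal,
                    censored_above=censored,
                )
            )
    return records


def make_study(
    spec: SyntheticStudySpec,
    registry: Mapping[str, IndicatorDefinition],
) -> str:
    """CSV text of the study's measurement table (canonical serialization)."""
    return measurements_to_csv(make_study_measurements(spec, registry))
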