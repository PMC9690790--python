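"""Analytic hierarchy process: judgment matrices, priority weights, consistency.

The AHP derives importance weights for a set of sibling elements from a
reciprocal pairwise-comparison (judgment) matrix on the Saaty 1-9 scale.
Weights are computed with the sum-product method: column-normalize the
matrix, sum rows, renormalize.  The quality of an expert's judgments is
measured by the consistency ratio CR = CI / RI with
CI = (lambda_max - n) / (n - 1); matrices with CR >= 0.1 are rejected.

Hierarchies (target -> criteria -> sub-criteria -> indicators) compose the
per-level local weights multiplicatively into one comprehensive weight per
leaf indicator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SAATY_VALUES",
    "RANDOM_CONSISTENCY_INDEX",
    "CR_THRESHOLD",
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyReport",
    "HierarchyNode",
    "validate_judgment_matrix",
    "column_normalize",
    "priority_vector",
    "lambda_max",
    "consistency",
    "aggregate_experts",
    "compose_weights",
]

#: Admissible entries of a strict Saaty-scale judgment matrix:
#: 1..9 and their reciprocals.
SAATY_VALUES: tuple[float, ...] = tuple(
    sorted({float(k) for k in range(1, 10)} | {1.0 / k for k in range(1, 10)})
)

#: Random consistency index RI by matrix order n (orders 1..9).
RANDOM_CONSISTENCY_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45,
}

#: Matrices with CR below this are considered acceptably consistent.
CR_THRESHOLD: float = 0.1

_RECIPROCITY_TOL = 1e-9
_SAATY_TOL = 1e-6


class JudgmentMatrixError(ValueError):
    """A pairwise-comparison matrix violates a structural invariant."""


@dataclass(frozen=True)
class JudgmentMatrix:
    """One expert's reciprocal pairwise-comparison matrix for a sibling set.

    Parameters
    ----------
    entries:
        Square array of positive importance ratios; ``entries[i, j]`` is how
        much more important element *i* is than element *j*.
    labels:
        Names of the compared elements, in row/column order.  Defaults to
        ``e1..en``.
    """

    entries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise JudgmentMatrixError(
                f"judgment matrix must be square, got shape {arr.shape}"
            )
        object.__setattr__(self, "entries", arr)
        labels = tuple(self.labels) or tuple(f"e{i + 1}" for i in range(arr.shape[0]))
        if len(labels) != arr.shape[0]:
            raise JudgmentMatrixError(
                f"{len(labels)} labels for a matrix of order {arr.shape[0]}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Normalized priority weights for a sibling set (sum to 1)."""

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)
        labels = tuple(self.labels) or tuple(f"e{i + 1}" for i in range(w.size))
        if len(labels) != w.size:
            raise ValueError("label count does not match weight count")
        object.__setattr__(self, "labels", labels)

    def as_dict(self) -> dict[str, float]:
        return {lab: float(x) for lab, x in zip(self.labels, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for a judgment matrix.

    ``cr`` is CI/RI; for orders 1 and 2 the random index is zero and a
    reciprocal matrix is always perfectly consistent, so CR is defined as 0.
    """

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool


def validate_judgment_matrix(
    m: JudgmentMatrix | np.ndarray | Sequence[Sequence[float]],
    strict: bool = False,
) -> JudgmentMatrix:
    """Check the structural invariants of a pairwise-comparison matrix.

    Verifies positivity, a unit diagonal and reciprocity
    (``b_ji == 1 / b_ij``); with ``strict=True`` every off-diagonal entry
    must additionally belong to the Saaty set {1/9..1/2, 1..9}, as required
    for questionnaire input.

    Returns the (wrapped) matrix unchanged; raises
    :class:`JudgmentMatrixError` naming the offending cell otherwise.
    """
    if not isinstance(m, JudgmentMatrix):
        m = JudgmentMatrix(np.asarray(m, dtype=float))
    a = m.entries
    n = m.n
    bad = np.argwhere(~(a > 0))
    if bad.size:
        i, j = bad[0]
        raise JudgmentMatrixError(
            f"entry ({i + 1},{j + 1}) = {a[i, j]!r} is not strictly positive"
        )
    for i in range(n):
        if abs(a[i, i] - 1.0) > _RECIPROCITY_TOL:
            raise JudgmentMatrixError(
                f"diagonal entry ({i + 1},{i + 1}) = {a[i, i]!r} must equal 1"
            )
    for i, j in itertools.combinations(range(n), 2):
        if abs(a[j, i] * a[i, j] - 1.0) > _RECIPROCITY_TOL:
            raise JudgmentMatrixError(
                f"reciprocity violated at ({j + 1},{i + 1}): "
                f"{a[j, i]!r} is not 1/{a[i, j]!r}"
            )
    if strict:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if min(abs(a[i, j] - s) for s in SAATY_VALUES) > _SAATY_TOL:
                    raise JudgmentMatrixError(
                        f"entry ({i + 1},{j + 1}) = {a[i, j]!r} is not on the "
                        "Saaty 1-9 scale"
                    )
    return m


def column_normalize(m: JudgmentMatrix) -> np.ndarray:
    """Divide every entry by its column sum, so each column sums to 1."""
    m = validate_judgment_matrix(m)
    return m.entries / m.entries.sum(axis=0, keepdims=True)


def priority_vector(m: JudgmentMatrix) -> WeightVector:
    """Sum-product priority weights of a judgment matrix.

    Row sums of the column-normalized matrix, renormalized to sum 1.  For a
    perfectly consistent matrix (``b_ij = w_i / w_j``) this recovers *w*
    exactly; otherwise it is a one-step approximation to the principal
    eigenvector.
    """
    m = validate_judgment_matrix(m)
    row = column_normalize(m).sum(axis=1)
    return WeightVector(row / row.sum(), m.labels)


def lambda_max(m: JudgmentMatrix, w: WeightVector | None = None) -> float:
    """Largest characteristic root, estimated as (1/n) sum_i (A w)_i / w_i."""
    m = validate_judgment_matrix(m)
    if w is None:
        w = priority_vector(m)
    wv = np.asarray(w.weights, dtype=float)
    zero = np.flatnonzero(wv <= 0)
    if zero.size:
        raise ZeroDivisionError(
            f"weight component {zero[0] + 1} is zero; lambda_max undefined"
        )
    return float(np.sum((m.entries @ wv) / wv) / m.n)


def consistency(m: JudgmentMatrix) -> ConsistencyReport:
    """Consistency test of a judgment matrix: CI, RI lookup, CR < 0.1.

    Supports orders 1..9 (the range the RI table covers); larger matrices
    raise ``ValueError`` rather than extrapolating the random index.
    """
    m = validate_judgment_matrix(m)
    n = m.n
    if n not in RANDOM_CONSISTENCY_INDEX:
        raise ValueError(
            f"no random consistency index for order {n}; supported orders are 1..9"
        )
    lm = lambda_max(m)
    ri = RANDOM_CONSISTENCY_INDEX[n]
    if n <= 2:
        # order-1 and order-2 reciprocal matrices are always consistent
        ci = 0.0
        cr = 0.0
    else:
        ci = (lm - n) / (n - 1)
        cr = ci / ri
    return ConsistencyReport(
        n=n, lambda_max=lm, ci=ci, ri=ri, cr=cr, passed=bool(cr < CR_THRESHOLD)
    )


def aggregate_experts(
    panel: Iterable[JudgmentMatrix | WeightVector],
    expert_weights: Sequence[float] | None = None,
    method: str = "vector_mean",
) -> tuple[WeightVector, list[int]]:
    """Aggregate an expert panel into one weight vector.

    Judgment matrices are first screened with the CR < 0.1 consistency test;
    failing experts are excluded and their (0-based) panel indices returned.
    The default ``vector_mean`` method averages the per-expert priority
    vectors arithmetically (optionally with per-expert weights) and
    renormalizes.  ``matrix_geometric`` instead aggregates the surviving
    matrices entrywise by the (weighted) geometric mean — which preserves
    reciprocity — and takes the priority vector of the aggregate.

    Returns ``(aggregate, excluded_indices)``; raises ``ValueError`` if no
    expert survives the consistency filter.
    """
    panel = list(panel)
    if expert_weights is not None and len(expert_weights) != len(panel):
        raise ValueError("one expert weight per panel member required")
    if method not in ("vector_mean", "matrix_geometric"):
        raise ValueError(f"unknown aggregation method {method!r}")

    kept: list[tuple[int, JudgmentMatrix | WeightVector]] = []
    excluded: list[int] = []
    labels: tuple[str, ...] = ()
    for idx, item in enumerate(panel):
        if isinstance(item, JudgmentMatrix):
            if consistency(item).passed:
                kept.append((idx, item))
            else:
                excluded.append(idx)
        else:
            kept.append((idx, item))
        if not labels:
            labels = item.labels
    if not kept:
        raise ValueError("no expert passed the CR < 0.1 consistency filter")
    sizes = {item.entries.shape[0] if isinstance(item, JudgmentMatrix) else item.weights.size
             for _, item in kept}
    if len(sizes) != 1:
        raise ValueError("panel members concern sibling sets of different sizes")

    ew = (np.asarray([expert_weights[i] for i, _ in kept], dtype=float)
          if expert_weights is not None else np.ones(len(kept)))
    if np.any(ew < 0) or ew.sum() <= 0:
        raise ValueError("expert weights must be nonnegative with positive sum")
    ew = ew / ew.sum()

    if method == "matrix_geometric":
        mats = []
        for _, item in kept:
            if not isinstance(item, JudgmentMatrix):
                raise ValueError("matrix_geometric aggregation requires matrices")
            mats.append(item.entries)
        logmean = np.tensordot(ew, np.log(np.stack(mats)), axes=1)
        agg = JudgmentMatrix(np.exp(logmean), labels)
        return priority_vector(agg), excluded

    vecs = np.stack([
        (priority_vector(item) if isinstance(item, JudgmentMatrix) else item).weights
        for _, item in kept
    ])
    mean = ew @ vecs
    return WeightVector(mean / mean.sum(), labels), excluded


# ---------------------------------------------------------------------------
# Evaluation hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HierarchyNode:
    """Node of the evaluation hierarchy (target/criterion/sub-criterion/indicator).

    ``local_weight`` is the node's priority among its siblings; leaves are
    indicator names.  The comprehensive weight of a leaf is the product of
    the local weights along its root path.
    """

    name: str
    local_weight: float = 1.0
    children: list["HierarchyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["HierarchyNode"]:
        if self.is_leaf:
            return [self]
        out: list[HierarchyNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def validate(self, tol: float = 1e-6) -> None:
        """Check that children's local weights sum to 1 at every node."""
        if self.is_leaf:
            return
        total = sum(c.local_weight for c in self.children)
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"local weights under {self.name!r} sum to {total:.6f}, not 1"
            )
        for c in self.children:
            if c.local_weight < 0:
                raise ValueError(f"negative local weight at {c.name!r}")
            c.validate(tol)

    @classmethod
    def from_dict(cls, d: Mapping) -> "HierarchyNode":
        """Build a hierarchy from ``{name, weight, children: [...]}`` mappings."""
        return cls(
            name=str(d["name"]),
            local_weight=float(d.get("weight", 1.0)),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "weight": self.local_weight}
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


def compose_weights(root: HierarchyNode, renormalize: bool = False) -> dict[str, float]:
    """Comprehensive weight of every leaf indicator.

    Each leaf's weight is the product of local weights along the path from
    the root; with valid local weights the leaf weights sum to 1 (the root's
    own local weight is ignored).  ``renormalize=True`` forces an exact unit
    sum, which irons out rounding in hierarchies transcribed from published
    tables.
    """
    root.validate()
    out: dict[str, float] = {}

    def walk(node: HierarchyNode, acc: float) -> None:
        if node.is_leaf:
            if node.name in out:
                raise ValueError(f"duplicate leaf indicator {node.name!r}")
            out[node.name] = acc
            return
        for c in node.children:
            walk(c, acc * c.local_weight)

    walk(root, 1.0)
    if renormalize:
        total = sum(out.values())
        out = {k: v / total for k, v in out.items()}
    return out
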