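"""Readers, writers and run configuration.

File conventions: CSV is comma-separated, dot-decimal, UTF-8.  Judgment
matrices travel as square CSV tables (first row/column are labels) or as
JSON ``{"labels": [...], "entries": [[...]]}``; hierarchies as YAML/JSON
``{name, weight, children: [...]}`` documents; measurements as CSV with the
columns ``indicator,treatment,value,value_before,soil_total_hm,metal``.

A measurement value may be written ``>x`` (e.g. an amendment stability of
``>3`` years) to mean "above the reported bound".

JSON reports are serialized with sorted keys and full float precision, so a
given evaluation always produces byte-identical output; display rounding
(two decimals for indicator scores, three for the composite) is applied
only in the Markdown rendering.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ahp import HierarchyNode, JudgmentMatrix, validate_judgment_matrix
from .evaluation import ComparisonVerdict, EvaluationResult
from .indicators import Measurement, MeasurementError

__all__ = [
    "RunConfig",
    "MEASUREMENT_COLUMNS",
    "read_judgment_matrix",
    "read_panel",
    "read_hierarchy",
    "write_hierarchy",
    "read_measurements",
    "write_measurements",
    "write_report",
    "render_markdown_report",
]

MEASUREMENT_COLUMNS = (
    "indicator", "treatment", "value", "value_before", "soil_total_hm", "metal",
)


@dataclass
class RunConfig:
    """Configuration of one evaluation run.

    Exactly one weight source is active: either the packaged hierarchy (or a
    user hierarchy file) or a directory/file of expert judgment matrices
    from which weights are computed.
    """

    registry_path: Optional[Path] = None
    hierarchy_path: Optional[Path] = None
    panel_path: Optional[Path] = None
    renormalize_missing: bool = False
    use_printed_weights: bool = True
    seed: Optional[int] = None
    display_decimals: int = 2

    def __post_init__(self) -> None:
        if self.hierarchy_path is not None and self.panel_path is not None:
            raise ValueError(
                "exactly one weight source: give a hierarchy or an expert panel, not both"
            )
        for p in (self.registry_path, self.hierarchy_path, self.panel_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                val = raw[f.name]
                if f.name.endswith("_path") and val is not None:
                    val = Path(val)
                kw[f.name] = val
        return cls(**kw)


# ---------------------------------------------------------------------------
# Judgment matrices
# ---------------------------------------------------------------------------

def _matrix_from_json(doc: Mapping) -> JudgmentMatrix:
    entries = np.asarray(doc["entries"], dtype=float)
    labels = tuple(doc.get("labels", ()))
    return JudgmentMatrix(entries, labels)


def read_judgment_matrix(path: str | Path, strict: bool = False) -> JudgmentMatrix:
    """Read one judgment matrix from CSV (labelled square table) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            m = _matrix_from_json(json.load(fh))
    else:
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(
                f"{path}: row labels {list(df.index)} differ from "
                f"column labels {list(df.columns)}"
            )
        m = JudgmentMatrix(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns))
    return validate_judgment_matrix(m, strict=strict)


def read_panel(path: str | Path, strict: bool = False) -> list[JudgmentMatrix]:
    """Read an expert panel: a directory of matrix files or one JSON array."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".csv", ".json")
        )
        if not files:
            raise FileNotFoundError(f"no .csv/.json matrices in {path}")
        return [read_judgment_matrix(p, strict=strict) for p in files]
    with open(path, encoding="utf-8") as fh:
        docs = json.load(fh)
    return [
        validate_judgment_matrix(_matrix_from_json(d), strict=strict) for d in docs
    ]


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def read_hierarchy(path: str | Path) -> HierarchyNode:
    """Read an evaluation hierarchy from a YAML or JSON document."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    node = HierarchyNode.from_dict(doc)
    node.validate()
    return node


def write_hierarchy(node: HierarchyNode, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(node.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def _parse_value(raw: str) -> tuple[float, bool]:
    raw = raw.strip()
    if raw.startswith(">"):
        return float(raw[1:]), True
    return float(raw), False


def read_measurements(
    path: str | Path,
    known_indicators: Optional[Sequence[str]] = None,
) -> list[Measurement]:
    """Parse a measurement CSV into validated records.

    Rejects malformed numerics, negative concentrations, duplicate
    (indicator, treatment) pairs and — when a registry's indicator names are
    supplied — unknown indicators, always naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MEASUREMENT_COLUMNS[:3] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    records: list[Measurement] = []
    seen: set[tuple[str, str]] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        name = rec["indicator"].strip()
        treatment = rec["treatment"].strip()
        if not name:
            continue
        if known_indicators is not None and name not in known_indicators:
            raise ValueError(f"{path}:{pos}: unknown indicator {name!r}")
        key = (name, treatment)
        if key in seen:
            raise ValueError(
                f"{path}:{pos}: duplicate measurement for {name!r}/{treatment!r}"
            )
        seen.add(key)
        try:
            value, censored = _parse_value(rec["value"])
            before = (
                float(rec["value_before"]) if rec.get("value_before", "").strip() else None
            )
            soil = (
                float(rec["soil_total_hm"]) if rec.get("soil_total_hm", "").strip() else None
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{pos}: malformed numeric value ({exc})") from None
        try:
            records.append(
                Measurement(
                    indicator=name,
                    treatment=treatment,
                    value=value,
                    value_before=before,
                    soil_total_hm=soil,
                    metal=rec.get("metal", "").strip() or None,
                    censored_above=censored,
                )
            )
        except MeasurementError as exc:
            raise ValueError(f"{path}:{pos}: {exc}") from None
    return records


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and math.isclose(v, round(v)) and abs(v) < 1e15:
        return str(int(round(v))) if float(int(round(v))) == v else f"{v:g}"
    return f"{v:g}"


def measurements_to_csv(records: Sequence[Measurement]) -> str:
    """Canonical CSV serialization of measurement records."""
    lines = [",".join(MEASUREMENT_COLUMNS)]
    for m in records:
        value = (">" if m.censored_above else "") + _fmt(m.value)
        lines.append(
            ",".join(
                [
                    m.indicator,
                    m.treatment,
                    value,
                    _fmt(m.value_before),
                    _fmt(m.soil_total_hm),
                    m.metal or "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_measurements(records: Sequence[Measurement], path: str | Path) -> None:
    Path(path).write_text(measurements_to_csv(records), encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _result_to_dict(r: EvaluationResult) -> dict:
    return {
        "treatment": r.treatment,
        "composite_score": r.composite,
        "grade": r.grade,
        "missing_indicators": list(r.missing_indicators),
        "compliance_violations": list(r.compliance_violations),
        "weights_renormalized": r.weights_renormalized,
        "indicator_scores": {
            k: {
                "raw_value": s.raw_value,
                "transformed_value": s.transformed_value,
                "score": s.score,
                "curve": s.curve,
                "compliant": s.compliant,
            }
            for k, s in sorted(r.scores.items())
        },
    }


def report_to_dict(
    after: EvaluationResult,
    before: Optional[EvaluationResult] = None,
    comparison: Optional[ComparisonVerdict] = None,
    assumptions: Optional[Mapping[str, object]] = None,
) -> dict:
    doc: dict = {"after": _result_to_dict(after)}
    if before is not None:
        doc["before"] = _result_to_dict(before)
    if comparison is not None:
        doc["verdict"] = {
            "grade_before": comparison.grade_before,
            "grade_after": comparison.grade_after,
            "grade_steps": comparison.grade_steps,
            "verdict": comparison.verdict,
        }
    if assumptions:
        doc["assumptions"] = dict(assumptions)
    return doc


def write_report(
    path: str | Path,
    after: EvaluationResult,
    before: Optional[EvaluationResult] = None,
    comparison: Optional[ComparisonVerdict] = None,
    assumptions: Optional[Mapping[str, object]] = None,
    markdown_path: Optional[str | Path] = None,
) -> dict:
    """Write the evaluation report as JSON (and optionally Markdown).

    Returns the report dictionary.  JSON keys are sorted and floats kept at
    full precision, so identical inputs give byte-identical files.
    """
    doc = report_to_dict(after, before, comparison, assumptions)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if markdown_path is not None:
        Path(markdown_path).write_text(
            render_markdown_report(doc), encoding="utf-8"
        )
    return doc


def render_markdown_report(doc: Mapping) -> str:
    """Human-readable report: scores to 2 decimals, composite to 3."""
    out: list[str] = ["# Stabilization-effect evaluation", ""]
    for key in ("before", "after"):
        if key not in doc:
            continue
        r = doc[key]
        out.append(f"## {key.capitalize()}: {r['treatment']}")
        out.append("")
        out.append("| indicator | value | transformed | score |")
        out.append("|---|---|---|---|")
        for name, s in r["indicator_scores"].items():
            out.append(
                f"| {name} | {s['raw_value']:g} | {s['transformed_value']:.4g} "
                f"| {s['score']:.2f} |"
            )
        out.append("")
        out.append(f"Composite score S = {r['composite_score']:.3f}, grade {r['grade']}.")
        if r["missing_indicators"]:
            out.append(f"Missing indicators: {', '.join(r['missing_indicators'])}.")
        if r["compliance_violations"]:
            out.append(
                "Group-I compliance violations: "
                + ", ".join(r["compliance_violations"]) + "."
            )
        out.append("")
    if "verdict" in doc:
        v = doc["verdict"]
        out.append(
            f"**Verdict:** grade {v['grade_before']} -> {v['grade_after']} "
            f"({v['grade_steps']:+d} steps): **{v['verdict']}**."
        )
        out.append("")
    if "assumptions" in doc:
        out.append("## Assumptions")
        for k, val in sorted(doc["assumptions"].items()):
            out.append(f"- {k}: {val}")
        out.append("")
    return "\n".join(out)
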