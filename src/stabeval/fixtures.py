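"""Packaged fixtures: indicator registry, weight hierarchy, pot-experiment data.

Three data files ship with the package:

* ``registry.yaml`` — the 16-indicator registry with response-curve
  thresholds (cadmium defaults for the heavy-metal indicators);
* ``hierarchy.json`` — the published evaluation hierarchy (soil 0.544,
  crop 0.316, amendment 0.140, with sub-criterion and indicator levels) and
  the published comprehensive weights verbatim;
* ``table10_measurements.csv`` — the pot-experiment measurement table
  (5 mg/kg Cd spike; control, reed-biochar and hydroxyapatite treatments).

The published comprehensive weights are questionnaire output, shipped as
data, never recomputed; they are available verbatim (they sum to 1.003 as
printed) or renormalized to exactly 1.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .ahp import HierarchyNode, compose_weights
from .indicators import IndicatorDefinition, Measurement
from .io import read_hierarchy, read_measurements
from .synthetic import SyntheticStudySpec

__all__ = [
    "data_path",
    "load_registry",
    "load_hierarchy",
    "paper_weights",
    "load_table10",
    "table10_study_spec",
    "FIXTURE_NAMES",
]

#: Names accepted by the CLI's fixture lookup.
FIXTURE_NAMES = {
    "paper/registry": "registry.yaml",
    "paper/table3": "hierarchy.json",
    "paper/table10": "table10_measurements.csv",
}

_DEF_FIELDS = {
    "group", "curve", "transform", "units", "L", "H", "L1", "H1",
    "reference_value", "compliance_limit", "assumption",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (or a fixture alias)."""
    name = FIXTURE_NAMES.get(name, name)
    with resources.as_file(resources.files("stabeval").joinpath("data", name)) as p:
        return Path(p)


def load_registry(
    path: Optional[str | Path] = None,
    overrides: Optional[Mapping[str, Mapping]] = None,
    metal: Optional[str] = "Cd",
) -> dict[str, IndicatorDefinition]:
    """Load the indicator registry, applying per-metal and user overrides.

    ``overrides`` merges by indicator name on top of the file's entries
    (e.g. to supply the mandatory local production/biomass references or
    thresholds for a metal other than cadmium).
    """
    path = Path(path) if path is not None else data_path("registry.yaml")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    registry: dict[str, IndicatorDefinition] = {}
    for name, raw in doc["indicators"].items():
        raw = dict(raw)
        by_metal = raw.pop("by_metal", {})
        if metal and metal in by_metal:
            raw.update(by_metal[metal])
        if overrides and name in overrides:
            raw.update(overrides[name])
        unknown = set(raw) - _DEF_FIELDS
        if unknown:
            raise ValueError(f"{name}: unknown registry fields {sorted(unknown)}")
        registry[name] = IndicatorDefinition(name=name, **raw)
    return registry


def load_hierarchy(path: Optional[str | Path] = None) -> HierarchyNode:
    """The packaged evaluation hierarchy (or one read from *path*)."""
    return read_hierarchy(path if path is not None else data_path("hierarchy.json"))


def paper_weights(variant: str = "printed") -> dict[str, float]:
    """Published comprehensive indicator weights.

    ``printed`` returns the table values verbatim (they sum to 1.003 due to
    rounding in the source); ``renormalized`` scales them to sum exactly 1;
    ``composed`` multiplies the hierarchy's local weights down each path,
    which also sums to 1 but can differ from the printed numbers by up to
    about 0.006 (printed-table rounding).
    """
    import json

    if variant in ("printed", "renormalized"):
        with open(data_path("hierarchy.json"), encoding="utf-8") as fh:
            doc = json.load(fh)
        out: dict[str, float] = {}

        def walk(d: Mapping) -> None:
            if "printed_comprehensive" in d:
                out[d["name"]] = float(d["printed_comprehensive"])
            for c in d.get("children", []):
                walk(c)

        walk(doc)
        if variant == "renormalized":
            total = sum(out.values())
            out = {k: v / total for k, v in out.items()}
        return out
    if variant == "composed":
        return compose_weights(load_hierarchy(), renormalize=True)
    raise ValueError(
        f"unknown weight variant {variant!r}; use printed, renormalized or composed"
    )


def load_table10(path: Optional[str | Path] = None) -> list[Measurement]:
    """The pot-experiment measurement records (34 rows, 3 treatments)."""
    registry = load_registry()
    return read_measurements(
        path if path is not None else data_path("table10_measurements.csv"),
        known_indicators=tuple(registry),
    )


def table10_study_spec() -> SyntheticStudySpec:
    """Study spec whose generated CSV reproduces the packaged table exactly.

    The 5.0 mg/kg soil total (the Cd spike, excluding the 0.18 mg/kg
    background) and the 1.27 g biomass reference in the registry are
    back-computed assumptions consistent with the published scores.
    """
    control = {
        "pH": 7.27, "SOM": 18.21, "CEC": 13.4, "A-N": 29.40, "A-P": 75.39,
        "A-K": 40.56, "AHM": 2.85, "biomass": 1.16,
        "hm_above_ground": 0.60, "hm_roots": 2.30,
    }
    rbc = {
        "pH": 7.22, "SOM": 21.86, "CEC": 13.4, "A-N": 33.92, "A-P": 79.01,
        "A-K": 47.78, "AHM": 2.14, "biomass": 1.26,
        "hm_above_ground": 0.40, "hm_roots": 1.95,
        "hm_amendment": 0.0, "stability": ">3",
    }
    hap = {
        "pH": 7.11, "SOM": 19.37, "CEC": 12.1, "A-N": 25.66, "A-P": 47.31,
        "A-K": 127.81, "AHM": 1.50, "biomass": 1.66,
        "hm_above_ground": 0.35, "hm_roots": 1.80,
        "hm_amendment": 0.0, "stability": ">3",
    }
    return SyntheticStudySpec(
        treatments={"control": control, "RBC": rbc, "HAP": hap},
        control="control",
        soil_total_hm=5.0,
        metal="Cd",
        seed=0,
    )
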