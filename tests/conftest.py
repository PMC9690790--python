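import numpy as np
import pytest

from stabeval import load_registry, load_table10, paper_weights


def eigen_priority(entries: np.ndarray) -> np.ndarray:
    """Independent oracle: principal eigenvector of a positive reciprocal
    matrix, normalized to sum 1 (dense eigen-decomposition)."""
    vals, vecs = np.linalg.eig(entries)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return v / v.sum()


def eigen_lambda_max(entries: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(entries).real))


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def printed_weights():
    return paper_weights("printed")


@pytest.fixture(scope="session")
def table10():
    return load_table10()


#: Published per-indicator scores of the pot experiment (34 cells), keyed by
#: (indicator, treatment); two-decimal values as printed.
TABLE10_PRINTED_SCORES = {
    ("pH", "control"): 0.87, ("SOM", "control"): 0.36, ("CEC", "control"): 0.34,
    ("A-N", "control"): 0.0, ("A-P", "control"): 1.0, ("A-K", "control"): 0.06,
    ("AHM", "control"): 0.0, ("biomass", "control"): 0.91,
    ("hm_above_ground", "control"): 0.98, ("hm_roots", "control"): 0.60,
    ("pH", "RBC"): 0.89, ("SOM", "RBC"): 0.47, ("CEC", "RBC"): 0.34,
    ("A-N", "RBC"): 0.03, ("A-P", "RBC"): 1.0, ("A-K", "RBC"): 0.10,
    ("AHM", "RBC"): 0.33, ("biomass", "RBC"): 0.99,
    ("hm_above_ground", "RBC"): 1.0, ("hm_roots", "RBC"): 0.68,
    ("hm_amendment", "RBC"): 1.0, ("stability", "RBC"): 1.0,
    ("pH", "HAP"): 0.95, ("SOM", "HAP"): 0.39, ("CEC", "HAP"): 0.21,
    ("A-N", "HAP"): 0.0, ("A-P", "HAP"): 1.0, ("A-K", "HAP"): 0.58,
    ("AHM", "HAP"): 0.63, ("biomass", "HAP"): 1.0,
    ("hm_above_ground", "HAP"): 1.0, ("hm_roots", "HAP"): 0.71,
    ("hm_amendment", "HAP"): 1.0, ("stability", "HAP"): 1.0,
}

#: Published composite scores and grades.
TABLE10_PRINTED_COMPOSITE = {"control": 0.165, "RBC": 0.371, "HAP": 0.471}
TABLE10_GRADES = {"control": "V", "RBC": "IV", "HAP": "III"}

#: Published comprehensive indicator weights (sum to 1.003 as printed).
TABLE3_PRINTED_WEIGHTS = {
    "pH": 0.052, "SOM": 0.021, "CEC": 0.017, "A-N": 0.021, "A-P": 0.022,
    "A-K": 0.022, "AHM": 0.300, "THM": 0.091, "biomass": 0.025,
    "production": 0.060, "hm_edible": 0.150, "hm_above_ground": 0.028,
    "hm_roots": 0.054, "cost": 0.042, "hm_amendment": 0.045,
    "stability": 0.053,
}
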