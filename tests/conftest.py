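import numpy as np
import pandas as pd
import pytest

from panelcover.cohort import (
    Cohort,
    CoreScore,
    MarkerAssay,
    MarkerInfo,
    TumorRecord,
    default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_record(pid, markers=None, registry=None, **kwargs):
    """A valid tumor record; ``markers`` maps marker_id -> list of core values
    (ints for DAKO, floats for percent when the rule is percent_cells, None for
    missing)."""
    defaults = dict(
        age=55.0,
        histology="ductal",
        grade=2,
        size_class="<=2cm",
        node_status="negative",
        er_positive=False,
        pr_positive=False,
    )
    defaults.update(kwargs)
    rec = TumorRecord(patient_id=pid, **defaults)
    registry = registry or default_registry()
    for mid, values in (markers or {}).items():
        percent = registry[mid].positivity_rule == "percent_cells"
        cores = tuple(
            CoreScore.missing()
            if v is None
            else (CoreScore(percent=float(v)) if percent else CoreScore(dako=int(v)))
            for v in values
        )
        rec.assays[mid] = MarkerAssay(mid, cores)
    return rec


@pytest.fixture
def toy_cohort(registry):
    """Three-patient cohort exercising positive, negative and missing assays."""
    records = [
        make_record("T1", {"GLUT1": [3, 3, 3], "HER2": [3, 3, 3], "MUC1": [2, 2, 2]}),
        make_record("T2", {"GLUT1": [0, 0, 0], "HER2": [2, 2, 2], "MUC1": [1, 0, 1]},
                    er_positive=True, histology="lobular_classical", grade=None),
        make_record("T3", {"GLUT1": [None, None, None], "HER2": [0, 1, 0],
                           "Mammaglobin": [40.0, 50.0, 60.0]},
                    node_status=None, size_class=None, age=72.0),
    ]
    return Cohort(records, registry)


@pytest.fixture
def toy_calls():
    """4 tumors with positivity sets {A}, {B}, {}, {A, B}."""
    return pd.DataFrame(
        {"A": [True, False, False, True], "B": [False, True, False, True]},
        index=pd.Index(["t1", "t2", "t3", "t4"], name="patient_id"),
    )


def random_calls(rng, n_tumors, markers, p=None):
    """Random boolean calls matrix for property tests."""
    if p is None:
        p = rng.uniform(0.05, 0.6, size=len(markers))
    data = {m: rng.random(n_tumors) < p[j] for j, m in enumerate(markers)}
    return pd.DataFrame(data, index=[f"p{i}" for i in range(n_tumors)])
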