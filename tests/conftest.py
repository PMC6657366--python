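import numpy as np
import pandas as pd
import pytest

from cytoms.cohort import BASE_COLUMNS, CORE_CYTOKINES
from cytoms.synthetic import CohortSpec, CytokineEffectSpec, generate_cohort


def make_specs(effect_size: float = 0.8, family: str = "lognormal",
               control_sd: float = 1.0):
    """A simple 8-analyte panel with a uniform shift, for unit tests."""
    return [
        CytokineEffectSpec(cytokine_name=name, control_mean=5.0,
                           control_sd=control_sd, ms_shift=effect_size,
                           distribution_family=family)
        for name in CORE_CYTOKINES
    ]


@pytest.fixture
def small_cohort():
    """A 60 MS / 40 control cohort with a clear group separation."""
    spec = CohortSpec(cohort_label="unit", n_ms=60, n_control=40,
                      cytokine_specs=make_specs(effect_size=2.0), seed=11)
    return generate_cohort(spec)


@pytest.fixture
def separable_table():
    """Two well-separated Gaussian blobs, linearly separable by a wide
    margin (verified in the model tests by a nearest-centroid check)."""
    rng = np.random.default_rng(42)
    n = 100
    rows = []
    for status, centre in (("MS", 10.0), ("control", 0.0)):
        X = rng.normal(centre, 0.5, size=(n, len(CORE_CYTOKINES)))
        X = np.abs(X) if centre == 0 else X  # keep concentrations >= 0
        for i in range(n):
            row = {
                "subject_id": f"sep-{status}-{i}",
                "cohort": "sep",
                "status": status,
                "course": "relapsing_remitting" if status == "MS" else "none",
                "age": 40.0 + rng.normal(0, 5),
                "gender": "F" if rng.random() < 0.5 else "M",
                "duration": 3.0, "edss": 2.0, "msss": 4.0, "treatment": 0,
            }
            row.update(dict(zip(CORE_CYTOKINES, X[i])))
            rows.append(row)
    return pd.DataFrame(rows, columns=BASE_COLUMNS + CORE_CYTOKINES)
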