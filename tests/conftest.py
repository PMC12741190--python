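import warnings

import numpy as np
import pandas as pd
import pytest

from lifespanomics import total_sum_normalize
from lifespanomics.core_tables import FeatureTable, SampleMeta
from lifespanomics.synthetic import (
    CohortConfig,
    TrajectorySpec,
    default_specs,
    simulate_cohort,
    simulate_lipid_panel,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort():
    """Study-scale synthetic cohort: 136 subjects, mixed trajectory kinds."""
    cfg = CohortConfig(seed=11)
    table, meta, truth = simulate_cohort(cfg, default_specs())
    return table, meta, truth


@pytest.fixture(scope="session")
def cohort_normalized(cohort):
    table, meta, truth = cohort
    return total_sum_normalize(table), meta, truth


@pytest.fixture(scope="session")
def lipid_panel():
    """Lipid panel with saturated-SPH newborn markers, matched subjects."""
    cfg = CohortConfig(seed=11)
    table, meta, truth = simulate_lipid_panel(cfg)
    return table, meta, truth


@pytest.fixture(scope="session")
def null_cohort():
    """1000 pure-noise features, n = 136, no zero inflation (calibration)."""
    cfg = CohortConfig(seed=29, zero_inflation=0.0)
    table, meta, truth = simulate_cohort(cfg, [TrajectorySpec("null", n_features=1000)])
    return table, meta, truth


@pytest.fixture()
def tiny_table():
    """3-feature x 4-sample handmade table with matching metadata."""
    data = pd.DataFrame(
        [[2.0, 4.0, 1.0, 3.0], [3.0, 6.0, 2.0, 1.0], [5.0, 10.0, 7.0, 6.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "age": [0.0, 3.0, 30.0, 70.0],
            "sex": ["F", "M", "F", "M"],
            "group": ["A_newborn", "B_early_childhood", "E_early_adulthood",
                      "G_late_adulthood"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data), SampleMeta(meta)
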