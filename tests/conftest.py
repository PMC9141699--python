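import numpy as np
import pytest

from gsprog.io import ExpressionMatrix, SurvivalTable, Transform, log_standardize
from gsprog.simulate import CohortSpec, PlantedSet, simulate_cohort

import pandas as pd


@pytest.fixture
def toy_surv():
    """Six patients, distinct times 1..6, all events observed."""
    return SurvivalTable(
        tuple(f"S{i}" for i in range(1, 7)),
        np.arange(1.0, 7.0),
        np.ones(6, dtype=int),
    )


@pytest.fixture
def small_cohort():
    """80-patient cohort with one planted 5-gene set (log-hazard 0.7/SD)."""
    spec = CohortSpec(
        n_patients=80, n_genes=40, seed=424242,
        planted_sets=(PlantedSet(5, 0.7),), censor_rate=0.3,
    )
    expr, surv, collection, truth = simulate_cohort(spec)
    return log_standardize(expr), surv, collection, truth


def make_matrix(values, transform=Transform.LOG_STANDARDIZED, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), transform)
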