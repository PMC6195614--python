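import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bh3rank.priming import FluorescencePlate

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def make_plate(sample_conditions: dict[str, dict[str, list[float]]]) -> FluorescencePlate:
    """Build a plate from {sample: {condition: [replicate rfus]}}."""
    rows = []
    for sid, conds in sample_conditions.items():
        for cond, rfus in conds.items():
            for rep, rfu in enumerate(rfus, start=1):
                rows.append((sid, cond, rep, float(rfu)))
    return FluorescencePlate(
        wells=pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "rfu"])
    )


@pytest.fixture
def simple_plate():
    """One sample, controls 1000/200, one drug at the midpoint (priming 50%)."""
    return make_plate(
        {"T01": {"DMSO": [1000, 1000, 1000], "FCCP": [200, 200, 200],
                 "drugA": [600, 600, 600]}}
    )


@pytest.fixture
def noiseless_cohort():
    from bh3rank.cohort import CohortParams, generate_cohort

    params = CohortParams(
        n_tumors=12, n_normals=2, ct_noise_sd=0.0, priming_noise_sd=0.0,
        rfu_noise_cv=0.0, seed=7,
    )
    return generate_cohort(params)


@pytest.fixture
def small_cohort():
    from bh3rank.cohort import CohortParams, generate_cohort

    return generate_cohort(CohortParams(seed=11))


def random_priming(rng: np.random.Generator, n_tumors: int = 31, n_drugs: int = 5) -> pd.DataFrame:
    return pd.DataFrame(
        rng.uniform(0, 100, size=(n_tumors, n_drugs)),
        index=[f"T{i:02d}" for i in range(n_tumors)],
        columns=[f"drug{j}" for j in range(n_drugs)],
    )
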