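import numpy as np
import pandas as pd
import pytest

from pcuste import (
    CohortSchema,
    CohortTable,
    GeneratorConfig,
    apply_standardization,
    fit_standardization,
    generate_cohort,
    split_cohort,
)


@pytest.fixture(scope="session")
def toy_schema():
    return CohortSchema(
        outcome="outcome",
        covariates=("a", "b"),
        predictors=("x1", "x2"),
    )


def make_toy(n_cases_a=3, n_cases_b=1, n_ctrl_a=10, n_ctrl_b=5, seed=0) -> CohortTable:
    """Two strata defined by covariate 'a' (b fixed 0); deterministic predictors."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for a, n, y in [(1, n_cases_a, 1), (0, n_cases_b, 1), (1, n_ctrl_a, 0), (0, n_ctrl_b, 0)]:
        for _ in range(n):
            rows.append(
                {
                    "participant_id": pid,
                    "outcome": y,
                    "a": a,
                    "b": 0,
                    "x1": rng.normal(y, 1),
                    "x2": rng.normal(0, 1),
                }
            )
            pid += 1
    return CohortTable(
        pd.DataFrame(rows),
        CohortSchema(covariates=("a", "b"), predictors=("x1", "x2")),
    )


@pytest.fixture
def toy_cohort():
    return make_toy()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """A 3,000-row cohort from the reference-calibrated generator."""
    cfg = GeneratorConfig.from_reference(n=3000, seed=11, incidence=0.05)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def std_split(synthetic_cohort):
    """Control-standardized 70/30 split of the synthetic cohort."""
    split = split_cohort(synthetic_cohort, 0.7, seed=3, stratified=True)
    params = fit_standardization(split.train)
    return apply_standardization(split.train, params), apply_standardization(split.test, params)
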