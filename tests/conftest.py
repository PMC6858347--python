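import warnings

import numpy as np
import pytest

from cistrans.pipeline import RunConfig, analyze_study
from cistrans.simulation import generate_synthetic_study


@pytest.fixture(scope="session")
def study():
    """Default planted synthetic study (seed 1)."""
    return generate_synthetic_study(seed=1)


@pytest.fixture(scope="session")
def study_result(study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_study(study.expr, study.alterations, RunConfig())


@pytest.fixture(scope="session")
def twenty_cohorts():
    """Twenty seeded replicate studies with their analysis results.

    Shared between the parameter-recovery and recurrence-comparison tests.
    """
    cohorts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(20):
            s = generate_synthetic_study(seed=seed)
            cohorts.append((s, analyze_study(s.expr, s.alterations, RunConfig())))
    return cohorts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
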