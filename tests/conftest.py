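import numpy as np
import pytest

import lapsecast as lc


@pytest.fixture(scope="session")
def small_cohort():
    """20 heterogeneous participants, 45-day studies (shared across tests)."""
    cohort, truth = lc.generate_cohort(
        lc.GeneratorConfig(n_participants=20, study_length=45, heterogeneity=1.5),
        seed=11,
    )
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort (148 x 90) for calibration checks."""
    return lc.generate_cohort(lc.GeneratorConfig(), seed=5)


def random_params(rng, k=2, n=10):
    """Random stable canonical parameters for filter tests."""
    b = np.sort(rng.uniform(-0.8, 0.9, size=k))[::-1]
    params = lc.SsmParams(
        A=rng.normal(0, 0.3, size=(n, k)),
        c=rng.normal(0.5, 0.2, size=n),
        r=rng.uniform(0.02, 0.3, size=n),
        b=b,
    )
    return params.canonicalize()
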