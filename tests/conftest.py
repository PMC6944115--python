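import numpy as np
import pytest

from gliostrat import synthetic


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across tests (seed fixed)."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def truth_groups(cohort):
    hi = set(cohort.truth["hi_samples"])
    return {s: ("hi" if s in hi else "lo") for s in cohort.truth["sample_ids"]}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
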