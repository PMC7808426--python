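import numpy as np
import pytest

from gutlink.synthetic import CohortConfig, generate_cohort, generate_variant_stream


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def labeled_stream():
    return generate_variant_stream(40, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
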