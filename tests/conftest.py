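import warnings

import numpy as np
import pytest

from ltc_subtyper.cohort import build_cohort
from ltc_subtyper.diseases import generator_disease_map
from ltc_subtyper.synthetic import default_params, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_params():
    return default_params(n_participants=400, seed=3)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    cohort, tally, rejects = build_cohort(
        small_bundle.claims,
        small_bundle.certifications,
        small_bundle.registry,
        generator_disease_map(),
    )
    return cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
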