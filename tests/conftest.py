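import numpy as np
import pytest

from glycoshock import (
    CohortSpec,
    EffectSpec,
    default_catalog,
    generate_cohort,
    generate_glycome_profiles,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def profiles(cohort, catalog):
    prof, manifest = generate_glycome_profiles(cohort, catalog, EffectSpec(), seed=2)
    return prof, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
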