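import pytest

from ploidyflow import AcquisitionConfig, SpeciesTruth
from ploidyflow.datasets import (
    load_endopolyploidy_individuals,
    load_endopolyploidy_populations,
    load_karyology,
)

#: Table-style C-level composition of a leaf with four endocycles
CAAMANOI_FRACTIONS = {
    "2C": 0.2261,
    "4C": 0.2559,
    "8C": 0.1096,
    "16C": 0.1279,
    "32C": 0.2368,
    "64C": 0.0437,
}


@pytest.fixture(scope="session")
def karyology():
    return load_karyology()


@pytest.fixture(scope="session")
def endo_populations():
    return load_endopolyploidy_populations()


@pytest.fixture(scope="session")
def endo_individuals():
    return load_endopolyploidy_individuals()


@pytest.fixture
def caamanoi_truth():
    return SpeciesTruth("E. caamanoi", 1.95, CAAMANOI_FRACTIONS)


@pytest.fixture
def default_config():
    return AcquisitionConfig(rng_seed=1234)
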