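import numpy as np
import pytest

from kdrfit.datasets import genotype_count_rows

# (site, year, phenotype, locus) -> published mutant allele frequency (4 dp)
PRINTED_FREQUENCIES = {
    ("Gangodawila", 2017, "Permethrin resistant", "F1534C"): 0.7000,
    ("Gangodawila", 2017, "Permethrin resistant", "V1016G"): 0.3600,
    ("Gangodawila", 2020, "Permethrin resistant", "F1534C"): 0.7586,
    ("Gangodawila", 2020, "Permethrin resistant", "V1016G"): 0.1667,
    ("Gangodawila", 2017, "Deltamethrin resistant", "F1534C"): 0.7000,
    ("Gangodawila", 2017, "Deltamethrin resistant", "V1016G"): 0.1800,
    ("Gangodawila", 2020, "Deltamethrin resistant", "F1534C"): 0.9167,
    ("Gangodawila", 2020, "Deltamethrin resistant", "V1016G"): 0.4048,
    ("Udahamulla", 2017, "Permethrin resistant", "F1534C"): 0.7778,
    ("Udahamulla", 2017, "Permethrin resistant", "V1016G"): 0.3519,
    ("Udahamulla", 2020, "Permethrin resistant", "F1534C"): 0.6875,
    ("Udahamulla", 2020, "Permethrin resistant", "V1016G"): 0.5536,
    ("Udahamulla", 2017, "Deltamethrin resistant", "F1534C"): 0.5469,
    ("Udahamulla", 2017, "Deltamethrin resistant", "V1016G"): 0.5435,
    ("Udahamulla", 2020, "Deltamethrin resistant", "F1534C"): 0.5357,
    ("Udahamulla", 2020, "Deltamethrin resistant", "V1016G"): 0.5000,
    ("Delkanda", 2017, "Permethrin resistant", "F1534C"): 0.8000,
    ("Delkanda", 2017, "Permethrin resistant", "V1016G"): 0.2292,
    ("Delkanda", 2020, "Permethrin resistant", "F1534C"): 0.8333,
    ("Delkanda", 2020, "Permethrin resistant", "V1016G"): 0.4375,
    ("Delkanda", 2017, "Deltamethrin resistant", "F1534C"): 0.6765,
    ("Delkanda", 2017, "Deltamethrin resistant", "V1016G"): 0.3636,
    ("Delkanda", 2020, "Deltamethrin resistant", "F1534C"): 0.7917,
    ("Delkanda", 2020, "Deltamethrin resistant", "V1016G"): 0.2692,
}


@pytest.fixture(scope="session")
def study_rows():
    """The in-package genotype-count table as (population, counts) pairs."""
    return genotype_count_rows()


@pytest.fixture(scope="session")
def printed_frequencies():
    return PRINTED_FREQUENCIES


@pytest.fixture
def rng():
    return np.random.default_rng(20240112)
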