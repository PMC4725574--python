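import numpy as np
import pytest

from karyocnv.synthetic_array import (
    default_marker_map,
    population_allele_freq,
    simulate_marker_map,
)


@pytest.fixture(scope="session")
def small_map():
    """Reduced-density map: ~100 markers per autosome."""
    return simulate_marker_map(2200, 100, 20, seed=1)


@pytest.fixture(scope="session")
def small_paf(small_map):
    return population_allele_freq(small_map)


@pytest.fixture(scope="session")
def dense_map():
    """Cohort-scale map: ~1000 markers per autosome."""
    return default_marker_map(seed=1)


@pytest.fixture(scope="session")
def dense_paf(dense_map):
    return population_allele_freq(dense_map)
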