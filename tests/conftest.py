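import numpy as np
import pytest

from fpcn_dynamics import (
    CohortSpec,
    build_design,
    default_block_spec,
    default_truth,
    define_contrasts,
)
from fpcn_dynamics.ppi import ppi_contrasts


@pytest.fixture(scope="session")
def design():
    """A balanced 3-cycle blocked design on a TR=2 s grid."""
    spec_map, total_s = default_block_spec()
    return build_design(spec_map, repetition_time=2.0, n_scans=int(total_s / 2.0))


@pytest.fixture(scope="session")
def contrasts():
    return define_contrasts()


@pytest.fixture(scope="session")
def ppi_c():
    """PPI-estimable contrast subset (single stimulus-domain row)."""
    return ppi_contrasts()


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort_spec(design):
    return CohortSpec(n_subjects=3, n_timepoints=design.n_scans, hrf_enabled=False,
                      noise_sd=0.2)
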