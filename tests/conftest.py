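import numpy as np
import pytest

from nirsimpair.core import build_probe_layout
from nirsimpair.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def layout():
    return build_probe_layout()


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_participants=6, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Six participants, full-length scans: shared across I/O and label tests."""
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def fast_spec():
    """Short scans (150 s, two usable 2-back blocks) for cheap pipeline tests."""
    return CohortSpec(n_participants=6, seed=7, scan_duration_s=150.0,
                      n_blocks=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
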