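import numpy as np
import pytest

from enamelmetrics import PhantomSpec, generate_phantom, packaged_cohort


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A crisp mid-range phantom: EA 15 deg, DA 7 deg, EDMR 140/120."""
    return generate_phantom(PhantomSpec(ea_true_deg=15.0, da_true_deg=7.0))


@pytest.fixture(scope="session")
def cohort_records():
    """Packaged digitization of the published variant tables."""
    return packaged_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
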