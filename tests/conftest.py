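import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pepsieve as ps

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def column():
    return ps.SUPERDEX_PEPTIDE


@pytest.fixture(scope="session")
def mem1k():
    return ps.RC_MEMBRANE_1K


@pytest.fixture(scope="session")
def mem3k():
    return ps.RC_MEMBRANE_3K


@pytest.fixture(scope="session")
def mid_dh_chromatogram():
    """Noiseless mid-hydrolysis fixture spanning the sieving transition."""
    chrom, truth = ps.generate_hydrolysate(ps.preset("10dh", seed=7))
    return chrom, truth


@pytest.fixture(scope="session")
def low_dh_fixture():
    """Noiseless low-hydrolysis fixture: almost all mass above the target."""
    chrom, truth = ps.generate_hydrolysate(ps.preset("3dh-col", seed=11))
    return chrom, truth


@pytest.fixture()
def two_species_profile():
    """Equal masses at 500 and 2000 g/mol on a uniform two-point grid."""
    return ps.HydrolysateProfile(
        time=np.array([0.0, 1.0]),
        mw=np.array([2000.0, 500.0]),
        concentration=np.array([1.0, 1.0]),
    )
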