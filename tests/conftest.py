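import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20250314)


@pytest.fixture(scope="session")
def tables():
    from antioxdft.fixtures import paper_fixtures
    return paper_fixtures()


@pytest.fixture(scope="session")
def hh_diatomic():
    """Symmetric H-H promolecular field, separation 3 Bohr."""
    from antioxdft.fixtures import make_diatomic_density
    return make_diatomic_density(("H", "H"), separation=3.0)


@pytest.fixture(scope="session")
def hh_grid(hh_diatomic):
    """The symmetric diatomic sampled on a modest lattice."""
    import numpy as np
    return hh_diatomic.density.sample(
        origin=[-3.0, -3.0, -4.0], axes=np.eye(3) * 0.25, counts=(25, 25, 33)
    )
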