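import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import nanopmf as npf
from nanopmf import fixtures


@pytest.fixture(scope="session")
def lattice_toy():
    return fixtures.make_fixture("lattice_toy")["toy"]


@pytest.fixture(scope="session")
def salt_2to2_pair_spec():
    """Two -24e nanospheres in 0.01 M 2:2 salt (the small ~70-ion system)."""
    cat, an = npf.symmetric_salt(2, 0.01)
    return npf.SystemSpec(
        nanoparticles=npf.build_geometry(2, 25.0, charge=-24.0),
        cation=cat, anion=an)


def synthetic_trajectory(positions, valences, cell_edge, radii=None):
    """Single-frame trajectory from hand-placed ion positions."""
    from nanopmf.results import Trajectory

    positions = np.asarray(positions, dtype=float)[None, :, :]
    valences = np.asarray(valences, dtype=float)
    if radii is None:
        radii = np.full(valences.shape, 2.0)
    return Trajectory(positions=positions, valences=valences,
                      radii=np.asarray(radii, dtype=float),
                      cell_lengths=np.full(3, float(cell_edge)), stride=1)
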