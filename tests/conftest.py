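import numpy as np
import pytest

from fungiglobin import simulate
from fungiglobin.templates import GLB2, GLB3F, GLB3S


@pytest.fixture(scope="session")
def glb3f():
    return GLB3F


@pytest.fixture(scope="session")
def glb3s():
    return GLB3S


@pytest.fixture(scope="session")
def glb2():
    return GLB2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_proteome():
    """Four genomes carrying every architecture class (probability 1)."""
    profile = simulate.TaxonProfile(
        "testtax",
        ("Ascomycota", "Pezizomycotina", "Sordariomycetes"),
        {label: 1.0 for label in ("FHb", "FHb_incomplete", "Sgb", "T1")},
    )
    return simulate.build_proteome(profile, n_genomes=4, seed=99, identity_range=(0.65, 0.8))
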