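import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nepre import FixtureSpec, make_chain, make_corpus

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def helix_chain():
    """10-residue mixed-composition alpha helix."""
    return make_chain(
        FixtureSpec(seed=101, n_residues=10, geometry="ideal_helix",
                    composition={"ALA": 2, "GLY": 1, "LEU": 1, "CYS": 1})
    )


@pytest.fixture(scope="session")
def coil_chain():
    """8-residue random coil, mixed composition."""
    return make_chain(
        FixtureSpec(seed=202, n_residues=8, geometry="random_coil",
                    composition={"ALA": 1, "GLY": 1, "TRP": 1, "SER": 1})
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Six 8-residue coil chains, mixed composition: a tiny training corpus."""
    return make_corpus(
        FixtureSpec(seed=303, n_residues=8, geometry="random_coil",
                    composition={"ALA": 2, "GLY": 1, "LEU": 1, "VAL": 1}),
        n_chains=6,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
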