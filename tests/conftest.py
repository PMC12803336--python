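import numpy as np
import pytest

from ppiscore.synthetic import SyntheticSpec, make_decoy_set, make_toy_dimer


@pytest.fixture(scope="session")
def planar_dimer():
    """Toy dimer with a flat, plane-separable interface."""
    return make_toy_dimer(SyntheticSpec(seed=11, intertwine=0.0))


@pytest.fixture(scope="session")
def mixed_dimer():
    """Toy dimer with a moderately intertwined interface."""
    return make_toy_dimer(SyntheticSpec(seed=11, intertwine=0.3))


@pytest.fixture(scope="session")
def interdigitated_dimer():
    """Toy dimer whose chains fully interdigitate."""
    return make_toy_dimer(SyntheticSpec(seed=11, intertwine=1.0))


@pytest.fixture(scope="session")
def decoy_ensemble(mixed_dimer):
    """Small decoy ensemble spanning DockQ, with its DockQ table."""
    return make_decoy_set(mixed_dimer, n_models=80, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
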