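import numpy as np
import pytest

from stwintron import PlantSpec, make_gene, make_stwintron, preset_model


@pytest.fixture(scope="session")
def model_a():
    return preset_model("A")


@pytest.fixture(scope="session")
def model_b():
    return preset_model("B")


@pytest.fixture(scope="session")
def model_d():
    return preset_model("D")


@pytest.fixture(scope="session")
def planted_a():
    """One clean Model-A stwintron with its annotation (seeded)."""
    spec = PlantSpec.random("A", seed=11)
    return make_stwintron(spec, seed=12)


@pytest.fixture(scope="session")
def toy_gene():
    """A seeded synthetic Model-A gene with 60-nt exons."""
    spec = PlantSpec.random("A", seed=21, phase=1)
    return make_gene(spec, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
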