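import numpy as np
import pytest

from hiqem.descriptors import DescriptorConfig
from hiqem.mlp_potential import TrainConfig, train_base
from hiqem.synthetic_data import (
    ModelHamiltonianSpec,
    ToyPESConfig,
    gen_conformers,
    gen_model_system,
)
from hiqem.systems import XCModel


@pytest.fixture(scope="session")
def small_systems():
    """A spread of small seeded model systems (4-8 basis functions)."""
    specs = [
        ModelHamiltonianSpec(n_atoms=4, n_basis_per_atom=1, n_electrons=4, seed=1),
        ModelHamiltonianSpec(n_atoms=3, n_basis_per_atom=2, n_electrons=6, seed=2),
        ModelHamiltonianSpec(
            n_atoms=4, n_basis_per_atom=2, n_electrons=6, seed=3, topology="ring"
        ),
        ModelHamiltonianSpec(
            n_atoms=4,
            n_basis_per_atom=2,
            n_electrons=8,
            seed=4,
            interaction_strength=0.15,
        ),
    ]
    return [gen_model_system(s) for s in specs]


@pytest.fixture(scope="session")
def hf():
    return XCModel("hf")


@pytest.fixture(scope="session")
def toy_local():
    return XCModel("toy-local", strength=0.12)


@pytest.fixture(scope="session")
def pes_config():
    return ToyPESConfig()


@pytest.fixture(scope="session")
def conformers(pes_config):
    """Small labeled conformer set from the default three-tier toy."""
    return gen_conformers(pes_config, 120, seed=7)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(hidden=(12, 12), n_members=2, epochs=120, transfer_epochs=80)


@pytest.fixture(scope="session")
def tiny_ensemble(conformers, tiny_train_config):
    """A small trained base ensemble shared across ML tests."""
    return train_base(conformers, config=tiny_train_config, tier=1, seed=5)


@pytest.fixture(scope="session")
def descriptor_config():
    return DescriptorConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
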