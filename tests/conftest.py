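import numpy as np
import pytest

from mrfe import ann, fixtures, voxel
from mrfe.structures import Atom, LIGAND, MolecularComplex, RECEPTOR, RadiiTable


@pytest.fixture(scope="session")
def radii():
    return RadiiTable()


@pytest.fixture
def carbon_pair(radii):
    """Minimal complex: one receptor carbon, one ligand carbon."""
    r_ion, r_vdw = radii.lookup("C")
    return MolecularComplex(
        [
            Atom("C", (0.0, 0.0, 0.0), RECEPTOR, False, r_ion, r_vdw),
            Atom("C", (3.0, 0.0, 0.0), LIGAND, False, r_ion, r_vdw),
        ],
        label="pair",
    )


@pytest.fixture(scope="session")
def toy_complex():
    return fixtures.make_toy_complex(seed=11, n_receptor_atoms=30, n_ligand_atoms=6)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest network that still exercises every layer kind."""
    return ann.NetworkSpec(
        input_shape=(5, 4, 4, 4),
        encoder_channels=(3, 4),
        encoder_strides=(2, 1),
        nested_channels=4,
        mid_sizes=(6,),
        perceptron_sizes=(5,),
    )


@pytest.fixture
def small_grid():
    return voxel.GridSpec(origin=(-4.0, -4.0, -4.0), spacing=2.0, shape=(4, 4, 4))
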