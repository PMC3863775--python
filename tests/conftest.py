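import numpy as np
import pytest

from capsidkit import synthetic
from capsidkit.structures import AtomRecord, Chain, Residue, Structure


@pytest.fixture(scope="session")
def fold_fixture():
    """Three-element fold with bridgeable cross-junctions and a remote N-terminus."""
    return synthetic.make_three_element_fold(seed=11)


@pytest.fixture(scope="session")
def toy_capsid():
    return synthetic.make_toy_capsid(t=7, subunit_atoms=5, seed=3)


@pytest.fixture(scope="session")
def hopf_rings():
    return synthetic.make_ring_set("hopf", seed=0)


@pytest.fixture(scope="session")
def small_map_pair():
    return synthetic.make_map_pair(box=48, voxel_size=1.5, band_limit=6.0, snr=4.0, seed=7)


def make_ca_chain(chain_id: str, positions, start: int = 1) -> Chain:
    residues = [
        Residue(
            seq_id=start + i,
            name="GLY",
            atoms=[AtomRecord("CA", "C", np.asarray(p, dtype=float))],
        )
        for i, p in enumerate(positions)
    ]
    return Chain(chain_id, residues)


@pytest.fixture
def two_atom_structure():
    chain = Chain(
        "A",
        [
            Residue(
                1,
                "GLY",
                [
                    AtomRecord("N", "N", np.array([0.0, 0.0, 0.0])),
                    AtomRecord("CA", "C", np.array([1.5, 0.0, 0.0])),
                ],
            )
        ],
    )
    return Structure([chain])
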