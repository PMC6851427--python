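import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from refeval import StructureModel, make_ideal_chain


@pytest.fixture
def helix():
    """20-residue mixed-sequence helical chain."""
    return make_ideal_chain(20, -57.0, -47.0, "AVLSKDEFRTMQNYAVLSKD", model_id="helix")


@pytest.fixture
def strand():
    return make_ideal_chain(16, -120.0, 130.0, "AVLSKDEFRTMQNYAV", model_id="strand")


def rigid_transform(structure: StructureModel, seed: int = 0, translation=None) -> StructureModel:
    """Apply a random proper rotation plus translation to a copy."""
    rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    t = np.array([5.0, -3.0, 11.0]) if translation is None else np.asarray(translation, float)
    out = structure.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = rot @ atom.coords + t
    return out


def translate(structure: StructureModel, vec) -> StructureModel:
    out = structure.copy()
    v = np.asarray(vec, dtype=float)
    for res in out.residues:
        for atom in res.atoms:
            atom.coords = atom.coords + v
    return out
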