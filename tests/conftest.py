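import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sahhkit.refdata import get_reference
from sahhkit.structures import Atom, Chain, Residue, StructureModel

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


@pytest.fixture(scope="session")
def pfu_ref():
    return get_reference("pfu")


@pytest.fixture(scope="session")
def sac_ref():
    return get_reference("sac")


@pytest.fixture(scope="session")
def bacterial_ref():
    return get_reference("bacterial")


def ca_model_from_sequence(sequence: str, structure_id: str = "toy") -> StructureModel:
    """C-alpha-only model whose chain sequence equals ``sequence``."""
    rng = np.random.default_rng(0)
    chain = Chain(id="A")
    t = np.arange(len(sequence))
    coords = np.stack([
        10.0 * np.cos(t / 3.0), 10.0 * np.sin(t / 3.0), 1.5 * t
    ], axis=1)
    for i, (aa, pos) in enumerate(zip(sequence, coords), start=1):
        res = Residue(seqid=i, icode="", name=_ONE_TO_THREE[aa])
        res.atoms["CA"] = Atom(name="CA", element="C", pos=pos)
        chain.residues.append(res)
    return StructureModel(structure_id=structure_id, chains=[chain])
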