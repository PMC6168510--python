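import numpy as np
import pytest

from splitscan.energetics import AMINO_ACIDS, PairwisePotential
from splitscan.structure_io import Atom, ProteinStructure, Residue


def make_residue(index, aa="A", ca=(0.0, 0.0, 0.0), cb=None, author=None,
                 backbone=None):
    """Hand-built residue; ``backbone`` adds N/C atoms at given coords."""
    atoms = []
    if backbone is not None:
        atoms.append(Atom("N", "N", np.asarray(backbone["N"], float)))
    atoms.append(Atom("CA", "C", np.asarray(ca, float)))
    if backbone is not None:
        atoms.append(Atom("C", "C", np.asarray(backbone["C"], float)))
    if cb is not None:
        atoms.append(Atom("CB", "C", np.asarray(cb, float)))
    return Residue(index=index, author_number=author if author else index,
                   aa=aa, atoms=atoms)


def make_structure(residues, chain_id="A"):
    return ProteinStructure(chain_id=chain_id, residues=residues)


def random_blob(n, seed, box=14.0):
    """Compact random cluster of CA/CB pseudo-residues: generic test
    structure with a dense, irregular contact network."""
    rng = np.random.default_rng(seed)
    residues = []
    for k in range(n):
        ca = rng.uniform(0.0, box, 3)
        aa = AMINO_ACIDS[rng.integers(0, 20)]
        cb = None
        if aa != "G":
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cb = ca + 1.53 * u
        residues.append(make_residue(k + 1, aa=aa, ca=ca, cb=cb))
    return make_structure(residues)


@pytest.fixture(scope="session")
def unit_potential():
    """Every contact worth exactly -1: pair energies become contact counts."""
    return PairwisePotential(contact_matrix=np.full((20, 20), -1.0),
                             cutoff=7.5, min_sequence_separation=2)


@pytest.fixture(scope="session")
def default_pot():
    from splitscan.energetics import default_potential
    return default_potential()


@pytest.fixture
def gag_structure():
    """Gly-Ala-Gly toy with full backbone, residues 4 Å apart."""
    residues = []
    for k, aa in enumerate("GAG"):
        x = 4.0 * k
        residues.append(make_residue(
            k + 1, aa=aa, ca=(x, 0.0, 0.0),
            cb=(x, 1.5, 0.0) if aa != "G" else None,
            backbone={"N": (x - 1.2, 0.5, 0.0), "C": (x + 1.2, 0.5, 0.0)}))
    return make_structure(residues)
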