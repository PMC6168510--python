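"""Read and write protein structures.

The internal model is deliberately small: a chain is an ordered list of
residues, each residue an ordered list of atoms with coordinates and a
van der Waals radius assigned from the element.  Residue indices are
1-based and sequential over the *resolved* residues of the selected
chain; author (PDB) numbering is kept alongside so reports can print
both.  Missing residues in the crystal do not create placeholders —
a cut across an unresolved region is not meaningful — but the gaps are
reported as warnings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# Bondi van der Waals radii (Å), with a generic-heavy-atom fallback.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues read as their parent type
    "MSE": "M", "SEC": "C", "PYL": "K",
}
ONE_TO_THREE = {v: k for k, v in reversed(THREE_TO_ONE.items())}


class StructureError(ValueError):
    """Raised for unusable structure input (missing chain, empty chain...)."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = VDW_RADII.get(self.element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    index: int            # 1-based sequential position in the chain
    author_number: int    # PDB residue number, may differ from index
    aa: str               # one-letter code, 'X' if unknown
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    has_ca: bool = True

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class ProteinStructure:
    chain_id: str
    residues: list[Residue]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def author_numbering(self) -> dict[int, int]:
        """Mapping internal 1-based index -> author residue number."""
        return {r.index: r.author_number for r in self.residues}

    def coords(self, atom_name: str = "CA") -> np.ndarray:
        """(N, 3) array of the named atom per residue; NaN rows if absent."""
        out = np.full((self.n_residues, 3), np.nan)
        for k, res in enumerate(self.residues):
            a = res.atom(atom_name)
            if a is not None:
                out[k] = a.coord
        return out


def read_structure(path: str, chain: str | None = None, model: int = 1) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Keeps one residue per standard amino acid of the requested chain, in
    file order.  Waters, ligands and non-amino-acid heteroatoms are
    discarded; of alternate locations only the first ('' or 'A') is
    kept.  A sequential 1-based index is assigned independently of the
    author numbering.

    Parameters
    ----------
    path : PDB file path.
    chain : chain identifier; ``None`` selects the first chain that
        contains amino-acid residues.
    model : 1-based model number (NMR-style multi-model files).
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if model < 1 or model > len(st):
        raise StructureError(f"model {model} not found (file has {len(st)})")
    gmodel = st[model - 1]

    gchain = None
    if chain is None:
        for c in gmodel:
            if any(r.name in THREE_TO_ONE for r in c):
                gchain = c
                break
        if gchain is None:
            raise StructureError("empty chain: no amino-acid residues in any chain")
    else:
        for c in gmodel:
            if c.name == chain:
                gchain = c
                break
        if gchain is None:
            raise StructureError(f"chain not found: {chain!r}")

    residues: list[Residue] = []
    idx = 0
    for gres in gchain:
        aa = THREE_TO_ONE.get(gres.name)
        if aa is None:
            if gres.het_flag == "A":  # nonstandard amino acid in ATOM records
                aa = "X"
            else:
                continue  # water / ligand / ion
        idx += 1
        atoms: list[Atom] = []
        seen: set[str] = set()
        for ga in gres:
            if ga.altloc not in ("\0", "", "A"):  # gemmi uses '\0' for no altloc
                continue
            if ga.name in seen:
                continue
            seen.add(ga.name)
            atoms.append(Atom(
                name=ga.name,
                element=ga.element.name.upper(),
                coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
            ))
        res = Residue(
            index=idx,
            author_number=gres.seqid.num,
            aa=aa,
            atoms=atoms,
            insertion_code=(gres.seqid.icode or "").strip(),
        )
        if res.ca is None:
            res.has_ca = False
            warnings.warn(
                f"residue {gres.name} {gres.seqid.num} (chain {gchain.name}) "
                f"has no CA atom; kept but flagged",
                stacklevel=2,
            )
        residues.append(res)

    if not residues:
        raise StructureError(f"empty chain: no amino-acid residues in chain {gchain.name!r}")

    # warn about numbering gaps: cuts across unresolved regions are not meaningful
    gaps = []
    for prev, nxt in zip(residues, residues[1:]):
        if prev.insertion_code == "" and nxt.insertion_code == "":
            if nxt.author_number - prev.author_number > 1:
                gaps.append((prev.author_number, nxt.author_number))
    if gaps:
        logger.warning(
            "chain %s has unresolved gaps between author residues: %s",
            gchain.name, gaps,
        )

    return ProteinStructure(chain_id=gchain.name, residues=residues)


def extract_sequence(structure: ProteinStructure) -> str:
    """One-letter sequence in residue-index order (length == n_residues)."""
    return "".join(r.aa for r in structure.residues)


def write_pdb(structure: ProteinStructure, path: str) -> None:
    """Write the structure back out as minimal ATOM records."""
    lines = []
    serial = 0
    for res in structure.residues:
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # PDB column rules: 1-3 char names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} "
                f"{structure.chain_id[:1]:1s}{res.author_number:4d}"
                f"{res.insertion_code[:1]:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
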