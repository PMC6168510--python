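"""Pairwise residue-residue energies and the split-energy profile.

The split energy of a cut between residues i and i+1 is

    SE(i) = E_N - (E_A + E_B)

where E_N is the energy of the intact chain and E_A, E_B the energies
of the two halves (residues 1..i and i+1..N) scored with unchanged
coordinates.  For any pairwise-additive potential this reduces exactly
to the sum of interaction energies of residue pairs straddling the cut,
which is how the profile is computed here; the three-total-energy form
is kept as a test invariant.

The default potential is a residue-level statistical contact potential:
a 20x20 symmetric table of contact energies applied to residue pairs
whose Cβ-Cβ distance (Cα for glycine) is within a cutoff and whose
sequence separation is at least ``min_sequence_separation``.  The table
shipped as package data is an additive hydrophobicity-derived one
(e_ij = -(h'_i + h'_j)/2 over a shifted Kyte-Doolittle scale, all
entries attractive); any user-supplied 20x20 plain-text table can be
substituted.  Absolute energy scale therefore differs from all-atom
force fields, which is why downstream thresholds operate on a rescaled
profile (see :mod:`splitscan.site_selection`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from splitscan.structure_io import ProteinStructure, Residue

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}


@dataclass
class PairwisePotential:
    """A 20x20 symmetric contact-energy table plus its contact definition.

    Parameters
    ----------
    contact_matrix : (20, 20) symmetric array, rows/columns ordered by
        :data:`AMINO_ACIDS`; kcal/mol-scale arbitrary units.
    distance_definition : ``"cbeta"`` (Cβ, Cα for Gly or when Cβ is
        missing), ``"ca"`` (Cα only) or ``"min"`` (heavy-atom minimum).
    cutoff : contact distance cutoff, Å.
    min_sequence_separation : pairs closer in sequence contribute zero.
    """

    contact_matrix: np.ndarray
    distance_definition: str = "cbeta"
    cutoff: float = 7.5
    min_sequence_separation: int = 2
    name: str = "contact"

    def __post_init__(self):
        m = np.asarray(self.contact_matrix, dtype=float)
        if m.shape != (20, 20):
            raise ValueError("contact_matrix must be 20x20")
        if not np.allclose(m, m.T):
            raise ValueError("contact_matrix must be symmetric")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")
        if self.distance_definition not in ("cbeta", "ca", "min"):
            raise ValueError(f"unknown distance definition {self.distance_definition!r}")
        self.contact_matrix = m

    def entry(self, aa_a: str, aa_b: str) -> float:
        ia = AA_INDEX.get(aa_a)
        ib = AA_INDEX.get(aa_b)
        if ia is None or ib is None:  # unknown residue type: mean contact energy
            return float(self.contact_matrix.mean())
        return float(self.contact_matrix[ia, ib])


@dataclass
class SplitEnergyProfile:
    """Per-cut split energies: values[k] is SE for the cut between
    residues k+1 and k+2 (cut index k+1 in 1-based terms; length N-1)."""

    values: np.ndarray
    smoothed: np.ndarray | None = None
    derivative: np.ndarray | None = None
    energy_units: str = "contact units"
    scale_factor: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("split-energy profile contains non-finite values")

    @property
    def n_cuts(self) -> int:
        return len(self.values)


def load_potential(path=None, **kwargs) -> PairwisePotential:
    """Load a 20x20 potential from a plain-text table.

    The format is a header row of one-letter codes, then 20 rows each
    beginning with its one-letter code; whitespace separated.  With
    ``path=None`` the packaged default table is loaded.
    """
    if path is None:
        ref = resources.files("splitscan").joinpath("data/contact_hydro.tsv")
        text = ref.read_text()
        kwargs.setdefault("name", "hydrophobic-contact")
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.split() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = [c.upper() for c in lines[0]]
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ValueError("potential table header must list the 20 amino acids")
    matrix = np.zeros((20, 20))
    if len(lines) != 21:
        raise ValueError("potential table must have 20 data rows")
    for row in lines[1:]:
        aa = row[0].upper()
        vals = [float(v) for v in row[1:]]
        if len(vals) != 20:
            raise ValueError(f"row {aa} does not have 20 values")
        for col_aa, v in zip(header, vals):
            matrix[AA_INDEX[aa], AA_INDEX[col_aa]] = v
    return PairwisePotential(contact_matrix=matrix, **kwargs)


_DEFAULT: PairwisePotential | None = None


def default_potential() -> PairwisePotential:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_potential()
    return _DEFAULT


def _interaction_coord(res: Residue, definition: str) -> np.ndarray | None:
    if definition == "ca":
        a = res.atom("CA")
        return None if a is None else a.coord
    # cbeta: CB, falling back to CA (glycine, or CB absent)
    a = res.atom("CB")
    if a is None:
        a = res.atom("CA")
        if a is not None and res.aa != "G":
            logger.debug("residue %d (%s) has no CB; using CA", res.index, res.aa)
    return None if a is None else a.coord


def _pair_distance(res_a: Residue, res_b: Residue, definition: str) -> float:
    if definition == "min":
        ca = np.array([a.coord for a in res_a.atoms if a.element != "H"])
        cb = np.array([a.coord for a in res_b.atoms if a.element != "H"])
        if len(ca) == 0 or len(cb) == 0:
            return np.inf
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
        return float(d.min())
    xa = _interaction_coord(res_a, definition)
    xb = _interaction_coord(res_b, definition)
    if xa is None or xb is None:
        logger.warning("residue %d or %d lacks the required atom; energy set to 0",
                       res_a.index, res_b.index)
        return np.inf
    return float(np.linalg.norm(xa - xb))


def pair_energy(res_a: Residue, res_b: Residue,
                potential: PairwisePotential | None = None) -> float:
    """Contact energy of one residue pair (0 beyond cutoff or below the
    minimum sequence separation); symmetric in its arguments."""
    if potential is None:
        potential = default_potential()
    if abs(res_a.index - res_b.index) < potential.min_sequence_separation:
        return 0.0
    d = _pair_distance(res_a, res_b, potential.distance_definition)
    if d > potential.cutoff:
        return 0.0
    return potential.entry(res_a.aa, res_b.aa)


def _contact_pairs(structure: ProteinStructure,
                   potential: PairwisePotential) -> list[tuple[int, int, float]]:
    """All unordered residue pairs with nonzero energy, as 1-based
    (i, j, energy) with i < j."""
    n = structure.n_residues
    sep = potential.min_sequence_separation
    out: list[tuple[int, int, float]] = []
    if potential.distance_definition in ("ca", "cbeta"):
        coords = np.full((n, 3), np.nan)
        for k, res in enumerate(structure.residues):
            x = _interaction_coord(res, potential.distance_definition)
            if x is not None:
                coords[k] = x
        valid = np.where(np.all(np.isfinite(coords), axis=1))[0]
        tree = cKDTree(coords[valid])
        for a, b in tree.query_pairs(potential.cutoff):
            ka, kb = int(valid[a]), int(valid[b])
            if ka > kb:
                ka, kb = kb, ka
            if kb - ka < sep:
                continue
            e = potential.entry(structure.residues[ka].aa, structure.residues[kb].aa)
            if e != 0.0:
                out.append((ka + 1, kb + 1, e))
    else:  # heavy-atom minimum distance: tree over all heavy atoms
        atom_coords, atom_res = [], []
        for k, res in enumerate(structure.residues):
            for a in res.atoms:
                if a.element != "H":
                    atom_coords.append(a.coord)
                    atom_res.append(k)
        atom_coords = np.asarray(atom_coords)
        atom_res = np.asarray(atom_res)
        tree = cKDTree(atom_coords)
        seen: set[tuple[int, int]] = set()
        for a, b in tree.query_pairs(potential.cutoff):
            ka, kb = int(atom_res[a]), int(atom_res[b])
            if ka > kb:
                ka, kb = kb, ka
            if kb - ka < sep or (ka, kb) in seen:
                continue
            seen.add((ka, kb))
            e = potential.entry(structure.residues[ka].aa, structure.residues[kb].aa)
            if e != 0.0:
                out.append((ka + 1, kb + 1, e))
    return out


def total_energy(structure: ProteinStructure,
                 potential: PairwisePotential | None = None) -> float:
    """Sum of pair energies over all unordered residue pairs (E_N when
    applied to the intact chain)."""
    if potential is None:
        potential = default_potential()
    return float(sum(e for _, _, e in _contact_pairs(structure, potential)))


def split_energy_profile(structure: ProteinStructure,
                         potential: PairwisePotential | None = None) -> SplitEnergyProfile:
    """SE(i) = E_N - (E_A + E_B) for every cut i in 1..N-1.

    Computed as the cross-half pair sum: each contact (a, b) with a < b
    contributes its energy to every cut a <= i < b.
    """
    if potential is None:
        potential = default_potential()
    n = structure.n_residues
    if n < 3:
        raise ValueError("structure too short: need at least 3 residues")
    diff = np.zeros(n)  # difference array over cut indices 1..n-1 (0-based 0..n-2)
    for a, b, e in _contact_pairs(structure, potential):
        diff[a - 1] += e
        diff[b - 1] -= e
    values = np.cumsum(diff)[: n - 1]
    # contacts cancel exactly in the cumulative sum; clean float dust
    values[np.abs(values) < 1e-12] = 0.0
    return SplitEnergyProfile(values=values)


def profile_to_tsv(profile: SplitEnergyProfile, structure: ProteinStructure) -> str:
    """Profile export: cut_index, author residue pair, raw/smoothed/derivative."""
    rows = ["cut_index\tauthor_pair\tSE_raw\tSE_smoothed\tderivative"]
    sm = profile.smoothed if profile.smoothed is not None else [float("nan")] * profile.n_cuts
    dv = profile.derivative if profile.derivative is not None else [float("nan")] * profile.n_cuts
    for k in range(profile.n_cuts):
        ri = structure.residues[k]
        rj = structure.residues[k + 1]
        rows.append(
            f"{k + 1}\t{ri.author_number}-{rj.author_number}\t"
            f"{profile.values[k]:.6g}\t{sm[k]:.6g}\t{dv[k]:.6g}"
        )
    return "\n".join(rows) + "\n"
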