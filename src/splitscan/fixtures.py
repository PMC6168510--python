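"""Synthetic structures and alignments for testing and demos.

Everything here is generated, not downloaded: the generators make the
whole pipeline exercisable without any external database.

* :func:`generate_dumbbell` builds a two-lobe "dumbbell": two compact
  pseudo-globular lobes (jittered cubic lattices of Cα/Cβ
  pseudo-residues) joined by an extended, fully exposed linker with no
  cross-lobe contacts.  The linker is the ground-truth split region —
  the topology of a protein with two folding cores — so dumbbells
  support parameter-recovery tests: the top-ranked predicted site must
  land in the linker.
* :func:`build_peptide` builds an ideal-geometry backbone (N, CA, C, O,
  CB) from a φ/ψ torsion list, for helix/strand/coil fixtures whose
  secondary structure is known by construction.
* :func:`generate_msa` emits an aligned-FASTA family whose first row is
  the ungapped query; selected columns are fully conserved, the rest
  drawn from a uniform background.

All generators are deterministic: one PRNG stream per seed, identical
bytes for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from splitscan.energetics import AMINO_ACIDS
from splitscan.structure_io import Atom, ProteinStructure, Residue, write_pdb


@dataclass
class FixtureSpec:
    kind: str = "dumbbell"        # dumbbell | hairpin | helix | extended | cage
    n_residues: int = 32          # per lobe (dumbbell) or total
    linker_length: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("fixtures need at least 3 residues per part")


# ---------------------------------------------------------------- backbone

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "CA-CB": 1.530,
         "C-O": 1.231}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2,
          "N-CA-CB": 110.5, "CA-C-O": 120.8}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d given a-b-c, |cd|, angle bcd, torsion abcd."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(sequence: str,
                  torsions: list[tuple[float, float]]) -> ProteinStructure:
    """Ideal-geometry peptide from per-residue (phi, psi); omega = 180.

    phi of the first residue and psi of the last are ignored (they are
    undefined on a real chain as well).
    """
    if len(sequence) != len(torsions):
        raise ValueError("sequence and torsion list must have equal length")
    n = len(sequence)
    coords: list[dict[str, np.ndarray]] = []
    for k in range(n):
        phi, psi = torsions[k]
        if k == 0:
            N = np.zeros(3)
            CA = np.array([_BOND["N-CA"], 0.0, 0.0])
            ang = np.radians(_ANGLE["N-CA-C"])
            C = CA + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = coords[k - 1]
            prev_psi = torsions[k - 1][1]
            N = _place(prev["N"], prev["CA"], prev["C"],
                       _BOND["C-N"], _ANGLE["CA-C-N"], prev_psi)
            CA = _place(prev["CA"], prev["C"], N,
                        _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega
            C = _place(prev["C"], N, CA, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        coords.append({"N": N, "CA": CA, "C": C})

    residues = []
    for k, aa in enumerate(sequence):
        c = coords[k]
        atoms = [
            Atom("N", "N", c["N"]),
            Atom("CA", "C", c["CA"]),
            Atom("C", "C", c["C"]),
        ]
        if k < n - 1:
            # carbonyl O opposite the next N
            O = _place(coords[k + 1]["N"], c["CA"], c["C"],
                       _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
            atoms.append(Atom("O", "O", O))
        if aa != "G":
            CB = _place(c["C"], c["N"], c["CA"],
                        _BOND["CA-CB"], _ANGLE["N-CA-CB"], 122.5)
            atoms.append(Atom("CB", "C", CB))
        residues.append(Residue(index=k + 1, author_number=k + 1, aa=aa,
                                atoms=atoms))
    return ProteinStructure(chain_id="A", residues=residues)


HELIX_TORSIONS = (-57.0, -47.0)
EXTENDED_TORSIONS = (-135.0, 135.0)
COIL_TORSIONS = (-75.0, 145.0)  # polyproline-II-like: extended but not strand


def generate_helix(n: int, sequence: str | None = None) -> ProteinStructure:
    seq = sequence or "A" * n
    return build_peptide(seq, [HELIX_TORSIONS] * n)


def generate_extended(n: int, sequence: str | None = None) -> ProteinStructure:
    seq = sequence or "A" * n
    return build_peptide(seq, [EXTENDED_TORSIONS] * n)


def generate_hairpin(n_strand: int = 6, loop_length: int = 4) -> ProteinStructure:
    """Cα-only antiparallel two-strand hairpin: strands 4.8 Å apart
    (cross-strand Cα distances ≈ 5 Å) joined by a short apex loop."""
    rise, sep = 3.4, 4.8
    pts: list[np.ndarray] = []
    for i in range(n_strand):                      # up strand at x = 0
        pts.append(np.array([0.0, i * rise, 0.0]))
    top = (n_strand - 1) * rise
    for i in range(loop_length):                   # apex arc
        t = np.pi * (i + 1) / (loop_length + 1)
        pts.append(np.array([sep / 2 - (sep / 2) * np.cos(t),
                             top + (sep / 2) * np.sin(t), 0.0]))
    for i in range(n_strand):                      # down strand at x = sep
        pts.append(np.array([sep, top - i * rise, 0.0]))
    residues = [Residue(index=k + 1, author_number=k + 1, aa="A",
                        atoms=[Atom("CA", "C", p)])
                for k, p in enumerate(pts)]
    return ProteinStructure(chain_id="A", residues=residues)


def cage_coords(n_shell: int = 200, shell_radius: float = 3.0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """A carbon atom fully enclosed by a dense shell of carbons; its
    Shrake-Rupley accessible area is zero by construction."""
    from splitscan.geometry_annotation import sphere_points
    shell = shell_radius * sphere_points(n_shell)
    coords = np.vstack([np.zeros(3), shell])
    radii = np.full(len(coords), 1.70)
    return coords, radii


# ---------------------------------------------------------------- dumbbell

def _lattice_lobe(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n compact jittered cubic-lattice points, closest to the center."""
    m = int(np.ceil(n ** (1 / 3))) + 2
    grid = np.array([[i, j, k] for i in range(-m, m + 1)
                     for j in range(-m, m + 1) for k in range(-m, m + 1)],
                    dtype=float) * spacing
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    pts = grid[order[:n]]
    return pts + rng.normal(0.0, 0.25, pts.shape)


def _arc_linker(x0: float, n: int, step: float, bump: float,
                rng: np.random.Generator) -> tuple[list[np.ndarray], float]:
    """n linker points on an outward arc from x0, successive points
    ``step`` apart; returns the points and the end x of the arc.

    The arc bulges away from the lobe-lobe axis the way a real exposed
    loop arcs away from the protein body, so mid-linker residues are
    the most solvent-exposed.
    """
    if n == 0:
        return [], x0
    # chord shorter than the along-arc length so the bump has room
    span = step * (n + 1) * 0.8
    ts = np.linspace(0.0, 1.0, 512)
    curve = np.column_stack([x0 + span * ts, np.zeros_like(ts),
                             bump * np.sin(np.pi * ts)])
    seglen = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    pts = []
    for i in range(1, n + 1):
        target = total * i / (n + 1)
        k = int(np.searchsorted(arclen, target))
        pts.append(curve[min(k, len(curve) - 1)] + rng.normal(0.0, 0.05, 3))
    return pts, x0 + span


def dumbbell_structure(spec: FixtureSpec,
                       ) -> tuple[ProteinStructure, tuple[int, int]]:
    """Two-lobe dumbbell as a ProteinStructure plus the ground-truth
    split region (inclusive range of cut indices inside the linker)."""
    rng = np.random.default_rng(spec.seed)
    n_lobe = spec.n_residues
    linker = spec.linker_length
    spacing = 4.0

    lobe_a = _lattice_lobe(n_lobe, spacing, rng)
    lobe_b = _lattice_lobe(n_lobe, spacing, rng)
    r_a = np.linalg.norm(lobe_a, axis=1).max()
    r_b = np.linalg.norm(lobe_b, axis=1).max()

    # order lobe residues deterministically (shuffled so chain order is
    # not correlated with burial)
    rng.shuffle(lobe_a)
    rng.shuffle(lobe_b)

    if linker > 0:
        gap = 5.0  # lobe surface to linker ends; no cross-lobe contacts
        linker_pts, x_end = _arc_linker(r_a + gap, linker, step=4.0,
                                        bump=8.0, rng=rng)
        shift = np.array([x_end + gap + r_b, 0.0, 0.0])
    else:
        linker_pts = []
        # fused lobes interpenetrate slightly so the junction carries
        # genuine cross-lobe contacts
        shift = np.array([r_a + r_b - spacing, 0.0, 0.0])

    all_ca = [*lobe_a, *linker_pts, *(lobe_b + shift)]
    residues = []
    for k, ca in enumerate(all_ca):
        aa = AMINO_ACIDS[rng.integers(0, 20)]
        atoms = [Atom("CA", "C", ca)]
        if aa != "G":
            # short pseudo-side-chain (CB-CG-CD) so lobes pack and
            # occlude the way real domains do
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = ca
            for name in ("CB", "CG", "CD"):
                step_dir = u + rng.normal(0.0, 0.25, 3)
                step_dir /= np.linalg.norm(step_dir)
                pos = pos + 1.52 * step_dir
                atoms.append(Atom(name, "C", pos))
        residues.append(Residue(index=k + 1, author_number=k + 1, aa=aa,
                                atoms=atoms))
    structure = ProteinStructure(chain_id="A", residues=residues)
    if linker > 0:
        truth = (n_lobe, n_lobe + linker)  # cuts flanking/inside the linker
    else:
        truth = (n_lobe, n_lobe)
    return structure, truth


def generate_dumbbell(spec: FixtureSpec) -> tuple[str, tuple[int, int]]:
    """Dumbbell fixture as PDB text plus the ground-truth linker cut range."""
    import io
    import tempfile
    import os

    structure, truth = dumbbell_structure(spec)
    fd, path = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_pdb(structure, path)
        with open(path) as fh:
            text = fh.read()
    finally:
        os.unlink(path)
    return text, truth


# ---------------------------------------------------------------- MSA

def generate_msa(length: int, conserved_positions: list[int],
                 n_sequences: int, seed: int = 0,
                 query: str | None = None) -> str:
    """Aligned-FASTA family: first row is the ungapped query; columns in
    ``conserved_positions`` (1-based) carry the query's residue in every
    row; all other columns are drawn uniformly per row."""
    bad = [p for p in conserved_positions if not 1 <= p <= length]
    if bad:
        raise ValueError(f"conserved positions out of range: {bad}")
    rng = np.random.default_rng(seed)
    if query is None:
        query = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
    if len(query) != length:
        raise ValueError("query length must equal alignment length")
    conserved = set(conserved_positions)
    rows = [("query", query)]
    for s in range(1, n_sequences):
        chars = []
        for j in range(length):
            if (j + 1) in conserved:
                chars.append(query[j])
            else:
                chars.append(AMINO_ACIDS[rng.integers(0, 20)])
        rows.append((f"seq{s}", "".join(chars)))
    out = []
    for rid, seq in rows:
        out.append(f">{rid}")
        out.append(seq)
    return "\n".join(out) + "\n"
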