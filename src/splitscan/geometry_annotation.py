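"""Solvent accessibility, secondary structure, loops, loop tightness.

SAA uses the Shrake-Rupley rolling-probe point-sampling algorithm: test
points on a sphere of radius r_atom + r_probe around each atom are
counted accessible when no neighbouring atom sphere covers them, and
the accessible fraction is converted to area.  Per-residue SAA is the
sum over the residue's atoms.  Defaults (960 points, 1.4 Å probe)
reproduce the analytic isolated-sphere area to well under 1%.

Secondary structure is taken verbatim from an external annotation when
one is provided (DSSP-style classes normalized to {H, E, C}); otherwise
a backbone-torsion heuristic assigns H in the alpha-helical phi/psi
basin and E in the extended basin, each requiring at least three
consecutive residues, and C elsewhere.  This heuristic stands in for a
full hydrogen-bond-based assignment (DSSP/Stride), which is out of
scope; users with Stride output can feed it in unchanged.

Loops are maximal runs of C.  A loop is "tight" — likely to connect
two interacting structural units — when its flanks are spatially close:
taking up to five residues on each side of the loop (skipping residues
that belong to other loops), each left-flank residue is paired with its
nearest right-flank residue by Calpha distance, and the loop is tight
if at least three of these pairs are closer than a threshold (10 Å).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from splitscan.structure_io import ProteinStructure

logger = logging.getLogger(__name__)


@dataclass
class LoopSegment:
    start: int  # 1-based residue index, inclusive
    end: int    # inclusive
    tight: bool = False

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("loop start must not exceed end")


@dataclass
class SurfaceAnnotation:
    saa: np.ndarray            # per-residue solvent accessible area, Å²
    ss: str                    # per-residue class over {H, E, C}
    loops: list[LoopSegment]

    def loop_of(self, index: int) -> int | None:
        """0-based id of the loop containing residue ``index``, or None."""
        for k, lp in enumerate(self.loops):
            if index in lp:
                return k
        return None


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe_radius: float = 1.4, n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent accessible area (Å²) by Shrake-Rupley."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be at least 92")
    n_atoms = len(coords)
    pts = sphere_points(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    out = np.zeros(n_atoms)
    max_reach = 2.0 * expanded.max()
    for i in range(n_atoms):
        test = coords[i] + expanded[i] * pts
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(test - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        out[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return out


def compute_saa(structure: ProteinStructure, probe_radius: float = 1.4,
                n_sphere_points: int = 960) -> np.ndarray:
    """Per-residue SAA (Å²): Shrake-Rupley per atom, summed per residue."""
    coords, radii, owner = [], [], []
    for k, res in enumerate(structure.residues):
        for a in res.atoms:
            coords.append(a.coord)
            radii.append(a.vdw_radius)
            owner.append(k)
    per_atom = atom_sasa(np.asarray(coords), np.asarray(radii),
                         probe_radius, n_sphere_points)
    out = np.zeros(structure.n_residues)
    np.add.at(out, np.asarray(owner), per_atom)
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_torsions(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) per residue in degrees; NaN where undefined (termini
    or missing backbone atoms)."""
    n = structure.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    bb = []
    for res in structure.residues:
        bb.append({nm: (res.atom(nm).coord if res.atom(nm) else None)
                   for nm in ("N", "CA", "C")})
    for k in range(n):
        if k > 0 and all(x is not None for x in
                         (bb[k - 1]["C"], bb[k]["N"], bb[k]["CA"], bb[k]["C"])):
            phi[k] = dihedral(bb[k - 1]["C"], bb[k]["N"], bb[k]["CA"], bb[k]["C"])
        if k < n - 1 and all(x is not None for x in
                             (bb[k]["N"], bb[k]["CA"], bb[k]["C"], bb[k + 1]["N"])):
            psi[k] = dihedral(bb[k]["N"], bb[k]["CA"], bb[k]["C"], bb[k + 1]["N"])
    return phi, psi


# phi/psi basins (degrees); deliberately conservative so that
# polyproline-II-like coil does not read as strand
_HELIX_PHI = (-120.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -90.0)
_SHEET_PSI = (90.0, 180.0)

_SS_NORMALIZE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def _in(val: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= val <= lo_hi[1]


def _enforce_min_run(ss: list[str], min_run: int = 3) -> str:
    out = list(ss)
    n = len(out)
    k = 0
    while k < n:
        j = k
        while j < n and out[j] == out[k]:
            j += 1
        if out[k] in "HE" and j - k < min_run:
            for t in range(k, j):
                out[t] = "C"
        k = j
    return "".join(out)


def assign_secondary_structure(structure: ProteinStructure,
                               external_ss: str | None = None) -> str:
    """Per-residue secondary structure over {H, E, C}.

    With ``external_ss`` (a DSSP/Stride-style string of length N) the
    annotation is normalized (G/I -> H, B -> E, everything else -> C)
    and used verbatim; otherwise the torsion heuristic applies.
    """
    n = structure.n_residues
    if external_ss is not None:
        if len(external_ss) != n:
            raise ValueError(
                f"external secondary structure has length {len(external_ss)}, "
                f"expected {n}")
        return "".join(_SS_NORMALIZE.get(c.upper(), "C") for c in external_ss)
    phi, psi = backbone_torsions(structure)
    ss = []
    for ph, ps in zip(phi, psi):
        if np.isnan(ph) or np.isnan(ps):
            ss.append("C")
        elif _in(ph, _HELIX_PHI) and _in(ps, _HELIX_PSI):
            ss.append("H")
        elif _in(ph, _SHEET_PHI) and _in(ps, _SHEET_PSI):
            ss.append("E")
        else:
            ss.append("C")
    return _enforce_min_run(ss)


def segment_loops(ss: str) -> list[LoopSegment]:
    """Maximal runs of C as loops (1-based, inclusive, tight unset)."""
    loops: list[LoopSegment] = []
    k = 0
    n = len(ss)
    while k < n:
        if ss[k] == "C":
            j = k
            while j < n and ss[j] == "C":
                j += 1
            loops.append(LoopSegment(start=k + 1, end=j))
            k = j
        else:
            k += 1
    return loops


def evaluate_tightness(loop: LoopSegment, loops: list[LoopSegment],
                       structure: ProteinStructure,
                       distance_threshold: float = 10.0,
                       min_pairs: int = 3,
                       flank_size: int = 5) -> bool:
    """Whether the loop's flanks are spatially close (see module docs).

    Flank residues that fall inside *another* loop, or off the chain,
    are skipped rather than replaced.  With fewer than ``min_pairs``
    usable left-flank residues the loop cannot be tight.
    """
    n = structure.n_residues
    others = [lp for lp in loops if lp is not loop and
              not (lp.start == loop.start and lp.end == loop.end)]

    def usable(idx: int) -> bool:
        if idx < 1 or idx > n:
            return False
        return not any(idx in lp for lp in others)

    left = [i for i in range(loop.start - flank_size, loop.start) if usable(i)]
    right = [i for i in range(loop.end + 1, loop.end + flank_size + 1) if usable(i)]
    if len(left) < min_pairs or not right:
        logger.info("loop %d-%d: insufficient flanks (left=%d right=%d); not tight",
                    loop.start, loop.end, len(left), len(right))
        return False
    ca = structure.coords("CA")
    close = 0
    for li in left:
        if not np.all(np.isfinite(ca[li - 1])):
            continue
        dmin = np.inf
        for ri in right:
            if not np.all(np.isfinite(ca[ri - 1])):
                continue
            dmin = min(dmin, float(np.linalg.norm(ca[li - 1] - ca[ri - 1])))
        if dmin < distance_threshold:
            close += 1
    return close >= min_pairs


def annotate(structure: ProteinStructure, external_ss: str | None = None,
             probe_radius: float = 1.4, n_sphere_points: int = 960,
             tightness_distance: float = 10.0, tightness_min_pairs: int = 3,
             flank_size: int = 5) -> SurfaceAnnotation:
    """Full surface/secondary-structure annotation with tightness flags."""
    saa = compute_saa(structure, probe_radius, n_sphere_points)
    ss = assign_secondary_structure(structure, external_ss)
    loops = segment_loops(ss)
    for lp in loops:
        lp.tight = evaluate_tightness(lp, loops, structure, tightness_distance,
                                      tightness_min_pairs, flank_size)
    return SurfaceAnnotation(saa=saa, ss=ss, loops=loops)


def annotation_to_tsv(annotation: SurfaceAnnotation,
                      structure: ProteinStructure) -> str:
    rows = ["residue_index\tauthor_number\taa\tsaa_A2\tss\tloop"]
    for res, s in zip(structure.residues, annotation.saa):
        lid = annotation.loop_of(res.index)
        loop_str = "NA" if lid is None else \
            f"{annotation.loops[lid].start}-{annotation.loops[lid].end}"
        rows.append(f"{res.index}\t{res.author_number}\t{res.aa}\t"
                    f"{s:.2f}\t{annotation.ss[res.index - 1]}\t{loop_str}")
    return "\n".join(rows) + "\n"
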