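"""Per-residue Kullback-Leibler conservation from a family alignment.

Each alignment column gets the KL divergence (in bits) of its
amino-acid frequency distribution from a background distribution:

    score = sum_a p_a * log2(p_a / q_a)   over residues with p_a > 0.

Gaps are excluded from the column counts; columns with more than half
gaps are marked missing rather than scored.  The background defaults to
the amino-acid composition of the whole alignment; a uniform background
(q_a = 1/20) is selectable, and optional Henikoff position-based
sequence weights are available (off by default — each row counts once).
The published "KL conservation score" exists in several variants; these
switches cover the common ones and the configured variant is echoed in
reports.

Scores are mapped onto structure residues through the alignment row of
a designated query sequence, aligning its ungapped sequence to the
structure's extracted sequence when the two differ by indels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, AlignIO

from splitscan.energetics import AA_INDEX, AMINO_ACIDS
from splitscan.structure_io import ProteinStructure, extract_sequence

logger = logging.getLogger(__name__)

GAP = "-"
MISSING = float("nan")


class AlignmentError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Rows of (id, aligned sequence); gaps normalized to '-'."""

    sequences: list[tuple[str, str]]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise AlignmentError("not an alignment: fewer than 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError("alignment not flush: rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.sequences)

    def row(self, seq_id: str) -> str:
        for rid, s in self.sequences:
            if rid == seq_id:
                return s
        raise AlignmentError(f"sequence {seq_id!r} not in alignment")


@dataclass
class ConservationProfile:
    """Per-structure-residue KL scores (bits); NaN marks unmapped or
    unscorable (all-gap / too gappy) residues."""

    scores: np.ndarray
    column_of_residue: np.ndarray  # 1-based alignment column, 0 = unmapped
    coverage: float = 0.0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.column_of_residue = np.asarray(self.column_of_residue, dtype=int)


def _normalize(seq: str) -> str:
    out = []
    for c in seq.upper():
        if c in (".", "-"):
            out.append(GAP)
        elif c in AA_INDEX:
            out.append(c)
        else:
            out.append("X")  # ambiguous; ignored in counts
    return "".join(out)


def read_alignment(path: str, fmt: str | None = None) -> MultipleAlignment:
    """Read an aligned-FASTA or Stockholm file.

    ``fmt`` is "fasta" or "stockholm"; ``None`` sniffs the first
    non-blank character ('#' -> Stockholm, '>' -> FASTA).
    """
    if fmt is None:
        with open(path) as fh:
            head = fh.read(4096).lstrip()
        fmt = "stockholm" if head.startswith("#") else "fasta"
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentError(f"alignment not flush or unreadable: {exc}") from exc
    rows = [(rec.id, _normalize(str(rec.seq))) for rec in aln]
    return MultipleAlignment(sequences=rows)


def henikoff_weights(msa: MultipleAlignment) -> np.ndarray:
    """Henikoff & Henikoff position-based weights, normalized to sum to
    the number of rows (so unweighted == all-ones)."""
    n, L = msa.n_rows, msa.n_columns
    w = np.zeros(n)
    for j in range(L):
        col = msa.column(j)
        kinds: dict[str, int] = {}
        for c in col:
            if c in AA_INDEX:
                kinds[c] = kinds.get(c, 0) + 1
        r = len(kinds)
        if r == 0:
            continue
        for i, c in enumerate(col):
            if c in kinds:
                w[i] += 1.0 / (r * kinds[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def column_kl(column: str, background: np.ndarray,
              weights: np.ndarray | None = None,
              max_gap_fraction: float = 0.5) -> float:
    """KL conservation score of one column, in bits; NaN for columns
    whose gap fraction exceeds ``max_gap_fraction``."""
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    background = background / background.sum()
    if weights is None:
        weights = np.ones(len(column))
    counts = np.zeros(20)
    n_gap = 0.0
    n_tot = 0.0
    for c, w in zip(column, weights):
        n_tot += w
        if c == GAP:
            n_gap += w
        elif c in AA_INDEX:
            counts[AA_INDEX[c]] += w
    if n_tot == 0 or n_gap / n_tot > max_gap_fraction or counts.sum() == 0:
        return MISSING
    p = counts / counts.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / background[mask])))


def alignment_background(msa: MultipleAlignment,
                         weights: np.ndarray | None = None,
                         pseudocount: float = 1e-4) -> np.ndarray:
    """Amino-acid composition of the whole alignment, with a small
    add-epsilon pseudocount so every background frequency is positive."""
    counts = np.full(20, pseudocount)
    if weights is None:
        weights = np.ones(msa.n_rows)
    for (_, seq), w in zip(msa.sequences, weights):
        for c in seq:
            k = AA_INDEX.get(c)
            if k is not None:
                counts[k] += w
    return counts / counts.sum()


UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


def conservation_scores(msa: MultipleAlignment,
                        background: str | np.ndarray = "alignment",
                        weighting: str = "none",
                        max_gap_fraction: float = 0.5) -> np.ndarray:
    """Per-column KL scores for the whole alignment.

    ``background``: "alignment" (composition-derived), "uniform", or an
    explicit 20-vector.  ``weighting``: "none" or "henikoff".
    """
    weights = henikoff_weights(msa) if weighting == "henikoff" else None
    if isinstance(background, str):
        if background == "uniform":
            q = UNIFORM_BACKGROUND
        elif background == "alignment":
            q = alignment_background(msa, weights)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        q = np.asarray(background, dtype=float)
    return np.array([
        column_kl(msa.column(j), q, weights, max_gap_fraction)
        for j in range(msa.n_columns)
    ])


def _map_query_to_structure(query_ungapped: str, struct_seq: str,
                            max_mismatch: float = 0.05) -> dict[int, int]:
    """Map 0-based positions of the ungapped query onto 0-based
    structure residue positions; identity fast path, else global
    alignment."""
    if query_ungapped == struct_seq:
        return {k: k for k in range(len(struct_seq))}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(query_ungapped, struct_seq)[0]
    mapping: dict[int, int] = {}
    mismatches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for dq in range(qe - qs):
            qi, si = qs + dq, ss + dq
            aligned_cols += 1
            if query_ungapped[qi] != struct_seq[si]:
                mismatches += 1
            mapping[qi] = si
    if aligned_cols == 0 or mismatches / aligned_cols > max_mismatch:
        raise AlignmentError(
            "query/structure mismatch: aligned query disagrees with the "
            f"structure sequence at {mismatches}/{aligned_cols} positions"
        )
    return mapping


def map_alignment_to_structure(msa: MultipleAlignment,
                               structure: ProteinStructure,
                               query_id: str,
                               background: str | np.ndarray = "alignment",
                               weighting: str = "none",
                               max_gap_fraction: float = 0.5) -> ConservationProfile:
    """Project per-column KL scores onto structure residues via the
    query row.  Residues outside the aligned region stay NaN."""
    qrow = msa.row(query_id)
    col_scores = conservation_scores(msa, background, weighting, max_gap_fraction)

    # ungapped query position -> alignment column
    q2col: list[int] = [j for j, c in enumerate(qrow) if c != GAP]
    query_ungapped = "".join(c for c in qrow if c != GAP)

    struct_seq = extract_sequence(structure)
    q2s = _map_query_to_structure(query_ungapped, struct_seq)

    n = structure.n_residues
    scores = np.full(n, MISSING)
    columns = np.zeros(n, dtype=int)
    for qi, si in q2s.items():
        col = q2col[qi]
        scores[si] = col_scores[col]
        columns[si] = col + 1
    coverage = float(np.mean(columns > 0))
    if coverage < 1.0:
        logger.info("conservation mapped for %.0f%% of structure residues",
                    100 * coverage)
    return ConservationProfile(scores=scores, column_of_residue=columns,
                               coverage=coverage)


def conservation_to_tsv(profile: ConservationProfile,
                        structure: ProteinStructure) -> str:
    rows = ["residue_index\tauthor_number\tkl_bits\talignment_column"]
    for res, s, c in zip(structure.residues, profile.scores,
                         profile.column_of_residue):
        sval = "NA" if math.isnan(s) else f"{s:.4f}"
        rows.append(f"{res.index}\t{res.author_number}\t{sval}\t{c or 'NA'}")
    return "\n".join(rows) + "\n"
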