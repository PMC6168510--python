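"""Split-site selection: smoothing, allowed ranges, filters, ranking.

The selection algorithm operates on the split-energy profile:

(A) the raw profile is smoothed with a sliding window of size 3,
    repeated five times;
(B) the derivative of the smoothed profile is computed, cuts with
    |E'| < 0.5 are grouped into maximal consecutive intervals;
(C) each interval is iteratively extended to the adjacent cut while
    |E_adjacent - E_boundary| < E_tr, where E_tr = |E_min|/20 and E_min
    is the global minimum of the smoothed profile; overlapping
    intervals are then merged;
(D) intervals corresponding to minima of the profile (the smoothed
    energy immediately outside both ends is higher than the respective
    boundary values) are discarded, as are intervals whose borders
    touch the chain termini.

Because the default contact potential is on an arbitrary energy scale,
the profile is rescaled before steps A-D so its global minimum equals a
reference value (-20 by default), which makes the derivative threshold
0.5 and E_tr = 1 meaningful for any pairwise table; rescaling can be
switched off to apply the thresholds on the native scale.

A pair of consecutive residues (i, i+1) is a candidate split site when
both residues' solvent accessible areas exceed 30 Å², both
conservation scores are below 2 bits, and at least one residue of the
pair lies in a loop.  Within each loop candidates are ordered by
SAA_i + SAA_j and only the top one or two survive (the second only if
more than five residues from the first).  Surviving candidates inside
allowed ranges are ranked: tight loops first, then by split energy with
the highest (least destabilizing, closest to zero) energy first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields

import numpy as np

from splitscan.energetics import SplitEnergyProfile
from splitscan.geometry_annotation import LoopSegment, SurfaceAnnotation
from splitscan.sequence_conservation import ConservationProfile
from splitscan.structure_io import ProteinStructure

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """All thresholds of the selection pipeline.

    Defaults follow the published procedure; energy-scale quantities
    (derivative_threshold, the E_tr divisor) assume the profile has
    been rescaled so its minimum is ``rescale_min``.
    """

    saa_threshold: float = 30.0          # Å², per residue of the pair
    kl_threshold: float = 2.0            # bits, strict "<"
    derivative_threshold: float = 0.5    # on the rescaled profile
    smoothing_window: int = 3
    smoothing_passes: int = 5
    e_tr_divisor: float = 20.0           # E_tr = |E_min| / divisor
    tightness_distance: float = 10.0     # Å
    tightness_min_pairs: int = 3
    flank_size: int = 5
    per_loop_max: int = 2
    per_loop_min_separation: int = 5     # residues, strict ">"
    match_tolerance: int = 2             # residues, inclusive
    rescale_min: float = -20.0           # 0 disables rescaling
    rank_order: str = "se"               # "se": highest SE first; "abs": |SE| first
    # structural / conservation knobs passed through to upstream modules
    distance_definition: str = "cbeta"
    contact_cutoff: float = 7.5
    min_sequence_separation: int = 2
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    conservation_background: str = "alignment"
    conservation_weighting: str = "none"

    def __post_init__(self):
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing window must be odd")
        for name in ("saa_threshold", "kl_threshold", "derivative_threshold",
                     "e_tr_divisor", "tightness_distance", "probe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rank_order not in ("se", "abs"):
            raise ValueError("rank_order must be 'se' or 'abs'")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "Config":
        """Read a plain-text ``key = value`` configuration file."""
        values: dict = {}
        valid = {f.name: f.type for f in dc_fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
                values[key] = _coerce(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str):
    low = raw.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


@dataclass
class AllowedRanges:
    """Intervals of allowed cut positions (1-based, inclusive)."""

    intervals: list[tuple[int, int]]
    e_min: float
    e_tr: float

    def __contains__(self, cut: int) -> bool:
        return any(s <= cut <= e for s, e in self.intervals)


@dataclass
class SplitSiteCandidate:
    i: int                 # residue index; the cut is between i and i+1
    j: int
    loop_id: int
    saa_i: float
    saa_j: float
    cons_i: float
    cons_j: float
    se: float              # smoothed (rescaled) split energy at cut i
    in_allowed: bool
    tight: bool
    rank: int | None = None

    @property
    def saa_sum(self) -> float:
        return self.saa_i + self.saa_j


def smooth_profile(values: np.ndarray, window: int = 3,
                   passes: int = 5) -> np.ndarray:
    """Repeated sliding-window mean; the window truncates at the ends."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("profile too short to smooth")
    if window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    if window > len(v):
        raise ValueError("smoothing window exceeds profile length")
    half = window // 2
    for _ in range(passes):
        out = np.empty_like(v)
        for k in range(len(v)):
            lo = max(0, k - half)
            hi = min(len(v), k + half + 1)
            out[k] = v[lo:hi].mean()
        v = out
    return v


def profile_derivative(smoothed: np.ndarray) -> np.ndarray:
    """Central differences; one-sided at the two ends."""
    v = np.asarray(smoothed, dtype=float)
    if len(v) < 3:
        raise ValueError("profile too short for a derivative")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / 2.0
    d[0] = v[1] - v[0]
    d[-1] = v[-1] - v[-2]
    return d


def finalize_profile(profile: SplitEnergyProfile,
                     config: Config | None = None) -> SplitEnergyProfile:
    """Smooth, differentiate and (by default) rescale the profile so the
    global smoothed minimum equals ``config.rescale_min``."""
    if config is None:
        config = Config()
    smoothed = smooth_profile(profile.values, config.smoothing_window,
                              config.smoothing_passes)
    factor = 1.0
    if config.rescale_min != 0:
        mn = smoothed.min()
        if mn < 0:
            factor = abs(config.rescale_min) / abs(mn)
    values = profile.values * factor
    smoothed = smoothed * factor
    profile.values = values
    profile.smoothed = smoothed
    profile.derivative = profile_derivative(smoothed)
    profile.scale_factor = factor
    return profile


def _merge(intervals: list[list[int]]) -> list[list[int]]:
    """Merge intervals that overlap or form one contiguous cut range."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0][:]]
    for s, e in intervals[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def reconstruct_allowed_ranges(profile: SplitEnergyProfile,
                               config: Config | None = None) -> AllowedRanges:
    """Steps B-D of the selection algorithm (see module docstring).

    The profile must carry ``smoothed`` and ``derivative`` tracks; call
    :func:`finalize_profile` first if it does not.
    """
    if config is None:
        config = Config()
    if profile.smoothed is None or profile.derivative is None:
        finalize_profile(profile, config)
    sm = profile.smoothed
    dv = profile.derivative
    n = len(sm)
    e_min = float(sm.min())
    e_tr = abs(e_min) / config.e_tr_divisor

    # (B) flat cuts -> maximal consecutive intervals (1-based cut indices)
    flat = np.abs(dv) < config.derivative_threshold
    intervals: list[list[int]] = []
    k = 0
    while k < n:
        if flat[k]:
            j = k
            while j < n and flat[j]:
                j += 1
            intervals.append([k + 1, j])
            k = j
        else:
            k += 1

    # (C) extension against the running boundary value
    for iv in intervals:
        while iv[0] > 1 and abs(sm[iv[0] - 2] - sm[iv[0] - 1]) < e_tr:
            iv[0] -= 1
        while iv[1] < n and abs(sm[iv[1]] - sm[iv[1] - 1]) < e_tr:
            iv[1] += 1
    intervals = _merge(intervals)

    # (D) discard terminal-touching intervals and minima intervals
    kept: list[tuple[int, int]] = []
    for s, e in intervals:
        if s <= 1 or e >= n:
            logger.info("interval %d-%d discarded: touches a chain terminus", s, e)
            continue
        left_up = sm[s - 2] > sm[s - 1]
        right_up = sm[e] > sm[e - 1]
        if left_up and right_up:
            logger.info("interval %d-%d discarded: profile minimum", s, e)
            continue
        kept.append((s, e))
    return AllowedRanges(intervals=kept, e_min=e_min, e_tr=e_tr)


def enumerate_candidates(structure: ProteinStructure,
                         profile: SplitEnergyProfile,
                         annotation: SurfaceAnnotation,
                         conservation: ConservationProfile,
                         allowed: AllowedRanges,
                         config: Config | None = None) -> list[SplitSiteCandidate]:
    """All residue pairs (i, i+1) passing the SAA / conservation / loop
    filters, annotated with split energy and allowed-range membership."""
    if config is None:
        config = Config()
    if profile.smoothed is None:
        finalize_profile(profile, config)
    saa = annotation.saa
    cons = conservation.scores
    out: list[SplitSiteCandidate] = []
    for i in range(1, structure.n_residues):  # cut i between residues i, i+1
        j = i + 1
        si, sj = float(saa[i - 1]), float(saa[j - 1])
        if si <= config.saa_threshold or sj <= config.saa_threshold:
            continue
        ci, cj = float(cons[i - 1]), float(cons[j - 1])
        if np.isnan(ci) or np.isnan(cj):
            logger.info("pair (%d,%d) excluded: conservation unavailable", i, j)
            continue
        if not (ci < config.kl_threshold and cj < config.kl_threshold):
            continue
        loop_id = annotation.loop_of(i)
        if loop_id is None:
            loop_id = annotation.loop_of(j)
        if loop_id is None:
            continue
        out.append(SplitSiteCandidate(
            i=i, j=j, loop_id=loop_id,
            saa_i=si, saa_j=sj, cons_i=ci, cons_j=cj,
            se=float(profile.smoothed[i - 1]),
            in_allowed=i in allowed,
            tight=annotation.loops[loop_id].tight,
        ))
    return out


def select_per_loop(candidates: list[SplitSiteCandidate],
                    config: Config | None = None) -> list[SplitSiteCandidate]:
    """Keep the top candidate per loop by SAA sum, plus the second-ranked
    one when it is more than ``per_loop_min_separation`` residues away.

    Only the top two by SAA sum are ever considered: a second site that
    fails the separation rule is dropped, not replaced by the third.
    """
    if config is None:
        config = Config()
    by_loop: dict[int, list[SplitSiteCandidate]] = {}
    for c in candidates:
        by_loop.setdefault(c.loop_id, []).append(c)
    kept: list[SplitSiteCandidate] = []
    for loop_id in sorted(by_loop):
        group = sorted(by_loop[loop_id], key=lambda c: (-c.saa_sum, c.i))
        kept.append(group[0])
        if config.per_loop_max >= 2 and len(group) > 1:
            second = group[1]
            if abs(second.i - group[0].i) > config.per_loop_min_separation:
                kept.append(second)
            else:
                logger.info(
                    "loop %d: second site %d within %d residues of top site %d; dropped",
                    loop_id, second.i, config.per_loop_min_separation, group[0].i)
    return sorted(kept, key=lambda c: c.i)


def rank_predictions(candidates: list[SplitSiteCandidate],
                     config: Config | None = None) -> list[SplitSiteCandidate]:
    """Rank allowed candidates: tight loops first, then by split energy
    (highest first by default; ``rank_order="abs"`` ranks by magnitude),
    ties broken by lower residue index.  Ranks are assigned in place."""
    if config is None:
        config = Config()
    allowed = [c for c in candidates if c.in_allowed]
    if config.rank_order == "abs":
        key = lambda c: (not c.tight, -abs(c.se), c.i)
    else:
        key = lambda c: (not c.tight, -c.se, c.i)
    ranked = sorted(allowed, key=key)
    for r, c in enumerate(ranked, 1):
        c.rank = r
    return ranked


def match_experimental(predicted: list[int], experimental: list[int],
                       tolerance: int = 2) -> list[dict]:
    """Per experimental site: hit iff some predicted site is within
    ``tolerance`` residues; the match is the nearest predicted site
    (lower index on distance ties)."""
    table = []
    for e in experimental:
        best = None
        if predicted:
            best = min(predicted, key=lambda p: (abs(p - e), p))
        hit = best is not None and abs(best - e) <= tolerance
        table.append({
            "experimental": e,
            "hit": hit,
            "predicted": best if hit else None,
            "distance": abs(best - e) if best is not None else None,
        })
    return table


def predictions_to_tsv(candidates: list[SplitSiteCandidate],
                       structure: ProteinStructure,
                       annotation: SurfaceAnnotation) -> str:
    """Report rows for ranked predictions followed by filtered-but-
    disallowed candidates (rank NA, in_allowed false)."""
    rows = ["rank\tchain\tres_i\tres_j\tloop\ttight\tsaa_i\tsaa_j\t"
            "cons_i\tcons_j\tSE_smoothed\tin_allowed"]
    order = sorted(candidates,
                   key=lambda c: (c.rank is None, c.rank if c.rank else 0, c.i))
    num = structure.author_numbering()
    for c in order:
        lp = annotation.loops[c.loop_id]
        rows.append("\t".join([
            str(c.rank) if c.rank is not None else "NA",
            structure.chain_id,
            str(num[c.i]), str(num[c.j]),
            f"{lp.start}-{lp.end}",
            str(c.tight).lower(),
            f"{c.saa_i:.2f}", f"{c.saa_j:.2f}",
            f"{c.cons_i:.4f}", f"{c.cons_j:.4f}",
            f"{c.se:.4f}",
            str(c.in_allowed).lower(),
        ]))
    return "\n".join(rows) + "\n"


def report_json(candidates: list[SplitSiteCandidate],
                profile: SplitEnergyProfile,
                allowed: AllowedRanges,
                config: Config,
                structure: ProteinStructure) -> str:
    doc = {
        "chain": structure.chain_id,
        "n_residues": structure.n_residues,
        "config": asdict(config),
        "profile": {
            "raw": [round(float(x), 6) for x in profile.values],
            "smoothed": [round(float(x), 6) for x in profile.smoothed],
            "derivative": [round(float(x), 6) for x in profile.derivative],
            "scale_factor": profile.scale_factor,
        },
        "allowed_ranges": {
            "intervals": [list(iv) for iv in allowed.intervals],
            "e_min": allowed.e_min,
            "e_tr": allowed.e_tr,
        },
        "candidates": [
            {**asdict(c), "author_i": structure.residues[c.i - 1].author_number,
             "author_j": structure.residues[c.j - 1].author_number}
            for c in candidates
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)
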