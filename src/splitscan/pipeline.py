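"""End-to-end prediction: structure + alignment in, ranked sites out."""

from __future__ import annotations

import logging
import os
from pathlib import Path

from splitscan import energetics, geometry_annotation, sequence_conservation
from splitscan.energetics import (PairwisePotential, default_potential,
                                  load_potential, profile_to_tsv,
                                  split_energy_profile)
from splitscan.geometry_annotation import annotate, annotation_to_tsv
from splitscan.sequence_conservation import (conservation_to_tsv,
                                             map_alignment_to_structure,
                                             read_alignment)
from splitscan.site_selection import (Config, enumerate_candidates,
                                      finalize_profile, predictions_to_tsv,
                                      rank_predictions,
                                      reconstruct_allowed_ranges, report_json,
                                      select_per_loop)
from splitscan.structure_io import read_structure

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("profile.tsv", "tracks.tsv", "conservation.tsv",
                "predictions.tsv", "report.json", "run.log")


def read_ss_file(path: str) -> str:
    """External secondary-structure input: either a bare one-line string
    or two whitespace-separated columns (residue index, class)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()
                 and not ln.startswith("#")]
    if len(lines) == 1 and " " not in lines[0] and "\t" not in lines[0]:
        return lines[0]
    pairs = []
    for ln in lines:
        parts = ln.split()
        if len(parts) < 2:
            raise ValueError(f"bad secondary-structure line: {ln!r}")
        pairs.append((int(parts[0]), parts[1]))
    pairs.sort()
    return "".join(c for _, c in pairs)


def run_pipeline(structure_path: str, msa_path: str, output_dir: str,
                 config: Config | str | None = None,
                 chain: str | None = None, model: int = 1,
                 query_id: str | None = None,
                 ss_path: str | None = None,
                 potential: PairwisePotential | str | None = None) -> dict:
    """Run the full prediction and write the report files.

    Returns a summary dict (paths, counts, ranked sites).  Zero
    predictions is a normal outcome.  On any module error the partial
    outputs are removed and the exception propagates.
    """
    if config is None:
        config = Config()
    elif isinstance(config, str):
        config = Config.from_file(config)
    if potential is None:
        potential = PairwisePotential(
            contact_matrix=default_potential().contact_matrix,
            distance_definition=config.distance_definition,
            cutoff=config.contact_cutoff,
            min_sequence_separation=config.min_sequence_separation,
        )
    elif isinstance(potential, str):
        potential = load_potential(
            potential,
            distance_definition=config.distance_definition,
            cutoff=config.contact_cutoff,
            min_sequence_separation=config.min_sequence_separation,
        )

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("splitscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        structure = read_structure(structure_path, chain=chain, model=model)
        logger.info("structure: chain %s, %d residues",
                    structure.chain_id, structure.n_residues)

        profile = split_energy_profile(structure, potential)
        finalize_profile(profile, config)
        allowed = reconstruct_allowed_ranges(profile, config)
        logger.info("allowed ranges: %s (E_min=%.3f, E_tr=%.3f)",
                    allowed.intervals, allowed.e_min, allowed.e_tr)

        external_ss = read_ss_file(ss_path) if ss_path else None
        annotation = annotate(
            structure, external_ss=external_ss,
            probe_radius=config.probe_radius,
            n_sphere_points=config.n_sphere_points,
            tightness_distance=config.tightness_distance,
            tightness_min_pairs=config.tightness_min_pairs,
            flank_size=config.flank_size)
        if not annotation.loops:
            logger.info("no loops in the secondary structure; "
                        "no candidate sites possible")

        msa = read_alignment(msa_path)
        qid = query_id or msa.sequences[0][0]
        conservation = map_alignment_to_structure(
            msa, structure, qid,
            background=config.conservation_background,
            weighting=config.conservation_weighting)

        candidates = enumerate_candidates(structure, profile, annotation,
                                          conservation, allowed, config)
        selected = select_per_loop(candidates, config)
        ranked = rank_predictions(selected, config)
        logger.info("%d filtered candidates, %d after per-loop selection, "
                    "%d ranked predictions",
                    len(candidates), len(selected), len(ranked))

        (out / "profile.tsv").write_text(profile_to_tsv(profile, structure))
        (out / "tracks.tsv").write_text(annotation_to_tsv(annotation, structure))
        (out / "conservation.tsv").write_text(
            conservation_to_tsv(conservation, structure))
        (out / "predictions.tsv").write_text(
            predictions_to_tsv(selected, structure, annotation))
        (out / "report.json").write_text(
            report_json(selected, profile, allowed, config, structure) + "\n")

        num = structure.author_numbering()
        return {
            "output_dir": str(out),
            "n_residues": structure.n_residues,
            "n_candidates": len(candidates),
            "n_selected": len(selected),
            "n_ranked": len(ranked),
            "allowed_ranges": allowed.intervals,
            "predictions": [
                {"rank": c.rank, "i": c.i, "j": c.j,
                 "author_i": num[c.i], "author_j": num[c.j],
                 "tight": c.tight, "se": c.se}
                for c in ranked
            ],
        }
    except Exception:
        for name in OUTPUT_FILES:
            p = out / name
            if p.exists() and name != "run.log":
                p.unlink()
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
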