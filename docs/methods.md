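# Methods

## Model

A split site is modelled as a cut between consecutive residues i and
i+1 of a single chain. The cut's cost is the split energy
SE(i) = E_N − (E_A + E_B): the energy of the intact structure minus
the summed energies of the two halves, both halves scored with
unchanged coordinates (no relaxation). Under any pairwise-additive
energy this telescopes to the sum of pair energies straddling the cut,
which is how the implementation computes the whole profile in one pass
(a difference-array accumulation over contacts); the three-evaluation
form is retained as a test invariant and must agree to 1e-9.

Assumptions: rigidity (the halves keep their fold), additivity (no
many-body terms), and a single chain (multi-chain complexes are scored
per selected chain; interactions with other chains are ignored, which
underestimates the cost of cutting interface-proximal cores).

## Energy function

The published procedure scores structures with an all-atom force
field. Re-implementing one is out of scope here; instead the energy is
a residue-level statistical contact potential: a symmetric 20×20 table
applied when the Cβ–Cβ distance (Cα for glycine or when Cβ is absent)
is within 7.5 Å and the sequence separation is ≥ 2. Distance
definition (`cbeta`, `ca`, heavy-atom `min`), cutoff and separation are
configurable.

The shipped table is additive: e_ij = −(h′_i + h′_j)/2 with h′ a
Kyte–Doolittle hydropathy shifted to (h + 5)/2, giving energies in
[−4.75, −0.25] (arbitrary attractive units). The one-body
(hydrophobic) component is the dominant factor of the classic
statistical contact matrices, and for this method only the *shape* of
the profile matters: with every entry attractive, SE ≤ 0 everywhere
and wells appear exactly where many contacts cross a cut. Any
user-supplied 20×20 plain-text table (header row/column of one-letter
codes) can replace it.

Because the absolute scale is arbitrary, the profile is rescaled before
segmentation so the global minimum of the smoothed profile equals
`rescale_min` (default −20). This makes the derivative threshold 0.5
and the extension threshold E_tr = |E_min|/20 = 1 meaningful for any
potential; setting `rescale_min = 0` disables rescaling for users whose
potential is already on the intended scale.

## Allowed-range reconstruction

1. Smooth the raw profile with a centred window of 3 (truncated at the
   ends), repeated 5 times.
2. Differentiate (central differences; one-sided at the ends) and group
   cuts with |E′| < 0.5 into maximal consecutive intervals.
3. Extend each interval cut-by-cut while the adjacent smoothed energy
   differs from the *running* boundary value by less than E_tr
   (the alternative — comparing against the original boundary — gives
   systematically shorter extensions; the running-boundary reading was
   chosen because the step is described as iterative). Merge intervals
   that afterwards overlap or form one contiguous cut range.
4. Discard intervals whose border touches the first or last cut, and
   intervals that sit in a basin — the smoothed energy immediately
   outside *both* ends higher than the respective boundary values.
   Shoulder intervals (up on one side, down on the other) are kept:
   the intent of the discard step is to remove well bottoms, and the
   basin test is the weakest condition that does so.

An independently coded step-by-step walker (plain loops, no shared
code) reproduces the implementation's intervals on synthetic
plateau/well profiles and on 200 random-walk profiles per run.

## Filters

A pair (i, i+1) is a candidate iff **both** residues have SAA > 30 Å²,
**both** have conservation < 2 bits (strict), and at least one residue
is in a loop. The ambiguous published exposure test ("their solvent
accessible area exceeds 30 Å²") is applied per residue, not to the
sum — the stricter reading, consistent with a single 27 Å² residue
disqualifying a site. Candidates with missing conservation are
excluded and logged. Per loop, candidates are ordered by
SAA_i + SAA_j; the best survives, the second-best survives only if
more than 5 residues from the best (it is dropped, not replaced by the
third). Candidates outside allowed ranges stay in the report with
`in_allowed = false` but are excluded from ranking.

### Solvent accessibility

Shrake–Rupley with a golden-spiral point set: per atom, the fraction
of points on the expanded sphere (r_vdw + 1.4 Å) not covered by any
neighbouring expanded sphere, times the sphere area; residue SAA is
the per-atom sum. Van der Waals radii are Bondi (C 1.70, N 1.55,
O 1.52, S 1.80; 1.70 default). The implementation agrees with
Biopython's `ShrakeRupley` to machine precision on identical inputs.
At the 960-point default the residual sampling noise on partially
occluded atoms is 1–2% per doubling of the point count, dropping below
1% from 1920 points; the isolated-sphere area is exact at any point
count. Analytic SASA programs such as Stride differ from Shrake–Rupley
by a few Å² per residue, which is why the 30 Å² threshold is
configurable.

### Secondary structure and loops

If an external annotation is supplied (DSSP/Stride-style) it is
normalized (G/I→H, B→E, else C) and used verbatim. Otherwise a φ/ψ
heuristic assigns H for φ ∈ [−120°, −30°], ψ ∈ [−80°, −5°] and E for
φ ∈ [−180°, −90°], ψ ∈ [90°, 180°], each requiring ≥ 3 consecutive
residues; everything else (including polyproline-II, deliberately
outside the E basin) is coil. This is a stand-in for hydrogen-bond
based assignment and is the least reliable component on real
structures — users with Stride/DSSP output should supply it. Loops are
maximal coil runs.

### Loop tightness

Flanks are the up-to-5 residues on each side of a loop, skipping
residues that belong to other loops (skipped, not replaced — the
literal reading of the flank definition). Each left-flank residue is
paired with its nearest right-flank residue by Cα distance ("closest
residue on the right" is interpreted as nearest within the flank, Cα
being the only atom guaranteed present); the loop is tight iff ≥ 3
pairs are closer than 10 Å. Fewer than 3 usable left-flank residues ⇒
not tight, with a logged reason.

## Ranking and matching

Sites in tight loops precede sites in loose loops; within a class,
higher (closer to zero) smoothed SE first; ties go to the lower
residue index. The source material states the energy ordering in two
conflicting ways ("higher split energy first" in the procedure,
"absolute value" in the narrative); the procedural reading is the
default and `rank_order = abs` selects the other. A predicted site
matches an experimental one iff |Δ| ≤ 2 residues (nearest predicted
site reported; lower index on distance ties).

## Synthetic data

The generators make the pipeline testable without downloads; all are
deterministic per seed.

* **Dumbbell** (`generate_dumbbell`): two compact lobes — jittered
  cubic lattices (4.0 Å spacing, σ = 0.25 Å) of pseudo-residues with
  Cα and a 3-atom Cβ–Cγ–Cδ side chain in a random direction — joined
  by a linker arcing 8 Å off the lobe–lobe axis with 4.0 Å spacing,
  ends 5 Å clear of the lobe surfaces. Defaults: 32 residues per lobe,
  8-residue linker. By construction no lobe–lobe atom pair is within
  the contact cutoff, so at least one linker cut has SE = 0 exactly,
  and the arc makes mid-linker residues the most solvent-exposed, as
  the flanks of a real surface loop are packed against the body. The
  chain order inside each lobe is shuffled so burial is uncorrelated
  with sequence position. With `linker_length = 0` the lobes
  interpenetrate by one lattice spacing, modelling a fused single
  body with no zero-SE cut. What the dumbbell does **not** emulate:
  real secondary structure (the pseudo-residues lack N/C atoms, so the
  torsion heuristic reads the whole chain as one loop), realistic
  side-chain packing, or conservation structure — so dumbbell recovery
  demonstrates the energy/exposure/segmentation machinery, not the
  loop segmentation or tightness ranking on real folds.
* **Torsion-built peptides** (`build_peptide`): ideal-geometry
  backbones (N, Cα, C, O, Cβ; standard lengths/angles, trans ω) from a
  φ/ψ list via natural-extension-of-reference-frame placement; used
  for helix/strand/coil fixtures whose secondary structure is known by
  construction, and validated by round-tripping the requested
  torsions.
* **Hairpin**: a Cα-only antiparallel two-strand geometry (4.8 Å
  strand separation) for tightness tests.
* **MSA generator**: aligned FASTA whose first row is the ungapped
  query; chosen columns carry the query residue in every row (KL =
  log2(20) against a uniform background), all other columns are drawn
  uniformly per row (expected KL ≈ 19/(2 ln 2 · n_rows) bits, well
  under the 2-bit threshold at the 50-row default).

## Conservation scoring

Per column, KL = Σ p_a log2(p_a/q_a) over amino acids with p_a > 0.
Gaps ('-' and '.') are excluded from counts; columns over 50% gaps are
marked missing (NaN), as are residues outside the aligned region —
missing values *exclude* a candidate rather than passing it. The
background q defaults to the alignment's own composition (with a 1e-4
pseudocount so q > 0); uniform background and Henikoff position-based
weighting are selectable. The published score has several variants;
the 2-bit threshold is honoured on whichever variant is configured,
and thresholds should be recalibrated if the background convention is
changed. Query-to-structure mapping uses identity when possible, else
a global pairwise alignment (match 2, mismatch −1, open −5,
extend −0.5), rejecting mappings with > 5% mismatches.

## Numerical and degenerate-input choices

* Cuts are indexed 1..N−1; "a split at residue i" in reports means the
  cut between i and i+1, printed with both internal and author
  numbering.
* Profile values with |SE| < 1e-12 after accumulation are snapped to
  zero (float dust from cancelling contributions).
* Empty allowed ranges, zero candidates and zero predictions are
  normal outcomes, reported with exit status 0.
* Structures with N < 3 are rejected; missing Cα is a warning (the
  residue is kept, flagged); unresolved gaps in author numbering are
  warned about, never bridged with placeholders, because a cut across
  an unresolved region is not meaningful.
* E_min ≥ 0 (a profile with no negative values) gives E_tr = 0: no
  extension happens, which is the correct degenerate behaviour.

## Problem sizes in tests

The suite runs the full pipeline on 24 dumbbell seeds (~70 residues,
~280 atoms each) and verifies the decomposition identity on 100 random
30-residue structures; both finish in seconds and are statistically
stable across seed windows (recovery 117/120 over five disjoint
24-seed windows during development).

## Known limitations

* The φ/ψ secondary-structure heuristic has no hydrogen-bond evidence;
  supply Stride/DSSP output for production use.
* The contact potential captures hydrophobic burial only; polar
  specificity (salt bridges, disulfides) is invisible, so profiles of
  proteins stabilized mainly by such interactions will understate
  their cores.
* Per-chain scoring ignores interfaces in complexes.
* The rescaling convention ties the 0.5 derivative threshold to the
  depth of the deepest well; proteins with one dominant and several
  shallow cores may see the shallow cores under-protected. The
  thresholds are exposed in `Config` for exactly this reason.
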