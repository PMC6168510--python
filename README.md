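# splitscan

Structure-guided prediction of **split sites** for split-protein design.

Splitting a protein into two fragments whose activity is restored only
upon induced reassembly (chemically induced dimerization, e.g.
FKBP/FRB + rapamycin) is a powerful way to put enzymes, GEFs, GDIs and
proteases under external control. The hard part is choosing the
scission point: cut inside a folding core and the halves misfold; cut a
conserved or buried position and activity never returns. `splitscan`
automates the choice from a structure and a family alignment.

## The method

For a chain of N residues, each cut point i (between residues i and
i+1) gets a **split energy**

```
SE(i) = E_N − (E_A + E_B)
```

where E_N is the energy of the intact structure and E_A, E_B are the
energies of the two rigid halves (residues 1..i and i+1..N). With a
pairwise-additive potential this is exactly the interaction energy
crossing the cut, so SE ≤ 0: deep wells mark folding cores that must
not be cut, plateaus near zero mark safe regions. The default potential
is a residue-level 20×20 contact table (Cβ–Cβ distance, 7.5 Å cutoff,
sequence separation ≥ 2); any plain-text table can be substituted, and
the profile is rescaled (global minimum → −20) so downstream
thresholds are scale-free.

The profile is smoothed (window 3, five passes) and segmented into
**allowed ranges**: near-flat stretches (|E′| < 0.5) are extended while
the adjacent energy stays within E_tr = |E_min|/20, merged, and pruned
of intervals that sit in energy minima or touch the chain termini.

Candidate sites are consecutive pairs (i, i+1) where both residues have
solvent accessible area > 30 Å² (Shrake–Rupley, 960 points, 1.4 Å
probe), both have Kullback–Leibler sequence conservation < 2 bits, and
at least one lies in a loop. Within each loop only the one or two most
exposed sites survive (the second only if more than five residues from
the first). Sites inside allowed ranges are ranked: loops whose flanks
bend back on themselves (**tight** loops, ≥ 3 flank pairs within 10 Å)
first, then by split energy, highest first.

## Worked example

No downloads needed — the package generates its own test structures.
A "dumbbell" fixture has two compact lobes joined by an exposed
8-residue linker (residues 33–40 here), the only sensible place to cut:

```
$ splitscan fixture dumbbell --seed 5 --out demo.pdb --msa-out family.fasta
dumbbell written to demo.pdb; true split region: cuts 32-40
matching family alignment written to family.fasta
$ splitscan predict --pdb demo.pdb --msa family.fasta --out out
1 split site(s) predicted:
  rank 1: residues 33-34 (SE -0.72, loose loop)
report written to out
```

The rank-1 site falls between residues 33 and 34 — inside the linker.
`out/predictions.tsv` carries the full evidence per site:

```
rank  chain  res_i  res_j  loop  tight  saa_i   saa_j   cons_i  cons_j  SE_smoothed  in_allowed
1     A      33     34     1-72  false  179.63  148.94  0.3269  0.4035  -0.7239      true
```

Both residues are highly exposed (SAA ≫ 30 Å²), unconserved (≪ 2
bits), and the cut's smoothed split energy is near zero — no folding
core is disturbed. `out/` also contains the raw/smoothed profile
(`profile.tsv`), per-residue SAA/secondary-structure/loop tracks
(`tracks.tsv`, `conservation.tsv`) and a JSON report echoing the full
configuration.

Predictions can be scored against known sites with the published
two-residue tolerance:

```
$ splitscan match --predicted 268,279 --experimental 268,300
experimental 268: hit (predicted 268)
experimental 300: miss
1/2 experimental sites matched within 2 residues
```

Library use mirrors the CLI: `read_structure`, `split_energy_profile`,
`reconstruct_allowed_ranges`, `annotate`, `map_alignment_to_structure`,
`enumerate_candidates`, `select_per_loop`, `rank_predictions`, or
`run_pipeline` for the whole chain of steps.

## Scope

`splitscan` scores rigid structures with a configurable pairwise
potential; it does not run molecular dynamics, build homology models,
repair structures, or design the fusion constructs themselves.
Profiles are computed per selected chain.
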