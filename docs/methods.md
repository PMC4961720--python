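# Methods

## Descriptor definitions and scale provenance

All six descriptors are compositional: they depend only on residue counts,
never on residue order. Four versioned plain-text scales ship under
`src/pepscan/data/scales/` and are the package's calibration surface:

* `boman` — sign-inverted cyclohexane→water transfer free energies of the
  side-chain analogues (Radzicka & Wolfenden 1988), oriented so hydrophilic
  residues are positive (D +8.72, L −4.92 kcal/mol). The Boman index is the
  *mean* over residues. Proline has no measured analogue value and is
  assigned 0.0; tyrosine is +0.14 (the orientation used in the
  protein-binding-potential literature). Neither residue occurs in the
  bundled study sequences, so neither assignment affects any calibrated
  value.
* `kyte_doolittle` — the standard hydropathy scale; GRAVY is its mean.
* `ww_interface` — Wimley–White *whole-residue* water→POPC-interface
  transfer free energies, using the charged-side-chain values for Asp/Glu
  and the neutral value for His. This variant choice is forced by
  calibration: it is the only combination that reproduces the published
  interface sums (e.g. 1.75 kcal/mol for the parent peptide and −0.26 for
  its E3G mutant). The descriptor is the whole-peptide **sum**, not a mean.
* `residue_mass` — average residue masses; molecular weight adds one water
  and supports C-terminal amidation (−0.98 Da) and N-acetylation
  (+42.04 Da). Free termini are the default because the published panel
  values match free-acid masses even though the NMR samples were amidated.

Net charge is the side-chain-only model (K/R = +1, D/E = −1, H = 0, termini
ignored) — the only integer model consistent with every published charge.
The hydrophobic set is {A,C,F,I,L,M,V,W}; glycine is excluded (MTP1's 60%
forces this).

## Display truncation

Published descriptor values are truncated toward zero at the printed
precision, not rounded (e.g. a Boman sum of 17.23 over 13 residues, mean
1.3254, prints as 1.32; −25.30/15 = −1.6867 prints as −1.68). Internal
computation keeps full float precision; `truncate_toward_zero` applies the
display rule through decimal arithmetic with a 9-decimal guard so that
values that are exact in rational arithmetic (1.3/13 = 0.1) are not pushed
down a digit by binary floating-point noise. The source scan table's GRAVY
column does not follow any single convention — two rows with identical
sequences print different values — so a handful of its GRAVY cells are
irreproducible by construction; every other column reproduces cell-for-cell
under truncation.

## Design procedure

`reactive_positions` ranks scan rows by the improvement (delta vs parent) of
a chosen descriptor, Boman index by default. The criterion is a parameter
because the underlying selection rule is a modelling choice; BI-improvement
top-k recovers the positions {8, 10, 12} highlighted for the CPT-1a parent.
Deltas are quantized to 9 decimals before ranking so that mathematically
tied positions (identical substitutions whose sums accumulate in different
orders) compare equal and fall back to the position-ascending tie-break;
ties with the k-th value are all returned.

`enumerate_candidates` performs an exhaustive assignment of alphabet
residues to subsets of the chosen positions, sizes 1..max_subs. By default
each alphabet residue is placed **at most once** (injective assignment) —
the reading under which the published {K, D} × {8, 12} design is optimal at
BI 2.06; with `allow_repeats=True` the search also considers e.g. D at both
positions, which scores higher (BI 2.30) but doubles the negative charge.
Identity substitutions are skipped. Ranking is by the criterion value
descending with a stable deterministic tie-break (fewer substitutions first,
then positions ascending, then the alphabet in user-given order), which
places K@8+D@12 ahead of its score-equal mirror — all descriptors being
compositional, any assignment and its permutation score identically.

## NMR analysis

Chemical-shift deviations use a single bundled αH random-coil reference
(Wüthrich 1986 values, measured in water) in every solvent. This is the
conventional shortcut, and it carries a caveat: between-solvent comparisons
of Δδ are then exactly between-solvent comparisons of the observed shifts,
so any referencing offset between a DMSO dataset (referenced to the DMSO
residual at 2.5 ppm) and a TFE/H₂O dataset (referenced to TSP) propagates
into Δδ wholesale. In the bundled tables the mean observed αCH shift is
*lower* in DMSO than in TFE/H₂O for both peptides, so a mean-Δδ comparison
does not show the TFE helicity enhancement; the per-residue minima (e.g.
Val13 of MTP1 at Δδ = −0.46 ppm in TFE/H₂O vs 0.00 in DMSO) do.

Helix classification: residues in maximal runs of at least `min_run`
consecutive residues with Δδ below `helix_threshold` are labelled helical.
Defaults: threshold −0.1 ppm (the conventional cutoff; deviations within
±0.1 ppm are treated as coil), `min_run` = 4 (one helical turn — the rule
itself states no run length, so this is a package choice exposed as a
parameter). Residues without an αCH record stay "unassigned" and break
runs; glycine diastereotopic αH pairs are stored as their mean in a single
αCH record.

Restraint accounting bins upper-limit distance restraints by |i−j|:
intraresidue 0, sequential 1, medium-range 2–4, long-range > 4; torsion
restraints are carried as a separate count. Only category accounting is in
scope — no structure calculation, target functions or ensemble RMSDs.

## Synthetic data

The generators emulate the inputs the analyses consume, not spectra:

* `random_peptide` draws residues i.i.d. from a composition (uniform over
  the 20 by default) at a chosen length (default 15, the longer of the two
  study peptides).
* `synthetic_shift_table` plants helical segments: αCH(i) = random-coil +
  μ(i) + N(0, σ), with μ = −0.35 ppm inside segments (a typical helical αH
  secondary shift, comfortably beyond the −0.1 ppm threshold) and 0
  elsewhere; σ defaults to 0.03 ppm. NH (8.30 ppm) and βCH (1.80 ppm)
  records are filled with plausible constants so the full reader is
  exercised; the N-terminal residue gets no NH, as in real tables. What the
  recovery experiment (≥95% per-residue accuracy over 200 seeded replicates)
  does **not** show: performance under neighbour- or temperature-dependent
  random-coil corrections, missing assignments, or solvent-referencing
  offsets of the kind discussed above.
* `synthetic_restraints` produces a restraint list whose per-category counts
  match a requested template exactly (gaps drawn uniformly within each
  category's range), with feasibility checks against the peptide length.

Each generator call owns one explicitly seeded NumPy `Generator`; there is
no hidden global state, and all outputs are bit-reproducible given
(seed, config).

## Numerical and interface choices

* Score ties in ranking use a 1e-12 tolerance; scan/report serialisation
  keeps full precision so TSV/JSON reports round-trip losslessly, with
  display truncation available as an option.
* The shift-table TSV dialect is documented in `read_shift_table`; parse
  errors carry line numbers. UPL restraint files are 7-column
  whitespace-delimited text with `#` comments.
* Degenerate inputs: empty sequences, non-canonical residues, clashing or
  mismatched mutations, duplicate αCH records, infeasible restraint
  templates and unknown scale names all raise explicit `ValueError`s.
* Problem sizes in the test-suite experiments (1000 random mutation pairs
  for the incremental-update oracle, 200 replicates for helix recovery,
  100–200 fuzz cases for conservation properties) were chosen as the
  smallest sizes at which the properties are convincingly exercised; each
  runs in well under a second.

## Known limitations

* No pH-dependent charge model or isoelectric point; the integer charge
  model is the panel's convention, not an electrostatics model.
* One random-coil table for all solvents (see above).
* The hydrophobic-ratio set and the descriptor panel match the AMP-database
  conventions used for the study peptides; other tools draw the hydrophobic
  boundary differently.
* No activity prediction beyond the descriptors, no helical-wheel surface
  assignment, and no structure calculation.
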