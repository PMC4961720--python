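# pepscan

Physicochemical descriptor scanning for antimicrobial peptide (AMP) design,
with NMR chemical-shift-deviation and NOE-restraint accounting.

## The problem

Short cationic/amphipathic peptides can kill foodborne pathogens, and
candidate AMPs are often designed on paper before any synthesis: take a
biologically meaningful parent sequence, scan it residue by residue to find
the positions whose side chains hold back the predicted activity, and place
charged residues there. `pepscan` implements that workflow for the pair of
peptides MTP1 (`KVSGVLFGTGLWVAL`) and MTP2 (`MAEAHQAKAFQDT`, a designed
double mutant V8K+F12D of the CPT-1a N-terminal tail `MAEAHQAVAFQFT`),
together with the NMR bookkeeping used to characterise their conformations.

## The descriptors

For a peptide with residues $r_1 \dots r_L$:

* **Boman index** (protein-binding potential, kcal/mol):
  $\mathrm{BI} = \frac{1}{L}\sum_i b(r_i)$, where $b$ is the sign-inverted
  cyclohexane→water transfer free energy of the residue (Radzicka–Wolfenden
  values); hydrophilic residues score positive and higher BI predicts higher
  antimicrobial/protein-binding potential.
* **GRAVY**: $\frac{1}{L}\sum_i \mathrm{KD}(r_i)$, the mean Kyte–Doolittle
  hydropathy.
* **Wimley–White interface value** (kcal/mol): $\sum_i \mathrm{WW}(r_i)$,
  the whole-peptide **sum** of whole-residue water→POPC-interface transfer
  free energies (charged Asp/Glu, neutral His).
* **Net charge**: $(\#K + \#R) - (\#D + \#E)$, His neutral, termini ignored.
* **Hydrophobic ratio**: percent of residues in {A,C,F,I,L,M,V,W}, truncated.
* **Molecular weight**: sum of average residue masses plus one water (free
  termini by default; amidation supported).

The design loop is: `glycine_scan` (substitute every position with Gly and
recompute the panel) → `reactive_positions` (rank positions by how much the
substitution improves a criterion, BI by default) → `enumerate_candidates`
(exhaustively place an alphabet such as {K, D} on those positions and rank).

The NMR side reads assigned proton-shift tables (a simple TSV dialect; the
published tables for MTP1/MTP2 in DMSO and TFE/H₂O 1:1 ship as data),
computes αCH chemical-shift deviations from random coil
$\Delta\delta_i = \delta^{obs}_{\alpha H}(i) - \delta^{rc}(r_i)$, labels
helical segments (runs of ≥ 4 residues with $\Delta\delta < -0.1$ ppm), and
counts CYANA-style distance restraints by sequence separation |i−j|
(intraresidue / sequential / medium-range / long-range).

## Worked example

```python
>>> import pepscan as pp
>>> from pepscan import datasets
>>> pp.descriptor_profile(datasets.MTP2).display()
{'mol_weight': 1447.58, 'boman_index': 2.06, 'hydrophobic_ratio': 46,
 'net_charge': -1, 'gravy': -0.761, 'ww_interface': 5.03}
```

MTP2 weighs ~1447.6 Da, carries net charge −1, is 46% hydrophobic, and its
Boman index of 2.06 kcal/mol (vs 0.42 for the wild-type parent) is what the
design optimised. The same run from the shell, end to end:

```sh
$ pepscan scan --seq MAEAHQAVAFQFT --display          # 13-row glycine scan
$ pepscan design --seq MAEAHQAVAFQFT --positions 8,12 --alphabet K,D \
      --max-subs 2 --display --top 3
label          sequence       boman_index  hydrophobic_ratio  net_charge  gravy   ww_interface
wild type      MAEAHQAVAFQFT  0.42         61                 -1          0.346   1.75
-------K---D-  MAEAHQAKAFQDT  2.06         46                 -1          -0.761  5.03
-------D---K-  MAEAHQADAFQKT  2.06         46                 -1          -0.761  5.03
-------D-----  MAEAHQADAFQFT  1.4          53                 -2          -0.246  2.91
```

The top-ranked candidate is exactly MTP2 (its score-equal mirror D8+K12 is
listed second under the deterministic tie-break). On the NMR side:

```python
>>> table = datasets.load_shift_table("MTP1", "TFE_H2O_1_1")
>>> profile = pp.csd_alpha(table, pp.load_random_coil())
>>> round(profile.entries[12].delta, 2)   # Val13
-0.46
```

a deviation well below the −0.1 ppm helix threshold.

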