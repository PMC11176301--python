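# pitmatch

Cross-sectional comparison of T-cell receptor (TCR) repertoires between
body compartments, built around the question that motivates it in type 1
diabetes: do islet-antigen-reactive (IAR) CD4+ T cells circulating in
blood carry the same TCRs as pancreas-infiltrating T cells (PIT)?
Because pancreatic biopsy is not possible in living donors, blood and
pancreas repertoires come from *different* people, and the comparison
rests on junction amino-acid sequences used as clonal barcodes.

## What it computes

Given cell-level rearrangement tables (AIRR-style TSV: one row per
recovered TRA/TRB chain), pitmatch:

1. **Filters** non-productive junctions (stop codons, frame violations)
   and removes whole cells bearing invariant innate-like chains (iNKT
   cells by the canonical `CVVSDRGSTLGRLYF` TRA junction; MAIT cells by
   TRAV1-2 paired with TRAJ33/TRAJ20/TRAJ12).
2. **Deduplicates** junctions per locus into repertoires with per-donor
   cell counts, V/J gene sets and nucleotide-sequence sets.
3. **Matches** every query junction against a reference repertoire by
   exact Levenshtein distance `d(a, b)` (unit-cost substitutions,
   insertions, deletions; banded dynamic programming, length-pruned).
   A TRA junction with `d ≤ 1` to any reference junction is
   **PIT-matched**; a TRB junction is PIT-matched iff a cell pairs it
   with a PIT-matched TRA.
4. **Tests enrichment** with exact statistics: Fisher 2×2 tests with
   sample odds ratios and Woolf CIs on log₂ OR, per-threshold match
   curves with a nested-model F-test against slope 1, per-gene V/J
   usage enrichment, donor-level Wilcoxon rank-sum comparisons, all
   Benjamini–Hochberg adjusted.
5. **Classifies clonality**: expanded (>1 cell), public (>1 donor),
   private (expanded, single donor), convergent (>1 nucleotide sequence
   for one amino-acid junction), with hypergeometric set-overlap tests
   and adapters for externally computed generation probabilities
   (-log₁₀ Pgen rank tests).
6. **Compares sequence features**: junction lengths, CDR/FR/N-region
   decomposition (`v3 + N + j5 = junction length`), Eisenberg-scale
   hydrophobicity (per-residue mean; P = 0.12, Y = 0.26), two-sample
   Kolmogorov–Smirnov tests; plus single-vs-multi-epitope specificity
   grouping of VDJdb-style exports.
7. **Maps TCR–peptide contacts** in modeled TCR–pMHC complexes
   (PDB/mmCIF): a TCR residue is a contact when its minimum heavy-atom
   distance to the peptide chain is strictly < 5 Å; contacts are
   aggregated per CDR/FR region and the CDR1:CDR3 contact ratio is
   regressed on TRA junction length.

A fully deterministic synthetic-data module generates multi-donor
repertoires by a toy V(D)J process (V 3' trimming, N insertion, J 5'
trimming), with planted cross-repertoire sharing, convergence and
structure fixtures — every number the pipeline reports can be checked
against planted truth.

## Worked example

```sh
python examples/01_worked_example_matching.py
```

prints, for the bundled curated junction tables (ten perfectly matched
IAR/PIT TRA pairs, the single-mismatch pairs of known islet
specificity, and the TRB trio from multi-specific clones):

```
Perfect-match IAR/PIT TRA pairs (expected distance 0):
  CAVRMNTGFQKLVF   d=0  (same V)
  ...
  IGRP39    CAGQTGANNLFF      vs CALQTGANNLFF      d=1
  ...
  CASSPQGGNTEAFF vs CASSVQGGNTEAFF: d=1

TRA bias of perfect matches: OR=8.8, p=1.1e-11
```

The odds ratio compares the TRA:TRB split of perfect matches (55:7)
against the locus split of the reference repertoire itself (4,614:5,143
unique junctions): junction sharing across compartments is a
TRA-chain phenomenon, not an artifact of reference composition.
`examples/02_synthetic_end_to_end.py` runs the whole pipeline on a
synthetic pair of repertoires with 25% planted exact sharing and
recovers every planted junction; `03` and `04` demonstrate the feature
decomposition and contact mapping.

There is also a thin CLI (`pitmatch match|enrich|clonality|features|contacts|simulate|run`)
for shell use; the Python API is the primary interface.

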