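# Methods

## Problem setting and model

The package compares TCR repertoires sampled from different
compartments (and, necessarily, different donors): a *query* repertoire
of blood islet-antigen-reactive (IAR) CD4+ T cells and a *reference*
repertoire of pancreas-infiltrating T cells (PIT). The unit of analysis
is the junction — the V(D)J recombination product spanning the
conserved cysteine to the conserved F/W, i.e. CDR3 plus its two anchor
residues. Identical or near-identical junction amino-acid sequences in
independent donors are treated as evidence of shared selection, because
the recombination process makes long junctions individually improbable.

Matching is plain Levenshtein distance on amino-acid strings.
Biochemical similarity between substituted residues is deliberately
ignored: the designation rule ("PIT-matched" = TRA junction within
distance 1 of any reference junction; TRB junctions inherit the label
from a paired TRA in the same cell) is a set-membership rule, and
weighting mismatches would change the membership semantics. The TRB
inheritance rule reflects the asymmetry of the phenomenon being
quantified: junction sharing across compartments is concentrated in
the TRA chain, and the paired TRB chains are typically divergent.

## Filtering rules

Productivity filtering removes junctions containing a stop ('*') and,
when the nucleotide sequence is available, junctions whose nt length is
not a multiple of 3 or whose translation disagrees with the declared
protein sequence. Without nucleotides the stop test is the only
operational in-frame test; an optional strict mode additionally
requires the C...F/W anchors (off by default, since productive
junctions with non-canonical anchors occur). Invariant innate-like
cells are removed whole-cell: any cell with an in-frame TRA chain equal
to the canonical iNKT junction `CVVSDRGSTLGRLYF`, or using TRAV1-2 with
TRAJ33/TRAJ20/TRAJ12 (MAIT), loses all its chains. Restricting the
trigger to in-frame chains makes the two filters commute, which the
suite verifies.

Gene names are compared at the *gene* level by default: the allele
suffix (`*01`) is stripped, whitespace removed, case ignored, and the
original string kept for display. V and J segments are much longer than
junctions and are not string-matched; two segments are "identical" iff
their names agree, with an allele-level mode available.

## Matching machinery

Distances are exact unit-cost edit distances computed by banded dynamic
programming (edlib) with early abandon at the configured threshold and
candidate pruning by length (|len(a) − len(b)| > k rules out distance
≤ k). Ties at the minimum are all retained; segment-identity flags use
"any hit" semantics because no best-hit rule is defined for tied hits.
Distance-1 matches split into substitution-type (equal length, Hamming
1) and indel-type; the mismatch *position* is defined only for the
substitution type. Positions are classified against per-junction
V 3'/J 5' boundaries: strictly before the V-end boundary → V-germline,
strictly after the J-start → J-germline, else N-region; whether the
boundary residues themselves count as germline is a configuration flag
(default: they do not, i.e. strict inequalities).

Two reference modes exist: within-locus (default; TRA vs TRA) and a
pooled mode that matches against the union of reference loci. Both are
exposed because published repertoire-overlap figures sometimes pool
reference loci while the biology argues within-locus.

## Statistics

* Fisher's exact test for every 2×2 comparison; the reported OR is the
  sample cross-product ratio, with Haldane–Anscombe correction (+0.5
  per cell) applied and flagged only when a cell is zero, so log₂ OR
  stays finite. The 95% CI is the Woolf (log-scale normal) interval.
  The p-value is always exact and uncorrected.
* The off-diagonal slope test fits query match counts on background
  match counts by OLS and compares against the model with slope fixed
  at 1 (intercept free in both) with a 1-df F test. "Linear modeling
  and ANOVA" admits several formalizations; the nested-model F test is
  the standard one.
* Group comparisons of matched fractions: pairwise Fisher tests within
  an expansion stratum, BH-adjusted across pairs; donor-level fractions
  compared by two-sided Wilcoxon rank-sum to guard against p-value
  inflation from many junctions per donor.
* Set overlaps use the exact hypergeometric upper tail; KS tests are
  the two-sided two-sample form (exact for small samples, as scipy
  selects). Multiple testing is Benjamini–Hochberg throughout with
  α = 0.05.

Degenerate inputs fail loudly: empty reference repertoires, 2×2 tables
with a zero margin, zero-variance regressors and empty KS groups raise
rather than return NaN. A zero-residual regression (constant ratio)
reports p = 1 for a zero slope rather than NaN.

## Clonality definitions

Expanded = junction seen in >1 cell, counted across all donors
(junction-level, following the definition on the junction AA sequence);
public = seen in >1 donor; private = expanded and confined to one
donor; singleton single-donor junctions are neither. A per-donor
expansion variant exists because junction-level expansion makes every
two-cell public junction "expanded". Convergent = more than one
distinct nucleotide sequence observed for one amino-acid junction;
junctions lacking nucleotide data are excluded from convergence
denominators and counted. Generation probabilities are never computed
here — a Pgen table from an external recombination-model tool is
consumed via an adapter, and distributions are compared on the
−log₁₀ scale with rank tests.

## Sequence features

Junction nucleotide decomposition takes the longest exact prefix match
against the V 3' germline segment, then the longest exact suffix match
against the J 5' segment constrained to the remaining length; the
remainder is the N region. The V claim is maximized first — a
deterministic tie-break for bases claimable by both segments — and
length is conserved exactly on every input. For TRB the simulator
inserts a fixed toy D segment between two N stretches and the truth
table merges N1+D+N2 as "N region" for feature parity with TRA.

Hydrophobicity is the Eisenberg consensus scale (R = −2.53 … I = 1.38)
aggregated as the arithmetic mean over all junction residues, anchors
included. Aggregation (mean|sum) and anchor inclusion are configurable;
the mean keeps values on the residue scale, where typical junction
medians fall between proline (0.12) and tyrosine (0.26). Lengths are
reported in nucleotides; when only protein is available, nt = 3×AA.
The junction convention is IMGT-style junction-with-anchors: junction
= CDR3 + 6 nt, applied when parsing HighV-QUEST-style feature tables.

Specificity grouping of VDJdb-style exports defines a unique chain as
(normalized V, CDR3 AA, normalized J) and labels it multi-specific iff
it is associated with more than one distinct epitope; rows without an
epitope are dropped and counted.

## Structure contacts

Models arrive as PDB v3.3 or mmCIF with an explicit chain→role map; no
structures are predicted, relaxed or superposed. All heavy atoms are
used (models lack hydrogens; no atom-subset selection is applied, and
the choice is configurable only through the coordinates supplied). A
TCR residue is a peptide contact when its minimum Euclidean distance to
any peptide heavy atom is strictly below 5.0 Å — a residue at exactly
the cutoff is not a contact. Region labels (CDR1–3, FR1–3) come from an
external annotation table; unannotated contacts map to "other" with a
warning. The CDR1:CDR3 contact ratio is defined only when CDR3 has at
least one contact, and is regressed on TRA junction length by OLS with
the usual t-test against slope 0.

## Synthetic data: what it emulates and what it does not

The generator draws, per clone: a V segment (3'-trimmed uniformly up to
6 nt), Poisson-length N insertion (mean 4 nt for TRA, 7 nt for TRB,
reflecting the heavier non-templated contribution in TRB), a 5'-trimmed
J segment, and a geometric clone size (mean 1.3 cells, putting roughly
a quarter of cells in expanded clones). Out-of-frame or stop-containing
draws are resampled so requested sizes are exact. Toy germline segments
(8 V, 6 J per locus) start at the conserved cysteine codon and end at a
phenylalanine codon, so generated junctions carry canonical anchors.
Planted effects — a cross-repertoire sharing probability, a distance-1
mutation rate with configurable substitution-position distribution, a
synonymous-variant convergence rate — are recorded per clone in a truth
table. A single seeded generator drives all sampling; identical
configurations produce byte-identical outputs.

Deliberate non-goals: no thymic selection, no realistic gene-usage
priors, no biologically calibrated trimming/insertion profiles, no
sequencing error. Passing recovery tests therefore demonstrates that
the pipeline measures what was planted under the generative model's
assumptions — not that real repertoires satisfy those assumptions. In
particular the toy germline's low diversity makes chance junction
collisions (and hence chance distance-1 matches) far more frequent
than in real data; recovery tests account for this by comparing
detected sets against planted truth sets rather than raw rates.

Structure fixtures place contact residues exactly 3.0 Å above peptide
atoms and non-contacts 30 Å away, with CA+CB pseudo-atoms per residue,
so planted per-region contact counts are recovered exactly at the 5 Å
cutoff and the strict-inequality convention is testable at 3.0 Å.

## Problem sizes and verification

The test suite checks implementations against independent brute-force
oracles: memoized-recursion edit distance (10⁴ random pairs plus metric
axioms), exhaustive enumeration of all 2×2 tables with total ≤ 30 for
Fisher, combinatorial tail sums for the hypergeometric (universes
≤ 25), all-splits enumeration for small-sample KS (group sizes ≤ 8),
and all-pairs distance scans for contact sets. Parameter-recovery runs
use 20 simulated repertoires of ~400–500 clones each per quantity —
sizes chosen so binomial standard errors are small relative to the
planted effects while a full run stays in the tens of seconds. The
acceptance script reruns all of these from scratch from a single seed.

## Known limitations

* The matched-fraction background comparison depends on the background
  repertoire's size convention (unique junctions vs junction
  observations); the background totals are therefore explicit
  parameters and no default is asserted.
* Whether published unique-junction totals deduplicate within or across
  cohorts is ambiguous; repertoire construction supports both
  (combine-then-dedup is the default).
* Mismatch-position analysis covers substitution-type distance-1 pairs
  only; indel-type pairs are counted and excluded.
* Pgen values, IMGT region annotations and structural models are
  consumed, not produced; their quality bounds the downstream analyses.
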