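# Methods

## The analysis this package implements

The NRBP family comprises conserved metazoan pseudokinases; vertebrates
carry two paralogs (NRBP1, NRBP2) produced by an early-vertebrate gene
duplication, while invertebrates carry a single copy.  The package
implements the computational side of that family's characterization:
assembling an ortholog set by reciprocal-search filtering, establishing that
the family members are pseudokinases from their catalytic-triad residues,
preparing alignments for tree inference by gap masking, quantifying
per-clade divergence on an (externally inferred) phylogeny, and the explicit
qPCR/colony-count formulas used in the accompanying L1-retrotransposition
experiments.  Tree inference itself (MAFFT/IQ-TREE territory) and all
wet-lab processing are out of scope; their outputs are consumed as inputs.

## Ortholog acceptance chain (`ortholog`)

Candidates enter as rows of 12-column tabular hit files.  Four rules are
applied, and a candidate must pass all of them:

1. **E-value** — forward-search E ≤ 1e-28, *inclusive*.  The boundary
   behavior is not dictated by the threshold itself; inclusive matches the
   common search-tool semantics of reporting "up to" a cutoff.
2. **Reciprocal top hit** — the candidate's maximal-bit-score reverse hit
   must be an accepted reference (NRBP1/NRBP2).  Ties at the top bit score
   accept if *any* tied subject is a reference: this is conservative toward
   inclusion and symmetric with the notion of "top-ranking hit".
   Candidates with no reverse hits are rejected.
3. **Coverage** — union of the reference residues covered by all HSPs of a
   candidate–reference pair, divided by the reference length, must be
   ≥ 0.80 (inclusive).  Coverage is measured on the *reference* side by
   default because the criterion is phrased as coverage *of* NRBP1/2; the
   query-side convention and per-HSP (non-pooling) behavior are selectable
   (`coverage_relative_to`, `pool_hsps`) since the original convention is
   not documented.
4. **Folded region** — at most `tolerance` (default 40) residues of the
   reference's predicted folded region may be uncovered.  The tolerance is
   a single total budget, not a per-terminus allowance; with no statement
   to the contrary, a total budget is the weaker (more faithful) reading.

Coordinates are 1-based inclusive externally (search-tool convention);
interval arithmetic converts to half-open ranges internally.  The interval
union is checked against per-residue set arithmetic in the tests.

`local_search` provides a desk-scale stand-in for a database search: affine
Smith–Waterman (BLOSUM62, open 11 / extend 1 via Biopython's
`PairwiseAligner`) with bit scores S′ = (λS − ln K)/ln 2 and
E = m·n·2^(−S′).  λ = 0.267 and K = 0.041 are fixed constants (the
customary gapped BLOSUM62 values), not estimated: at the scales this
package operates, only the ordering and rough magnitude of E-values matter.
Residues outside the matrix alphabet are mapped to `X` (scored like an
ambiguous residue).

## Triad classification (`triad`)

The domain model is a position-specific scoring matrix built from a seed
alignment: per-column log-odds in bits,
log₂(((count + pc) / (n + 20·pc)) / background), Laplace pseudocount
pc = 1, uniform background 1/20.  Columns with > 50% gaps are dropped as
insert columns and the annotated triad columns are remapped; a triad column
dropping out is an error because the seed cannot then anchor the triad.

Queries are aligned *globally* to the profile by affine-gap dynamic
programming (default gap open 4 bits, extend 1 bit).  Global rather than
local alignment is appropriate because inputs are pre-filtered to cover the
folded kinase domain; terminal gaps are penalized but tolerated.  The
insertion-state recurrence is evaluated with a prefix-maximum so each DP row
is vectorized; traceback uses stored pointers.  The DP optimum equals
exhaustive enumeration on small instances (checked in the tests).

The triad residues are read at the three annotated columns and compared to
exactly K (β3 lysine), D (HRD aspartate), D (DFG aspartate) — no
conservative substitutions, since the criterion scores these specific
residues and any relaxation would be an unstated liberalization.  An
unmapped (gapped) triad column counts as a mismatch: an absent catalytic
residue cannot be functional.  **Pseudokinase ⇔ ≥ 2 of 3 mismatches.**
One kinase domain per sequence is assumed.

A small **synthetic** kinase-domain seed alignment ships with the package
(`data/kinase_seed_synthetic.afa`, generated by the family simulator) so
the classifier runs offline; curated seeds (e.g. a Pfam kinase-domain
alignment) can be supplied through the same interface.

## Alignment masking and identity (`msa`)

A column is removed when its gap fraction is ≥ `max_gap_fraction`
(default 0.10) — inclusive removal, per the rule's "10% or more" phrasing.
Percent identity uses global affine-gap alignment (BLOSUM62, open 10,
extend 0.5 — the most common protein global-alignment default) with the
denominator selectable: full alignment length (EMBOSS-needle convention,
default), shorter sequence, or gap-free columns only.  The convention is
exposed because published identity values rarely state it.

## Divergence statistics (`phylo`)

Trees are parsed from Newick with internal-node labels kept as support
values (tree-inference convention; "perfect support" = 100).  Rerooting at
an outgroup splits the outgroup's branch 50/50 across the new root — the
split is not identifiable from data, so the symmetric default is used.
Leaf-to-root distance is the plain path sum of branch lengths
(substitutions/site); no rate re-normalization is applied.

Clade pairs are compared by two-sided Welch's t-tests (scipy, unequal
variances, Welch–Satterthwaite df) with Benjamini–Hochberg step-up
adjustment (statsmodels) across the tested pairs; the pair list is a
required input because which pairs form the family of tests is an analysis
decision.  Degenerate cases return flagged conventional values instead of
raising — t = 0, p = 1 for identical constant samples, ±∞ with p = 0 for
constant samples with different means — so a pipeline does not die on a
constant clade.  The paired bit-score test follows the same conventions and
additionally reports the fraction of pairs favoring the first reference.

## Synthetic data generator (`synthetic`)

The generator emulates the statistical structure the analysis assumes, with
all ground truth known:

* **Topology** — three clades (invertebrate; P1 = NRBP1-like;
  P2 = NRBP2-like), each a balanced (symmetric-split) tree; invertebrate is
  sister to (P1, P2).  The fixed, shared topology removes tree shape as a
  confounder in distance comparisons.
* **Branch lengths** — internal and stem edges have fixed length
  `base_rate` (expected substitutions/site per edge; default 0.05), and
  only pendant edges are random, Exponential with mean `base_rate`.  This
  makes leaf-to-root distances i.i.d. within a clade — exactly the
  assumption of the downstream leaf-level Welch test.  Had internal edges
  been random too, leaves would share ancestral noise and the nominal test
  level would not hold by construction.  Every edge of the P2 subtree
  *including its stem* is scaled by ρ (`rate_multiplier_fast_clade`), so
  ρ = 1 makes P1 and P2 exchangeable in distribution.
* **Sequences** — the root sequence is uniform over the 20 residues;
  along each branch of length b every site substitutes independently with
  probability 1 − e^(−b), uniformly to one of the other 19 residues.  This
  is the simplest process that exposes rate differences; there are no
  indels, no codon structure, and no empirical exchangeability matrix, so
  passing tests demonstrate recovery of *rate and triad* signal, not
  robustness to realistic alignment error.  Insertions for stress-testing
  the profile aligner are planted afterwards by `plant_insertions`.
* **Triads** — three fixed, well-separated positions (L/4, L/2, 3L/4) are
  frozen during evolution; "intact" clades carry K/D/D, "degenerate" clades
  carry clade-specific non-consensus residues at all three positions.
  Freezing keeps triad state a controlled variable.  The default plants
  *degenerate* triads in every clade, matching the family being modeled (a
  pseudokinase family); recovery experiments override this per clade.
* **Ct tables** — built by inverting the RIP enrichment formula around a
  control baseline (Ct(RIP) = 26, Ct(Input) = 20), so the estimator returns
  `true_fold` exactly at zero noise; Gaussian Ct noise is added otherwise.
* **Randomness** — one integer seed expands via `SeedSequence` into
  independent streams (tree, sequences, triad planting); identical configs
  give byte-identical output.

## Problem sizes used in the checks

The recovery experiments run at 50 leaves/clade (150 sequences of 300
residues), 100 simulated families per rate setting; triad recovery uses 201
sequences with planted insertions of up to 10 residues; the brute-force
oracle comparisons use 1000 random coverage instances, 100 random
alignments, and 100 random statistical instances each.  These sizes were
chosen as the smallest at which the planted effects are unambiguous while
the whole suite stays interactive.

## Known limitations

* The substitution process is site-independent and uniform; distances in
  substitutions/site are exact by construction rather than estimated from
  sequences, so the divergence experiments validate the statistics, not
  tree estimation.
* The profile model has no insert/delete state probabilities (not a full
  profile HMM) and no E-value calibration for profile hits.
* `local_search` implements exact affine Smith–Waterman without database
  search heuristics; its E-values use fixed Karlin–Altschul constants.
* The published 55.7% NRBP1–NRBP2 identity depends on the (unnamed)
  alignment program's conventions; the package exposes the denominator and
  gap-cost choices and treats ±1 percentage point as agreement.  The real
  UniProt sequences must be user-supplied (see
  `data/reference/README.txt`).
* Replicate Ct values are aggregated by arithmetic mean before Δ
  computations (standard ΔΔCt practice); efficiency-corrected qPCR models
  are not implemented.
* The direction of the RIP IP-efficiency adjustment is a modeling choice:
  the fold is *divided* by the experimental/control ORF1p IP ratio, so more
  precipitated protein cannot inflate apparent RNA enrichment; the
  reciprocal is selectable (`adjust_direction="multiply"`).
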