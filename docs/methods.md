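# Methods

## Scope and data model

The package analyzes cohorts of annotated signal peptides (SPs).  An SP
record carries the amino-acid sequence, the cleavage position (1-based index
of the last SP residue; the (−1) position of the (−3,−1) rule), optional
N/H/C region boundaries, and optional metadata: chromosome, subcellular
location label, secretion titer (U L⁻¹, the activity of a reporter enzyme
secreted under that SP), the SP's coding sequence, and the first residues of
the downstream mature protein.  Annotation tables are plain TSV; sequences
are FASTA.  Tables exported from spreadsheets must be saved as TSV — the
package deliberately has no spreadsheet dependency.

## Region decomposition

When boundaries are provided they are always used; analyses of annotated
cohorts therefore reflect the annotations, not the heuristic.  Otherwise the
N/H/C partition is computed deterministically from Kyte–Doolittle (KD)
hydropathy:

1. **Seed** — the contiguous window of length min(7, L−3) with maximal mean
   KD; ties go to the leftmost window.
2. **Extension** — grow the window left and right while the adjacent
   residue has KD ≥ 1.0.
3. **Clipping** — enforce n ≥ 1 and c ≥ 2 by trimming the H side nearer the
   violated bound.

The constants (seed 7, threshold 1.0, leftmost ties) are fixed design
choices: hydrophobic-core annotation has no published closed form, and
fixing them makes every downstream number reproducible.  A sequence whose
best window has negative mean KD has no hydrophobic core; it is still
partitioned (around the best window) but flagged, and a warning is logged.
Sequences shorter than 6 residues are rejected.  On synthetic cohorts with
strongly hydrophobic cores (mean KD ≥ 2.5) and non-positive-hydropathy
flanks the heuristic recovers planted boundaries within ±1 residue for
essentially all SPs (the package asserts ≥ 90%).

## Feature metrics

- **Hydropathy profile**: arithmetic mean KD per sliding window, default
  window 9; for sequences shorter than the window a single whole-sequence
  mean is returned.  `X` residues are excluded from window means,
  composition tables and charge counts (with a logged warning); any other
  non-canonical residue is a hard error.
- **Compound score** = (maximum window mean) × (H-region length).  The
  maximum window mean is a *mean*, not a sum: compound scores of ~23–24
  then correspond to a core of mean KD ≈ 2.5 and length ≈ 9, which is the
  scale on which the unfavourable band [23, 24] is defined.  The
  translocation-bias thresholds (≤ 1.75 post-translational-dependent,
  ≥ 1.81 SRP-biased) are on the *per-residue* scale (the max window mean
  itself); the two scales are deliberately kept distinct.
- **N-region charge** = (#K + #R + #H) − (#D + #E).  Histidine is counted
  positive; the free N-terminal amine is not counted.
- **(−3,−1) motif**: AXA iff Ala at −3 and −1; VXA iff Val at −3 and Ala at
  −1; everything else OTHER.  The classes partition every cohort.
- **Conservation**: per-position information content log₂20 + Σ p log₂ p,
  with no small-sample correction — cohort columns here have hundreds of
  observations, where the correction is negligible, and the uncorrected
  statistic has clean bounds [0, log₂20].
- **Deletion scan**: one variant per H-region position; each variant is
  re-decomposed and re-scored, and flagged when the deletion moves a score
  out of the [23, 24] band.

## Cleavage-context matrix and fusion shifts

Signal peptidase site preference is modelled as a position-specific
log₂-odds matrix over positions −3, −2, −1, +1, +2 around the cleavage bond
(no position 0 exists).  Foreground counts come from the annotated native
contexts (last three SP residues plus the first two mature residues);
background frequencies are pooled over the training sequences; both are
smoothed with the same pseudocount (default 1.0, must be positive) so all
weights are finite.  Cohorts need ≥ 20 SPs with mature context to train.

For a fusion (SP + mature prefix), every candidate last-SP-residue position
within ±5 of the annotated site (intersected with [4, len−2]) is scored by
summing the five position weights; the argmax is the predicted site and
ties keep the leftmost (more N-terminal) position, which preserves the
native site when it ties a downstream competitor.  This matrix is a
transparent stand-in for a full cleavage predictor: shifted *fractions* on
consistently annotated cohorts are meaningful, but individual shift calls
do not numerically reproduce neural-network predictors, so any published
count of shifted SPs is a soft target checked as a rate.

## Codon bias

Codon usage is compared on within-family fractions (per amino acid, the
share of each synonymous codon), standard nuclear code, stop codons
excluded; internal stops and ambiguous codons are excluded with warnings.
The SP-vs-ORFeome comparison reports per-codon deltas, which sum to zero
within each family.  "Rare" has no canonical definition at this scale, so
it is operationalized: a codon is rare when its reference (ORFeome)
fraction is strictly below the 0.25 within-family quantile of its family's
fractions; single-codon families contribute none.  The quantile is
configurable, and a fixed external usage table can be supplied as the
reference instead.  Because amino-acid composition differs strongly between
SPs (Leu-rich) and the ORFeome, overall rare-codon shares confound
composition with within-family bias; recovery tests therefore compare
within-family fractions, never the pooled share.

## Cohort statistics

Deduplication is exact string identity on the SP sequence, first occurrence
kept.  Category titer summaries use the arithmetic mean and sample SD
(ddof = 1) of the titered SPs, with untitered SPs counted separately; SPs
with zero titer are included.  The score-bin categorizer rounds the
compound score half-away-from-zero to an integer.  The secretion-rule
report flags, per SP: n = 5; h ∈ {8, 9}; c = 5; net N-charge +1; AXA/VXA
motif; compound score outside [23, 24]; unshifted cleavage site.  Ranking
is by rule count then compound score (both descending, then gene id) for a
deterministic listing; when no shift analysis ran the "not shifted" flag is
False rather than silently true.

## Synthetic cohort generator

The generator exists to make every analysis stage testable: each configured
frequency and effect size must be recoverable by the stage that measures
it.  Defaults encode the study conditions of the genome-wide yeast cohort
the package targets:

- **Cohort**: 352 SPs of which 30 are duplicate sequences (distinct gene
  ids re-using an already drawn SP, with their own titer draw), giving 322
  unique SPs after dedup.  Uniqueness of the non-duplicate draws is
  enforced by rejection sampling (100-retry cap).
- **Region lengths**: categorical, N over 2–20 (mode 5, long right tail),
  H over 6–14 (mode 9), C over 3–8 with P(c=5) = 0.6438.
- **Composition**: per-region categorical residue distributions —
  positive-rich N, Leu-rich H (P(L) = 0.2659), Ala/polar C.  Two anchors
  are calibrated analytically so the *pooled* cohort statistics realize
  their targets: N-region positive probabilities are scaled by
  E[n]/(E[n]−1) to offset the invariant initial Met (pooled positives
  22.37%, Arg+Lys 87.86% of positives), and the free-position Ala
  probability in C solves (E[c]−2)·x + p_AXA + (p_AXA + p_VXA) =
  0.2326·E[c] so pooled C-region Ala realizes 23.26% once the Ala planted
  by the motif frequencies is counted.
- **Cleavage context**: with probability p_AXA = 0.199 / p_VXA = 0.211 an
  AXA / VXA motif is planted at (−3,−1).  OTHER sites still obey the
  biological small-residue (−3,−1) rule (Ser/Gly/Thr/Cys there, just not
  the motif residues), and intact sites are followed by a charged
  mature-start block at +1/+2.  This gives every intact native site a
  recognizable five-position context — which is what makes shift detection
  identifiable with a five-position matrix.
- **Fusion shifts**: with p_shifted = 0.11 the native site is degraded
  (both (−3) and (−1) drawn from residues violating the small-residue rule)
  and a complete strong context (A-x-A plus charged +1/+2 block) is planted
  in the mature prefix three residues downstream.  The measured shifted
  fraction recovers p_shifted; with the default conditions the false-shift
  rate on intact SPs is ~0.2% and planted shifts are essentially always
  detected.
- **Codon model**: within each synonymous family the base distribution has
  geometric skew (ratio 0.5, alphabetical order); SP coding sequences are
  back-translated from a boosted model in which rare codons (below the
  0.25 within-family quantile of the base model) get twice the
  probability, renormalized — emulating rare-codon enrichment in SP coding
  regions without claiming a mechanism.  The background ORFeome (default
  400 ORFs of 150–450 codons) uses the base model.
- **Titer model**: titer = 4106 U L⁻¹ × Π(active multipliers) ×
  exp(σ·Z), σ = 0.3 (median-1 log-normal noise).  Multipliers: AXA/VXA
  motif ×1.3, N-charge +1 ×1.2, shifted ×0.51, compound score in [23, 24]
  ×0.7.  Because a planted shift forces an OTHER native motif, motif and
  shift flags are negatively correlated by construction; the 0.51
  multiplier is therefore recovered by comparing flag-adjusted means
  (other-flag multipliers divided out using the recorded ground truth),
  and the marginal cohort mean exceeds the 4106 baseline (the >1
  multipliers raise it).  Class probabilities among unshifted SPs are
  rescaled so the cohort-level motif marginals equal the configured
  frequencies.
- **Randomness**: a single `numpy.random.default_rng(seed)` stream; no
  global state; regenerated files are byte-identical for a fixed seed.

What the generator does *not* emulate: real N-terminal methionine
processing, pre-pro leaders (pro-regions are out of scope; such SPs are
pass-through metadata), sequence correlations along the SP beyond the
region/site structure above, genuine yeast codon-usage values, chromosome
synteny, or any mechanistic link between hydrophobicity and titer beyond
the configured flag multipliers.  Passing recovery tests therefore shows
the *analysis* is correct and well-calibrated on data satisfying its
assumptions — not that those assumptions hold in any particular genome.

## Problem sizes and tolerances

Fraction recoveries are asserted within 3 binomial SDs of the configured
value and effect-size recoveries within 2 SEs.  The reference-scale checks
use the default 352-SP cohort; frequency recoveries use 5,000 SPs (3
binomial SDs on p = 0.11 is then ±1.3 points); codon-model recovery uses a
uniform-composition ORFeome of ~6×10⁵ codons, where every within-family
deviation stays below 0.01; boundary recovery uses 500 strongly structured
SPs.  These sizes keep each statistic's sampling error well inside the
asserted tolerance while the whole suite runs in well under a minute.

## Numerical and degenerate-input choices

Composition and codon tables normalize exactly (asserted to 1e-9).  TSV
annotation output uses `%.17g` floats so write→read round-trips are exact;
report TSVs use 6 significant digits so repeated runs are byte-identical.
Empty cohorts, empty CDS sets, mixed-length conservation inputs,
sub-6-residue SPs, non-positive pseudocounts, unknown chromosomes and
unwritable output directories are hard errors; parsers never silently drop
records.
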