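# Methods

## Design

`triohet` analyzes a *trio design*: two inbred parents (P1, P2) and their
F1 hybrid, profiled by RNA-seq in one or more tissues with replicates.
Expression is handled in TPM (transcripts per million); allele-resolved
F1 counts (reads assignable to the P1- vs P2-derived allele via parental
SNPs) are consumed as pre-tabulated count tables — read alignment, SNP
calling and haplotype read-backed phasing happen upstream and are out of
scope.

## Replicate QC

Pairwise Pearson correlations are computed over all samples; a sample is
flagged when its *best* correlation against any replicate of the same
(genotype, tissue) group is strictly below 0.85. Using the maximum keeps
the excluded set minimal: in a discordant pair accompanied by a third
concordant replicate, only the sample that agrees with nobody is removed.
Single-replicate groups are never flagged. A zero-variance sample has no
defined correlation and is flagged, since it cannot demonstrate
concordance. Group means (arithmetic mean TPM over retained replicates)
feed all downstream tests.

## Expression breadth

A gene is *active* in a tissue at mean TPM ≥ 1 (the same floor the SPE
criteria use). With fraction f of tissues active: silent (f = 0),
tissue-specific (0 < f ≤ 0.2), intermediate (0.2 < f ≤ 0.8),
constitutive (f > 0.8). Both boundaries are inclusive on the lower class
so that, with 15 tissues, the classes correspond to the integer bins
1–3 / 4–12 / 13–15.

## Parental divergence

DE calls are pluggable: externally produced tables (gene, tissue, log2FC
oriented P2/P1, adjusted *P*) are re-thresholded at adj *P* < 0.05 and
|log2FC| ≥ 1. The built-in test (`call_de_internal`) pools replicates per
parent, tests each gene with a two-sided Fisher exact test of
[[gene reads, rest of library]] between parents, adjusts with
Benjamini–Hochberg within tissue, and computes log2FC from library-
normalized pooled counts with pseudo-count 1. This is a deliberate
simplification — it has no dispersion model, so with strongly
overdispersed replicates it over-rejects relative to a negative-binomial
DE model; supply external DE tables when that matters.

Single-parent expression requires all four clauses on (silent parent A,
expressed parent B): TPM_A ≤ 1st percentile of expression, TPM_B ≥ 10 ×
TPM_A, TPM_B ≥ 1, TPM_A < 0.1. The percentile is taken over *positive*
TPMs of that parent and tissue: genome-scale TPM vectors are
zero-inflated, and including zeros collapses the 1st percentile to 0,
reducing the percentile clause to exact silence. Each bound is a
parameter.

Cross-tissue direction consistency (for DEGs, SPE genes and ASE genes)
classifies genes with calls in ≥ 2 tissues (parameter) as consistent-P1,
consistent-P2, or mixed.

## Additivity classification

TPM is a per-million measure, so a TPM value *t* is treated as *t*
transcripts out of 10⁶ and two values are compared by a two-sided Fisher
exact test on [[round(x), 10⁶−round(x)], [round(y), 10⁶−round(y)]]
(the scale is a parameter). Three tests per gene — F1 vs mid-parent
(MPP), vs high parent, vs low parent, all at α = 0.05, unadjusted —
drive the decision tree documented in `triohet.additivity`. Two
conventions the tree needs that the classification literature leaves
open: the mid-parent value is the unweighted mean of the parental mean
TPMs, and a DEG significantly different from all three references but
lying strictly between the parents gets the explicit label
`ambiguous_nonadditive` rather than being forced into a named class.
No multiple-testing correction is applied inside the classifier; the
three p-values are reported per call so users can re-threshold.

The Fisher construction has a resolution floor: its detection width at
level t TPM is about 2·√(2t) per-million units, so a 2.0-fold parental
split at TPM ≈ 50 (100 vs 75 against the mid-parent) is inside the
indifference zone (p ≈ 0.07). Conversely its width ignores biological
replicate variance, so at very high TPM (≳ 400 at replicate CV ~10%)
even true equality is rejected. The classifier is therefore most
informative in the few-tens-to-few-hundreds TPM range, which is where
most expressed genes sit.

## Allele-specific expression

SNP rows require ≥ 10 reads per allele and a minor-allele fraction ≥ 2%;
retained SNPs are summed per gene and tissue. The gene-level test is the
exact two-sided binomial test against 50:50, two-sided mass defined by
minimum likelihood (all outcomes with null pmf ≤ the observed one);
doubling the one-sided tail is available as an option. Effect size is
aFC = log2((P2 reads + ½)/(P1 reads + ½)), oriented P2 over P1; the ½
pseudo-count keeps zero-count genes finite. The ASE-vs-parental
comparison is an OLS regression of aFC on parental log2FC with adjusted
R² = 1 − (1−R²)(n−1)/(n−2).

## cis/trans classification

Three tests per gene and tissue: (A) parental difference — Fisher exact
of [[reads, library−reads]] between parents on pooled replicate counts;
(B) allelic difference — the binomial ASE test; (C) trans component —
Fisher exact of [[P1 reads, P2 reads], [F1 P1-allele, F1 P2-allele]],
significant when the parental ratio is not reproduced by the hybrid's
allelic ratio. The decision table (A,B,¬C → cis-only; A,¬B,C →
trans-only; A,B,C → enhancing/compensating by whether the parental and
allelic biases point the same way; ¬A,B,C → compensatory; none →
conserved; remainder → ambiguous) is exhaustive and mutually exclusive.
Direction agreement uses the signs of the parental rate ratio and of the
allelic imbalance; if either is exactly tied the gene is ambiguous.

Library sizes matter for test A: for genome-complete count matrices the
pooled column totals are correct, but for a gene panel (or simulated
subset) the true library must be supplied (`PipelineConfig.library_size`)
— column sums of a panel underestimate it and bias A toward
significance. Test A shares the internal DE test's limitation: it models
per-million sampling only, so extra-Poisson replicate variance inflates
its rejection rate for truly conserved genes. The null-calibration suite
therefore verifies its size under Poisson sampling, and the conserved
class should be read as "no divergence detectable at sequencing-noise
scale".

## Pattern enrichment

Regulatory and additivity calls are joined on (gene, tissue) and
cross-tabulated. The global test is Pearson's chi-square of independence
without continuity correction (the residuals are the reported quantity:
residual = (obs−exp)/√exp, chi² = Σ residual²). Per-cell significance
collapses each cell to a 2×2 table [[cell, rest of row],
[rest of column, remainder]] with a two-sided Fisher exact test — one
concrete operationalization of per-cell stars on a residual heatmap.

## Synthetic trio generator

`simulate_trio` draws, per gene: a baseline TPM (log-normal, median 50,
σ_log 0.6 — the mid-range where the Fisher classifier is informative); a
regulatory category that fixes the parental log2 ratio Δ and cis log2
component γ (conserved (0,0); cis-only (L,L); trans-only (L,0);
enhancing (L,L/2); compensating (L,−L/2); compensatory (0,L/2)); and an
additivity class that fixes the F1 mean (MPP, high, low, 1.5×high,
0.5×low). Parents sit at baseline·2^(±Δ/2); the F1 P2-allele fraction is
r = 2^γ/(1+2^γ), making the cis component of the allelic ratio equal the
planted cis effect by construction. SPE genes are drawn among
cis-only/trans-only genes; their silent parent is exactly 0 and, for
cis-consistent SPE, the corresponding hybrid allele is silent too
(r ∈ {0,1}). Under-dominant cannot be planted on an SPE gene (0.5×0
equals the low parent exactly, so the label would not be identifiable).

Counts are negative-binomial with Var = μ + αμ², α = 0.002 by default —
replicate CVs of ~5–10% at moderate expression, appropriate for
replicates sampled simultaneously under identical conditions, which is
the design this generator emulates. Field datasets with looser replicate
control have larger dispersion, and the pooled-count Fisher tests would
then over-reject; the calibration and recovery results certify the
statistical machinery under the stated noise model, not performance on
arbitrary real data. `nb_dispersion=None` switches to noise-free mode
(counts equal rounded means, TPM layer carries planted means exactly);
`0.0` gives pure Poisson. Sequencing depth is parameterized as reads per
TPM unit (default 20, i.e. a 20M-read library), and F1 allele totals are
Poisson around `allele_depth` (default 500). Planted parental effects
default to |log2FC| ~ N(2.0, 0.4) truncated at ≥ 1.5: effects below
~2.8-fold at panel-typical TPMs fall inside the Fisher indifference zone
described above, so smaller planted effects would carry class labels the
test provably cannot certify. All draws flow from one `numpy` Generator
seeded by `SimConfig.seed`; identical configs are bit-reproducible.

## Benchmark sizes and numerical conventions

The packaged benchmarks use 1,200–2,000 genes × 1 tissue × 3 replicates
(null calibration at 10,000 genes, allele depth 200), recovery measured
on planted effects ≥ 2-fold with min-parent TPM ≥ 50, and cis/trans
recovery at observed allele depth ≥ 500 with category proportions
weighted toward cis/trans so each class holds several hundred genes.
Fisher p-values come from `scipy.stats.fisher_exact`, the binomial test
from `scipy.stats.binomtest`; the test suite checks both against exact
integer-arithmetic enumeration (`math.comb`/`fractions`) to 1e-10.
Degenerate inputs follow fixed conventions: equal TPMs short-circuit to
p = 1; a zero row in the trans test carries no ratio information and
returns p = 1 with a warning; identical constant groups in the
flanking-variant Welch test return p = 1; t-test pairs with a singleton
group are skipped.

## Known limitations

* No dispersion-modelled DE test is included; the internal Fisher DE is
  a stand-in for self-contained runs.
* SNP-to-gene aggregation is plain summation; reference-mapping bias and
  phasing uncertainty are not modelled.
* The additivity Fisher test's power profile (floor at low TPM,
  over-rejection at very high TPM under biological noise) is inherent to
  testing TPMs as per-million counts.
* Gene–gene correlation, mean–dispersion trends and tissue-correlated
  effects are not simulated; per-gene, per-tissue draws are independent.
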