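# triohet

Trio (parent–parent–hybrid) transcriptome analysis for heterosis studies.

Heterosis — the superior performance of an F1 hybrid over its inbred
parents — leaves footprints in the hybrid transcriptome. Given replicated
expression profiles of two parents (P1, P2) and their F1 across tissues,
plus F1 allele-resolved read counts, `triohet` answers the standard
questions of a trio design:

* **Parental divergence** — which genes are differentially expressed
  between the parents (adjusted *P* < 0.05 and |log2FC| ≥ 1), how large
  are the changes (≥2/≥4/≥8-fold bins), and which show **single-parent
  expression** (SPE: TPM ≥ 1 in one parent, TPM < 0.1 and below the 1st
  percentile in the other, with a ≥10-fold gap)?
* **Expression additivity** — is the hybrid's level TPM_F1 at the
  mid-parent value TPM_MPP = (TPM_P1 + TPM_P2)/2 (additive), at the
  high/low parent (dominant/recessive), or outside the parental range
  (over-/under-dominant)? Decided by two-sided Fisher exact tests of F1
  against MPP, high and low parent on per-million contingency tables at
  *P* = 0.05.
* **Allele-specific expression (ASE)** — after SNP-level filtering (≥10
  reads per allele, minor fraction ≥ 2%) and gene-level aggregation, is
  the F1 allelic ratio off 50:50 (exact binomial test), and how strong is
  the bias (allelic fold change aFC = log2 of the allele-count ratio)?
* **cis/trans regulatory divergence** — combining the parental difference
  (A), the hybrid allelic difference (B) and a parental-ratio vs
  allelic-ratio comparison (C) into seven categories: cis-only,
  trans-only, cis+trans enhancing/compensating, compensatory, conserved,
  ambiguous. cis effects are inherited as allelic imbalance in the
  hybrid; trans effects act on both alleles and leave them balanced.
* **Pattern enrichment** — are regulatory categories and hybrid
  expression classes associated (Pearson chi-square of independence,
  per-cell residuals (obs−exp)/√exp, per-cell Fisher exact stars)?

A synthetic trio generator (`triohet.simulate`) plants all of this
structure — negative-binomial counts, parental fold changes, additivity
classes, SPE genes, cis/trans architectures with matching allele counts —
so every stage can be benchmarked against known truth without any
external data. Replicate quality control (pairwise Pearson *r* < 0.85
flags a sample) and expression-breadth classes
(silent / tissue-specific / intermediate / constitutive at 20%/80% of
tissues) round out the toolkit.

## Worked example

`examples/01_simulate_and_classify.py` simulates 500 genes in one tissue
(3 replicates, sequencing noise on) and classifies hybrid expression:

```
hybrid expression classes among parental DEGs (n=236):
  additive                59.3%
  dominant_P1              5.9%
  dominant_P2              7.2%
  recessive_P1             9.7%
  recessive_P2             7.2%
  over_dominant            6.8%
  under_dominant           3.8%
and among non-DEGs (n=264):
  additive                79.5%
  over_dominant           11.0%
  under_dominant           9.5%

agreement with the planted truth: 92.2%
```

Most genes are additive in the hybrid; among parental DEGs a sizeable
minority sits at one parent's level (dominant/recessive) or outside the
parental range, and the calls recover 92% of the planted classes under
noise. `examples/02_ase_and_cistrans.py` does the same for ASE and
cis/trans classification, and `examples/03_full_pipeline.py` runs the
whole pipeline from TSV files, equivalently to the CLI:

```sh
triohet simulate --outdir sim --seed 5 --n-genes 300
triohet run-all --tpm sim/tpm.tsv --counts sim/counts.tsv \
    --samples sim/samples.tsv --allele-counts sim/allele_counts.tsv \
    --outdir out
```

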