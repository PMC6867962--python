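# Methods

## Model and procedure

The pipeline quantifies, per drug and per pair of populations, whether the
drug's gene pathway carries more potentially functional,
population-differentiated variation than random gene sets of the same size
and length profile. It is a chain of five computations:

1. **Allele frequencies.** Per-population alternate-allele frequencies are
   counted from called genotypes only (missing calls leave both numerator
   and denominator), with the per-site per-population called count nₖ
   retained, since the F_ST estimator weights by it.
2. **Pairwise F_ST.** The Nei-style estimator F_ST = (H_T − H_S)/H_T with
   sample-size-weighted within-heterozygosity H_S and total heterozygosity
   H_T evaluated at the weighted mean frequency M = Σnₖpₖ/N. The weighted M
   is a deliberate choice: the definition of M as "the mean frequency" is
   ambiguous, and only the weighted version guarantees H_T ≥ H_S (Jensen's
   inequality on the concave heterozygosity function), hence F_ST ∈ [0, 1].
   The unweighted variant is retained behind `m_weighting="unweighted"`;
   the rare negative values it produces are clamped to zero and counted.
   Because heterozygosity at M is symmetric under M ↔ 1 − M, it is
   irrelevant which of the two alleles is labelled "more frequent"; the
   engine uses the alternate allele uniformly and a test asserts the
   relabelling invariance. A site is ineligible for a pair when either
   population has no called genotypes or when the pair is jointly
   monomorphic (H_T = 0); multiallelic sites are skipped at VCF ingestion
   with a logged count.
3. **pdSNP calling.** Per pair, eligible SNPs are ranked by F_ST descending
   and the top ceil(q·n) are called (q = 0.01 by default), with every SNP
   tied at the cutoff value included. The rank-based rule (rather than an
   interpolated percentile) is deterministic across platforms; ties only
   ever enlarge the set.
4. **Functional annotation.** SNPs are classified per (SNP, gene) into
   nsSNP/sSNP (coding consequence is an input column, as from a dbSNP-style
   annotation), 5′UTR, 3′UTR, intron, promoter — the 5,500 bases strictly
   upstream of the TSS, strand-aware, i.e. [TSS−5500, TSS−1] on + genes and
   mirrored on − genes — or intergenic. Within a gene the precedence is
   exon > UTR > intron > promoter; a SNP overlapping several genes annotates
   to each independently (pathways are gene-level, so multi-gene credit is
   the conservative choice). The pf decision table grants coding evidence
   (protein domain/functional region, modification site, NMD/ESE-ESS) to
   both coding classes, deleteriousness only to nsSNPs, codon-usage bias
   only to sSNPs, TFBS evidence to promoter/5′UTR, conserved-region and
   miRNA evidence to 3′UTR, splice evidence to introns, and selection-region
   evidence to any genic class; intergenic SNPs are never pf. Evidence is
   consumed as boolean flags — the upstream predictors are inputs, not
   reimplemented here.
5. **Enrichment and downstream summaries.** Drug–gene sources are unioned
   per drug (case-insensitive drug ids). The resampling null draws, per
   iteration, one gene per pathway gene from the same gene-length decile of
   the universe, without replacement within the iteration, and records the
   pf-pdGene proportion; Z = (p_obs − mean)/SD over 10,000 iterations.
   Within a stratum only the count of drawn genes that are pf-pdGenes
   matters, and under without-replacement sampling that count is exactly
   hypergeometric; the implementation draws the per-stratum counts directly.
   This is a distributional identity, not an approximation, and makes the
   full 10,000 iterations effectively free. Deciles are quantile bins on
   gene length with tied edges merged, so (near-)constant-length universes
   collapse to a single stratum; a stratum smaller than its required draws
   is widened to adjacent deciles (logged). A degenerate null (SD = 0)
   yields an undefined Z and "not significant" rather than ±∞. Both
   decision rules are computed — Z > 2.58 (normative) and the
   top-0.5-percentile empirical rule — and no multiple-testing correction
   is applied across drugs or pairs, deliberately: the analysis screens and
   reports effect profiles rather than controlling a family-wise error.

Group ranking takes, per drug, mode(Z) × (number of significant pairs),
where the mode is computed after rounding Z to one decimal (the mode of a
continuous score is otherwise ill-defined) with modal ties resolved to the
largest value, favouring the stronger-differentiation report; both choices
are config-exposed. Undefined Z values leave both factors. Group score is
the member-score mean over scored members; groups under three scored members
are excluded, and the top 30 per kind are flagged. Label/ADR analyses use
right-continuous empirical CDFs of significant-pair counts, a pooled
two-sided Student's t-test (the groups are treated as homoscedastic; Welch
is exposed), literature concordance as the fraction of curated (drug,
mapped-pair) cases with Z above threshold — the pair mapping is an input
column, since it is a curation, not an algorithm — and per-source ADR report
shares for the union of top-20 drugs with a flag for drugs significant in
≥ 10 pairs.

## Synthetic data generator

The generator emulates the study design: a 14-population panel (default
sample sizes 59, 79, 86, 97, 100, 89, 60, 58, 55, 54, 93, 87, 98, 14; 1029
individuals; configurable down to 2 populations), Balding–Nichols allele
frequencies — per population Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform
ancestral p, with drift F (default 0.05, a typical continental-scale human
value; F = 0 returns p exactly) — binomial diploid genotypes written as VCF
v4.2, non-overlapping genes with 5′UTR/alternating exon–intron/3′UTR
structure and lognormal lengths (median ≈ 18 kb), uniform SNP placement,
per-region Bernoulli evidence flags, drug pathways drawn uniformly from the
gene universe, multi-source splits with configurable overlap whose union
restores the pathway, logistic-link PGx labels, Poisson ADR counts with
source-specific base rates, and a literature table of planted cases.

Planted enrichment is defined on **truth** pf-pdGene labels: truth gene sets
are derived by running the F_ST machinery on the noise-free frequencies with
the panel sample sizes as weights, so recovery is well-posed before any
genotype noise enters. A drug planted at factor e for pair q draws each
pathway slot from that pair's truth pf-pdGene set with probability
min(1, e·background).

What the generator does **not** model: linkage disequilibrium, demography,
selection, multiallelic sites, isoform structure, or real database schemas.
Passing tests therefore demonstrate the statistical machinery — estimator
fidelity, null calibration, power against planted signal, end-to-end
reproducibility — not performance on real panels, where LD clustering of
pdSNPs within genes and database biases will matter.

All randomness derives from one master seed through named
`SeedSequence(seed, spawn_key)` sub-streams (one per generator stage, one
per (drug, pair) cell in the enrichment null), so stages are individually
regenerable and results are independent of execution order.

## Numerical choices and degenerate inputs

- F_ST under weighted M is clipped to [0, 1]; excursions are roundoff
  (≤ 1e-15 observed), not estimator behaviour.
- Zero sample size in a direct pairwise call is an error; in matrix mode it
  marks the site ineligible for that pair.
- pdSNP calling on a column with no eligible SNPs is an error; q outside
  (0, 1) is rejected.
- Empty literature/ADR tables short-circuit to empty outputs, not errors.
- The t-test returns p = 1 on zero pooled variance with equal means.

## Problem sizes

The test suite and analysis drivers run deliberately small studies — 2–4
populations, 2,000–20,000 SNPs, 60–150 genes, tens of drugs, 500–2,000
resampling iterations — chosen so the full suite completes in seconds while
every statistical check retains power (the hypergeometric null makes
iteration count nearly free; 2,000 iterations give a Monte-Carlo SE on the
null mean below 0.01 for 20-gene pathways). The acceptance script's
end-to-end run uses conditions where the truth pf-pdGene background per pair
is ~10% of the gene universe (20,000 SNPs, 150 genes covering ~60% of the
chromosome, evidence rates 0.2), the regime in which the planted-recovery
analysis is defined; the 14-population default exists for full-scale use.

## Known limitations

- The percentile significance rule uses the empirical 0.995 quantile of a
  discrete null; for very small pathways its attained level can sit well
  below 0.5%.
- The Z rule is mildly anti-conservative for small pathways (skewed null),
  which is why the calibration bound is 3% rather than the nominal ~0.5%.
- Truth pf-pdGene sets (from noise-free frequencies) and realized calls
  (from genotypes) differ by ranking churn at the top-1% boundary; planted
  recovery through the full pipeline therefore needs a non-trivial
  background, as discussed above.
- Region classification assumes 1-based inclusive intervals and biallelic
  SNPs throughout.
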