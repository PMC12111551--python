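# Methods

This note documents the statistical model behind `pleioscan`, the
synthetic data it is validated on, the numerical choices baked into the
implementation, and what the passing tests do and do not establish.

## The screening model

Each screen combines exactly two case-control GWAS — one cancer trait
and one autoimmune/autoinflammatory trait — on the log odds-ratio scale.
Before combination the autoimmune betas are multiplied by −1 while the
effect allele is kept, so a variant whose allele raises autoimmune risk
and lowers cancer risk presents *concordant* effects to the fixed-effect
model and can reach combined significance. With weights
`w_i = 1/se_i²`:

```
beta_meta = (w_a·beta_a + w_b·beta_b) / (w_a + w_b)
se_meta   = (w_a + w_b)^(−1/2)
Z         = beta_meta / se_meta
Q         = w_a·(beta_a − beta_meta)² + w_b·(beta_b − beta_meta)²
```

Q is referred to χ² with k−1 = 1 df; it is computed on the same
(flipped) scale used for the combination, so the heterogeneity decision
is consistent with the estimate it tests. Retention requires, jointly:
original per-trait p < `p_trait_max` (10⁻³), heterogeneity
p ≥ `p_het_min` (0.05), and combined p < `p_meta_max` (5×10⁻⁸). The
filter *order* is per-trait first, then meta + Q on survivors; the
retained set is order-invariant but the per-stage counts in the QC
report are specific to this documented order. Truly concordant variants
cancel after the flip (beta_meta ≈ 0) and additionally trip Q, so the
two guards are redundant by design rather than either being
load-bearing alone.

Assumptions inherited from the fixed-effect model: the two cohorts are
independent (no sample overlap), effects are homogeneous after the
flip, and the per-study estimates are asymptotically normal. No
random-effects fallback, genomic control or overlap correction is
offered — heterogeneous variants are screened *out*, not re-modelled.

## Clumping and annotation

Clumping is single-level plink-style greedy selection at
`r2_lead = 0.1`: the most significant unassigned SNP leads and absorbs
unassigned same-chromosome SNPs with r² ≥ 0.1; after exhaustion, clumps
whose member spans lie within `merge_distance = 1 Mb` (block-boundary
distance, not lead-to-lead) merge into one locus while every clump lead
remains a distinct lead SNP. Cross-pair uniqueness of leads is by rsid
identity, not LD. Significance ranking uses a −log10 p column computed
via the normal log-survival function, because two-sided p-values
underflow float64 around |Z| ≈ 38 and the literal p ordering would
degenerate to the positional tie-break inside strong signals. Ties
break by position then rsid, so runs are reproducible.

Nearest-gene distance is 0 inside the gene body, else the smaller of
the distances to the 1-based inclusive interval ends; ties break by
distance-to-start, then symbol. No distance cap is applied. Pathway
overrepresentation is the exact hypergeometric upper tail with the gene
annotation table as the universe; ranking for the "top 10 per database"
selection uses the raw p (BH-adjusted values are reported but not used
for cutting), and "immune-related" pathway names are matched by a
configurable case-insensitive keyword list (interferon, TCR, BCR,
cytokine, inflammat, immun, leukocyte, t-cell, natural killer,
dendritic) as a reproducible stand-in for expert judgment.

## Harmonization and sign conventions

Trait pairs join on rsid (with position concordance enforced where both
sides report it). Allele reconciliation handles label swaps (negate
beta, complement eaf), strand flips (relabel) and both at once;
palindromic SNPs (A/T, C/G) are dropped when either side's effect-allele
frequency falls in the configurable ambiguity window (0.4, 0.6) or is
missing, and otherwise resolved by frequency concordance. The
autoimmune sign flip is recorded in table metadata and guarded against
double application; the screen refuses unflipped input. Direction
strings in the output ("+-" etc.) are always on the *original* trait
scales. The eQTL alignment step defines the cancer-risk allele as the
effect allele when the cancer beta is positive, else the other allele,
re-expresses the eQTL Z for that allele (negating on swap), and declares
palindromic or incompatible allele sets unresolvable rather than
guessing.

## The synthetic-data generator

The generator produces every input the screen consumes, deterministically
for a given config + seed.

**Genotypes.** Each LD block is a latent Gaussian AR(1) chain thresholded
into two independent haplotypes per individual at the MAF quantile.
Thresholding attenuates correlation, so the latent correlation of every
adjacent pair is *calibrated* (bivariate-normal CDF + Brent root
finding, cached) such that the realized adjacent genotype correlation
equals `block_rho`; correlation then decays approximately geometrically
within a block and is zero across blocks. MAFs share a block-level base
value drawn from `maf_range` with ±0.02 jitter — variants in strong LD
necessarily have similar frequencies, and this keeps the calibration
target attainable. Defaults: 50 blocks of 8 SNPs, 2000 reference
individuals, MAF in (0.15, 0.45).

**Summary statistics.** Per-SNP marginal effects are induced from the
planted causal effects through the empirical within-block LD
(`beta_j = Σ r_jc · (sd_c/sd_j) · beta_c`). Standard errors use the
case-control asymptotic formula `se = 1/sqrt(2·n_eff·p(1−p))` with
`n_eff = 4/(1/cases + 1/controls)`; defaults are 50k cases / 50k
controls per trait, the scale of the large source GWAS. The default
*analytic* mode draws `beta_hat ~ N(beta_marginal, se²)` with
independent errors per SNP — distributionally exact under asymptotics
and fast at any cohort size. The opt-in *phenotype* mode simulates
binary outcomes under a logistic model (intercept set from the design
case fraction) for explicitly generated cohorts and fits per-SNP
logistic regressions by vectorized Newton iterations; it exists for
end-to-end realism checks at small n, not for production-scale runs.
Planted effect classes: `opposite` (the screen's target), `concordant`,
`heterogeneous` (opposite signs, very unequal magnitude, tripping Q),
`a_only`/`b_only`, `null`. A fraction of trait-B rows can be emitted
with swapped or strand-complemented allele labels to exercise
harmonization; generated allele pairs are non-palindromic by default so
those perturbations are always resolvable.

**Expression.** One latent infiltration factor per cohort; marker genes
and driven genes load on it with `infiltration_loading` (default 0.9,
implying a product-moment correlation of ~0.81 between any two loaded
genes), all other genes are independent noise, and every gene row is
Z-scored across samples. Defaults: 4 cohorts × 500 samples, mirroring a
four-cancer-cohort design at realistic TCGA cohort sizes.

**What the generator does not emulate:** realistic human LD maps,
population structure, relatedness, imputation error, sample overlap
between cohorts, correlated sampling errors between LD neighbours (the
analytic mode draws them independently), X chromosome, indels, and any
non-factor covariance in expression (batch effects, tumor purity).
Passing recovery tests therefore demonstrate that the pipeline's logic
is correct under the model the screen itself assumes — not that the
screen is robust to confounding a real multi-GWAS analysis can contain.

## Validation scenarios and problem sizes

The packaged scenarios fix the study conditions used by the tests and
the acceptance script: null calibration on 10⁵ effect-free SNPs
(expected: zero full-screen survivors; Q rejection at the nominal 5%);
recovery of 20 planted opposite-effect loci at |beta| = 0.15 with
50k/50k per trait (block_rho 0.95, so each causal SNP has several tags
at r² ≥ 0.8 — recovery tolerates the ~5% per-SNP false heterogeneity
exclusion by accepting any lead in r² ≥ 0.8 LD with the causal variant)
alongside 20 concordant decoys (expected: none recovered); and
expression prioritization of 5 driven among 32 candidate genes
(expected: exactly the driven set). The IVW/Q closed forms are checked
against 60-digit exact rational arithmetic on 10⁴ random inputs at
1e-10 relative error, and clumping against an independently coded
stepwise reference on 200 random ≤15-SNP instances including planted
p-value ties.

## Numerical and I/O choices

- Two-sided p-values via the normal survival function (accurate into
  subnormals); Z = 0 maps to p = 1 exactly; ranking via log-space
  −log10 p as above.
- Degenerate inputs: non-positive se is a domain error; constant
  vectors make Spearman's ρ undefined (NaN with a warning, never a
  silent 0); monomorphic SNPs get zero off-diagonal r² and a flag, and
  a planted effect on one is a generation error.
- Duplicate rsids within a file keep the smallest-p record; a missing p
  column is recomputed as 2·Φ(−|beta/se|), a missing se derived from p.
- Summary statistics are written at 17 significant digits and parsed
  with numpy's correctly rounded float parser, so write→read round-trips
  bit-exactly (pandas' fast parser does not guarantee this).
- MAF/info QC thresholds are inclusive at the boundary (exclusion is
  strict `<`), and records lacking eaf or info pass the corresponding
  filter, matching sources that do not report those metrics.

## Known limitations

- k = 2 studies per meta-analysis by construction; the many-trait
  design is expressed as independent pairwise screens plus rsid-level
  lead deduplication.
- The immune-pathway keyword list is a proxy for manual curation; with
  other pathway nomenclatures it needs re-configuring.
- Expression prioritization treats the supplied matrices as
  authoritative (no normalization is re-done) and requires all four
  markers in every cohort.
- eQTL alignment consumes one user-supplied record per (SNP, gene) and
  does not arbitrate between tissues or sources.
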