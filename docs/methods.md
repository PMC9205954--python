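# Methods

## Cohort model and outcomes

The unit of analysis is a CRC case with (a) genome-wide imputed germline
dosages in [0, 2], (b) targeted tumor sequencing summarized as a per-gene
binary indicator — 1 if the tumor carries at least one non-silent SNV or
indel in the gene — plus per-sample burden counts (non-silent SNVs,
non-silent indels, non-synonymous point mutations), and (c) covariates: age
at diagnosis, sex, study of origin, and ten genetic principal components
supplied as inputs (PC computation and relatedness filtering are upstream of
this package).

Hypermutated tumors (mismatch-repair/polymerase-deficient biology) carry an
order of magnitude more mutations and would otherwise dominate every
per-gene outcome, so analyses run twice: in the non-hypermutated stratum,
and in the combined sample with hypermutation status as a covariate.
Hypermutation is classified from the non-synonymous point-mutation count,
either at the fixed headline threshold of ≥23 or data-driven ("valley"
method): the count histogram is smoothed with a centered moving average
(window 5), the two highest local maxima at least 5 counts apart are taken
as modes (a mode must reach 1% of the dominant mode's height, which keeps
far-tail ripples from qualifying), and the threshold is the argmin strictly
between them, ties resolved toward the smaller count. All constants are
keyword arguments. Genes enter an analysis when their non-silent carrier
fraction in the stratum is **at least** 5% (inclusive, configurable).

## Variant sets

Testing every genome-wide variant against every gene is hopeless at cohort
scale, so (variant, gene) pairs come from three a-priori sets, each pair
carrying machine-checkable provenance:

* **gwas_suggestive** — variants with overall-CRC-risk p strictly below
  1e-5, paired with every analyzed gene.
* **functional** — any of: variant in an exon of the gene; within 1000 bp
  upstream of the TSS (strand-aware; offset 1..1000); within 200 kb of the
  gene body in either direction AND inside a variant enhancer locus (VEL);
  within 200 kb AND inside a distal promoter/enhancer linked to that gene
  in digestive or immunology tissue; beyond 200 kb AND inside an enhancer
  linked to the gene by expression AND inside a VEL. The gene body is the
  union span of the gene's exons and distances are measured from its
  nearest edge; all distance thresholds are inclusive. Rule (d)/(e)
  enhancer membership requires an explicit gene link in the annotation
  track, not mere proximity. Genes without annotation, and a configurable
  sex-chromosome exclusion list (default AMER1, BCOR, MXRA5, USP9X, which
  lack GWAS/functional annotation), are dropped with logged warnings.
* **cna_region** — variants inside recurrent somatic CNA regions, paired
  with every analyzed gene on the same chromosome (the paired gene need not
  be the region's own target gene; this deliberately admits trans-like
  relationships).

## Multiple testing

Within a set, neighboring variants are strongly correlated, so a per-variant
Bonferroni correction is replaced by the Li–Ji effective number of tests:
for eigenvalues λᵢ of the Pearson dosage-correlation matrix,
M_eff = Σᵢ [I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)], computed per chromosome and summed
(between-chromosome LD is taken as zero; this is also what keeps the
eigendecomposition tractable). Negative numerical eigenvalues are clipped to
zero, and eigenvalues are rounded to 10 decimals before the floor so that a
value numerically ε below an integer does not lose a whole unit — the
estimator is discontinuous at integers, and the rank-deficient extremes
(identity → p, all-ones → 1) must be exact. The significance threshold is
α / (n_outcomes × M_eff) with n_outcomes the number of genes tested (1 for
the summary-statistics re-analysis).

## Association engine

Each pair is fit by maximum-likelihood logistic regression (IRLS via
statsmodels GLM) with additive dosage coding; study enters as indicator
contrasts. Tests are two-sided Wald (the reported odds ratios with 95% CIs
are `exp(β ± 1.96·se)`), which at stratum-scale n is very slightly
conservative in the far tail — a property quantified by the calibration
tests rather than corrected. Quasi-separated or non-convergent fits (|β| ≥
15, failed IRLS, or degenerate SE) are retained in the output flagged
`converged = False` and excluded from significance calls, never silently
dropped. The scan reports its most associated pair whether or not it clears
the threshold.

## GRS mixed-effects score test

The genetic risk score is the weighted dosage sum over known CRC risk
variants; weights arrive pre-adjusted for winner's curse and are never
re-derived here. For an outcome y (total non-silent burden as a count, or a
pathway mutation indicator as binary) the null model includes covariates and
the GRS. Three p-values are reported:

* `p_pi`: Wald p of the GRS coefficient (binary: logistic; count:
  log-linear quasi-likelihood with Pearson-χ² variance inflation, since
  burden counts are overdispersed);
* `p_tau`: score statistic Q = Σⱼ (gⱼ′(y − μ̂))² over the individual
  variant dosage columns, referred to a Satterthwaite moment-matched
  chi-square. The null covariance of the score vector is
  V = φ·(G′WG − G′WX(X′WX)⁻¹X′WG) with W the GLM working weights, giving
  scale c₂/c₁ and df c₁²/c₂ from c₁ = tr(V), c₂ = tr(V²). Zero-variance
  dosage columns are removed first (they carry no signal and would distort
  nothing but are excluded for cleanliness);
* `p_overall`: Fisher's combination −2(ln p_pi + ln p_tau) on χ²(4); with
  no residual variants the test degenerates to p_overall = p_pi.

This is an original implementation of the mixed-effects score-test
structure, validated by type-I-error calibration simulation (overall
rejection 0.049 at nominal 0.05 in the shipped acceptance check) rather
than against any external package.

## CNA-region GWAS re-analysis

Summary statistics (per-variant EAF, log-OR, SE, p) are restricted to CNA
regions with inclusive 1-based bounds, thresholded strictly below
α / M_eff, and clumped greedily: the smallest-p remaining variant becomes a
lead and removes all remaining same-chromosome variants within ±500 kb
(a 1-Mb window read as an exclusion radius — the GWAS clumping norm; a
fixed-tile alternative would merge adjacent independent signals). Ties
break by (chromosome, position), so output is independent of input order.
Leads are flagged known when a supplied known locus lies within 1 Mb on the
same chromosome. The gain-vs-loss test forms the 2×2 table of region
direction × contains-a-lead and computes the two-sided Fisher exact p by
full hypergeometric enumeration (probabilities ≤ the observed table's, with
the conventional 1+1e-7 tie tolerance); counting regions-with-≥1-lead
rather than loci avoids double-weighting a region with two leads.

## Synthetic-data generator

The generator is the package's test bed and demo substrate; its defaults
emulate the targeted-sequencing study population.

* **Genotypes.** Variants sit in LD blocks laid out deterministically
  across chromosomes 1–22. Per block and haplotype, an exchangeable-
  correlation latent normal (r = 0.6 by default) is thresholded at the
  EAF quantile; two haplotypes sum to a dosage. `within_block_r` is the
  latent haplotype correlation — the induced dosage correlation is lower
  (tetrachoric attenuation), which only matters if one needs an exact
  dosage-scale r.
* **Burden.** Non-silent totals draw from a two-component negative-binomial
  mixture, mixed 241:1134 (hypermutated fraction 0.175). Component means
  (5.36, 45.42) are calibrated so the component medians are 5 and 44 at
  the default sizes (9.5, 12). The hypermutated size parameter is chosen
  for the defining feature of the real distribution — two clearly
  separated peaks with an interior valley — rather than its raw SD, which
  in real cohorts is inflated by a few ultramutated outliers that a
  two-parameter NB cannot capture jointly with the gap; consequently the
  generator under-represents the extreme right tail (real maxima reach
  several hundred mutations). Indels split off binomially (18% / 29% per
  class), and non-synonymous point counts are identified with the
  non-silent SNV count (binomial thinning keeps the NB family and size).
  The "true" valley recorded in the truth object is the valley functional
  applied to the expected histogram, i.e. exactly what the detector
  estimates.
* **Gene indicators.** logit P(Y_g = 1) = intercept_g + hyper_shift·hyper +
  Σ planted β·dosage, with per-gene intercepts jittered around
  logit(baseline carrier frequency) and a hypermutation shift of +2.2
  log-odds — a modelling convenience (hypermutated tumors mutate every
  gene more often), not an estimate of any real cohort quantity. The SNV
  total is raised where needed so a sample mutated in g genes carries at
  least g non-silent mutations.
* **Annotations.** Genes are anchored to LD blocks so that, by
  construction, each functional rule matches at least one variant
  (exonic, promoter-window, near-VEL, digestive-enhancer, and — when a
  second block shares the chromosome — distal expression-linked
  enhancer ∩ VEL). 37 CNA regions (configurable) with both gain and loss
  labels span the block landscape.
* **Summary statistics.** Null variants draw Z ~ N(0,1); planted loci get
  fixed Z (defaults: six in-CNA loci on distinct chromosomes, five of them
  listed as known, plus two outside any region). SEs follow the
  case–control information 1/√(2p(1−p)·n·φ(1−φ)) at n = 125,478, φ = 0.5.
  Optionally the cohort's own variants receive summary rows with a few
  suggestive hits so the gwas_suggestive set is exercisable end to end.
* **Covariates** are drawn independently of genotypes (age ~ N(61.6,
  12.2²), 49.2% male, four studies with the cohort's weights, PCs ~
  N(0,1)).
* **Determinism.** Every stage derives its own substream from the single
  config seed; identical config + seed reproduce byte-identical outputs.

What passing tests on this generator do **not** show: robustness to
population stratification that PCs fail to absorb (covariates are
independent of genotypes by default), to genotyping/imputation error, to
realistic recombination landscapes and long-range LD, or to the extreme
burden right tail. The generator's logistic outcome model matches the
analysis model, so parameter-recovery results speak to implementation
correctness, not to model misspecification on real data.

## Numerical and design notes

* Internal coordinates are 1-based inclusive everywhere; BED is converted
  at the I/O boundary, and the conversion is an involution.
* Missing dosages are mean-imputed per variant at load (the M_eff
  computation needs complete matrices); imputation counts are logged.
  Variants are kept when minor-side frequency exceeds the MAF cutoff
  (default 1%), and loaders canonicalize row order so shuffled input files
  yield identical state.
* Variant identity is chrom:pos:ref:alt; rsID-style labels ride along.
* The problem sizes used in the shipped calibration checks (e.g. 600-case
  cohorts for the null-scan replicates, 1134 for fit-level calibration,
  200 replicates for effect recovery) are chosen as the smallest scales at
  which the quantities under test are stable; all are plain keyword
  arguments for anyone wanting larger runs.

## Known limitations

* Somatic variant calling, imputation, PCA/relatedness, winner's-curse
  weight derivation, and derivation of VELs/enhancer links/CNA regions are
  out of scope: all arrive as inputs.
* Wald tests only; no Firth correction or score/LRT alternative, so very
  sparse gene outcomes rely on the non-convergence flag rather than a
  penalized fit.
* The M_eff estimator is the eigenvalue (Li–Ji) form only.
* The gain/loss enrichment test conditions on the observed lead count; it
  does not model region length or variant density differences between gain
  and loss regions.
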