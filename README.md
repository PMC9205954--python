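# gsassoc

Germline–somatic integration analysis for colorectal cancer (CRC) cohorts.

Colorectal tumors develop through distinct somatically altered pathways, and
the host (germline) genome may shape which genes become somatically mutated.
`gsassoc` implements, as a tested and reusable pipeline, the two complementary
analyses such a study runs:

1. **Targeted germline→somatic association.** For a cohort of CRC cases with
   genome-wide imputed genotype dosages and targeted tumor sequencing, test
   each germline variant against the binary outcome "tumor carries ≥1
   non-silent mutation in gene *g*", via logistic regression adjusted for age
   at diagnosis, sex, study, the top ten principal components and (in the
   combined stratum) hypermutation status:

   `logit P(Y_g = 1) = β₀ + β₁·dosage + γ′·covariates`

   Because a full GWAS per gene is underpowered at cohort scale, variants are
   drawn from three a-priori sets: (i) suggestive overall-CRC-risk variants
   (GWAS p < 1e-5), (ii) putative functional variants of each gene (exonic,
   promoter-proximal, near-gene enhancer/VEL, distal expression-linked
   enhancer ∩ VEL), and (iii) variants inside recurrent somatic
   copy-number-amplification (CNA) regions, paired with mutated genes on the
   same chromosome. Multiple testing is controlled at
   `α / (n_genes × M_eff)`, where the effective number of independent tests
   `M_eff = Σᵢ [ I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋) ]` is computed chromosome by
   chromosome from the eigenvalues λᵢ of the LD correlation matrix (the
   Li–Ji estimator). A genetic risk score (GRS = Σⱼ wⱼ·dosageⱼ over known
   CRC loci) is additionally tested against total tumor mutational burden
   and pathway-level mutation indicators with a mixed-effects score test
   (fixed GRS effect + variance-component test for effects not through the
   GRS, Fisher-combined).

2. **CNA-region-restricted GWAS re-analysis.** Overall-CRC-risk summary
   statistics from a large case–control GWAS are restricted to the recurrent
   somatic CNA regions, thresholded at `0.05 / M_eff`, clumped into 1-Mb
   lead-SNP loci, flagged known vs novel against a supplied locus list, and
   tested for gain-vs-loss enrichment with a two-sided Fisher exact test.

Real cohorts of this kind are controlled-access, so the package ships a
first-class synthetic-data generator that emulates every input: LD-blocked
dosages, covariates, a bimodal mutation-burden mixture (hypermutated vs not,
classified at ≥23 non-synonymous point mutations or at the valley of the
burden histogram), gene-level mutation indicators with plantable germline
effects, annotation tracks, and summary statistics with planted loci inside
and outside CNA regions. Every generator records its ground truth for
parameter-recovery testing.

## Worked example

Run the bundled demo (a 400-case synthetic cohort) end to end and render the
report:

```bash
gsassoc run-all --config src/gsassoc/data/demo.yaml --outdir demo_run --seed 7
gsassoc report --outdir demo_run
```

```
Mutation burden by stratum:
  stratum   n  mean_nonsilent  sd_nonsilent  median_nonsilent  min_nonsilent  max_nonsilent
    hyper  68       50.161765     13.844133              47.0             26             91
non_hyper 332        6.460843      5.097980               6.0              0             38
 combined 400       13.890000     17.996878               6.0              0             91

CNA-region GWAS: {"n_in_region": 845, "meff": 798.99..., "threshold": 6.2578e-05,
                  "n_significant": 11, "n_loci": 6, "n_known": 5}

Lead SNPs in CNA regions:
    id  chrom     pos  eaf       OR            p region_label region_direction  known
lead00      1 5005250 0.31 1.062289 2.559625e-12        CNA00             gain   True
...
lead05      6 5005250 0.13 1.084073 1.046192e-11        CNA05             loss  False

Gain/loss enrichment: {"fisher_p": 0.6665, "table": {...}}
```

Reading this: the hypermutated stratum (17% of cases) carries a median of 47
non-silent mutations against 6 in the rest — the bimodal structure that
motivates stratified analysis. The CNA-restricted GWAS finds 11 significant
variants at the M_eff-corrected threshold, which clump into 6 independent
1-Mb loci; 5 sit near entries of the supplied known-locus list and one is
novel, and the Fisher test finds no gain-vs-loss imbalance (p = 0.67). All
six recovered leads are exactly the loci the generator planted.

Each stage is also exposed individually (`simulate`, `phenotype`,
`build-sets`, `meff`, `scan`, `grs-test`, `cna-gwas`), and the library API
(`gsassoc.*`) underneath is what all commands and tests call. A
`manifest.json` with config hash, per-stage output checksums and warnings
makes reruns verifiable: the same config and seed reproduce byte-identical
stage outputs.

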