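"""Synthetic study inputs with the statistical structure the analysis assumes.

The generator emulates a colorectal-cancer germline-somatic cohort:

* LD-blocked imputed genotype dosages. Each block draws a latent
  exchangeable-correlation multivariate normal per haplotype, thresholds it
  at the effect-allele-frequency quantile, and sums two haplotypes into a
  dosage in {0,1,2}. ``within_block_r`` is the latent (haplotype-level)
  correlation; the dosage correlation it induces is somewhat lower.
* A bimodal non-silent mutation-burden distribution: a two-component
  negative-binomial mixture whose component medians are 5 (non-hypermutated)
  and 44 (hypermutated) at the default means/dispersions, mixed 1134:241.
* Gene-level binary somatic mutation indicators from a logistic model with
  per-gene intercepts, an additive hypermutation-class shift, and optional
  planted germline log-odds effects.
* Annotation tracks (gene models, variant enhancer loci, enhancer-gene
  links, CNA regions) laid out so that every functional variant-set rule is
  exercised by at least one variant.
* GWAS summary statistics for a large case-control study with planted
  associated loci inside and outside CNA regions; null variants draw their
  Z-score from the standard normal.

All generators are pure functions of (config, seed): per-stage random
substreams are derived deterministically from the single config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .containers import (
    COUNT_COLUMNS,
    SUMMARY_STAT_COLUMNS,
    AnnotationBundle,
    GenotypeMatrix,
    SomaticGeneMatrix,
)
from .somatic import valley_of_histogram
from . import io as gio

# substream tags (second word of the seed sequence)
_STAGES = {
    "genotypes": 1, "covariates": 2, "somatic": 3, "annotations": 4,
    "summary_stats": 5, "grs": 6,
}

_CHROMS = [str(c) for c in range(1, 23)]
_VARIANT_SPACING = 1_500          # bp between variants within a block
_BLOCK_STRIDE = 3_000_000         # bp between blocks sharing a chromosome
_BLOCK_BASE = 5_000_000           # genomic start of the first block slot


@dataclass(frozen=True)
class PlantedEffect:
    """A germline-to-somatic effect: per-dosage log odds ratio on one gene."""
    variant_id: str
    gene: str
    beta: float


@dataclass(frozen=True)
class PlantedLocus:
    """A planted GWAS signal (Z-score scale) at a fixed genomic position."""
    id: str
    chrom: str
    pos: int
    eaf: float
    z: float
    in_cna: bool
    known: bool


@dataclass
class SimulationConfig:
    """All generative quantities of the synthetic cohort.

    Defaults emulate the targeted-sequencing study population: 1375 cases of
    which a fraction 241/1375 are hypermutated, burden mixture medians 5/44,
    covariates (age, sex, four studies, ten PCs), and a 125,478-sample GWAS.
    """

    seed: int = 17
    # genotypes
    n_samples: int = 1375
    n_blocks: int = 40
    variants_per_block: int = 25
    within_block_r: float = 0.6
    eaf_range: tuple[float, float] = (0.05, 0.95)
    # somatic outcome model
    n_genes: int = 64
    planted_effects: tuple[PlantedEffect, ...] = ()
    baseline_carrier_freq: float = 0.04
    carrier_freq_jitter_sd: float = 1.0
    hyper_fraction: float = 241 / 1375
    hyper_shift: float = 2.2
    # burden mixture (non-hyper, hyper): NB means calibrated so component
    # medians are 5 and 44 at the default dispersions (size parameters)
    burden_means: tuple[float, float] = (5.36, 45.42)
    burden_dispersions: tuple[float, float] = (9.5, 12.0)
    indel_fraction: tuple[float, float] = (0.18, 0.29)
    # covariates
    age_mean: float = 61.6
    age_sd: float = 12.2
    sex_male_fraction: float = 0.492
    study_weights: dict = field(default_factory=lambda: {
        "CORSA": 0.077, "CPSII": 0.159, "OFCCR": 0.463, "SFCCR": 0.301})
    pc_scale: float = 1.0
    # annotations
    n_cna_regions: int = 37
    cna_flank: int = 400_000
    # GWAS summary statistics
    gwas_n_variants: int = 8000
    gwas_n: int = 125_478
    gwas_case_fraction: float = 0.5
    gwas_planted: tuple[PlantedLocus, ...] | None = None
    # also emit summary-stat rows for the cohort's own variants, planting
    # suggestive (|Z|=5.5) signals at the first variant of this many blocks
    gwas_include_cohort_variants: bool = True
    gwas_cohort_hits: int = 5
    # GRS
    n_grs_variants: int = 20

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("n_blocks", "variants_per_block", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.eaf_range
        if not (0.01 < lo <= hi < 0.99):
            raise ValueError("eaf_range must satisfy 0.01 < lo <= hi < 0.99")
        for p in (self.baseline_carrier_freq, self.hyper_fraction,
                  self.sex_male_fraction, self.gwas_case_fraction):
            if not (0 <= p < 1):
                raise ValueError(f"probability {p} outside [0, 1)")
        if any(d <= 0 for d in self.burden_dispersions):
            raise ValueError("burden dispersions must be > 0")
        if any(m <= 0 for m in self.burden_means):
            raise ValueError("burden means must be > 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGES[stage]])


@dataclass
class CohortTruth:
    """Ground truth retained for parameter-recovery tests."""
    planted_effects: pd.DataFrame   # variant_id, gene, beta
    hyper_status: pd.Series         # latent class per sample
    true_valley: int | None         # valley of the expected nonsyn histogram
    gwas_planted: pd.DataFrame      # id, chrom, pos, eaf, z, in_cna, known
    known_loci: pd.DataFrame        # chrom, pos, id, citation


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    somatic: SomaticGeneMatrix
    annotations: AnnotationBundle
    summary_stats: pd.DataFrame
    grs_weights: pd.DataFrame
    pathways: dict[str, list[str]]
    truth: CohortTruth

    def __post_init__(self) -> None:
        if list(self.truth.hyper_status.index) != self.genotypes.samples:
            raise ValueError("truth labels do not align with sample ids")
        known = set(self.genotypes.variants["id"])
        genes = set(self.somatic.genes)
        for _, row in self.truth.planted_effects.iterrows():
            if row["variant_id"] not in known:
                raise ValueError(f"planted variant {row['variant_id']} missing")
            if row["gene"] not in genes:
                raise ValueError(f"planted gene {row['gene']} missing")


# ---------------------------------------------------------------------------
# deterministic genomic layout (shared by genotypes and annotations)
# ---------------------------------------------------------------------------

def _block_chrom(block: int) -> str:
    return _CHROMS[block % len(_CHROMS)]


def _block_start(block: int) -> int:
    return _BLOCK_BASE + (block // len(_CHROMS)) * _BLOCK_STRIDE


def variant_layout(config: SimulationConfig) -> pd.DataFrame:
    """Positions of every simulated variant; pure function of the dimensions."""
    rows = []
    idx = 0
    for b in range(config.n_blocks):
        chrom, start = _block_chrom(b), _block_start(b)
        for i in range(config.variants_per_block):
            rows.append({
                "id": f"v{idx:05d}", "chrom": chrom,
                "pos": start + i * _VARIANT_SPACING,
                "ref": "A", "alt": "G", "block": b, "slot": i,
            })
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-blocked dosages: exchangeable latent normals thresholded per
    haplotype at the EAF quantile, two haplotypes summed per sample."""
    rng = config.rng("genotypes")
    layout = variant_layout(config)
    n, r = config.n_samples, config.within_block_r
    lo, hi = config.eaf_range
    eafs = rng.uniform(lo, hi, size=len(layout)) if hi > lo else np.full(len(layout), lo)
    dosages = np.empty((n, len(layout)))
    for b in range(config.n_blocks):
        cols = layout.index[layout["block"] == b].to_numpy()
        thresh = stats.norm.ppf(eafs[cols])
        block_dos = np.zeros((n, len(cols)))
        for _hap in range(2):
            shared = rng.standard_normal(n)[:, None]
            eps = rng.standard_normal((n, len(cols)))
            z = np.sqrt(r) * shared + np.sqrt(1 - r) * eps
            block_dos += (z < thresh).astype(float)
        dosages[:, cols] = block_dos
    variants = layout[["id", "chrom", "pos", "ref", "alt"]].copy()
    variants["eaf"] = eafs
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age, sex (1 = male), study and ten PCs, independent of genotypes."""
    rng = config.rng("covariates")
    n = config.n_samples
    studies = list(config.study_weights)
    w = np.array([config.study_weights[s] for s in studies], dtype=float)
    cov = pd.DataFrame({
        "age": np.round(rng.normal(config.age_mean, config.age_sd, n), 1),
        "sex": (rng.random(n) < config.sex_male_fraction).astype(int),
        "study": rng.choice(studies, size=n, p=w / w.sum()),
    }, index=[f"S{i:05d}" for i in range(n)])
    for k in range(1, 11):
        cov[f"PC{k}"] = rng.normal(0.0, config.pc_scale, n)
    cov.index.name = "sample"
    return cov


# ---------------------------------------------------------------------------
# somatic outcomes
# ---------------------------------------------------------------------------

def gene_names(config: SimulationConfig) -> list[str]:
    return [f"G{i:03d}" for i in range(config.n_genes)]


def expected_nonsyn_histogram(config: SimulationConfig,
                              upper: int = 400) -> np.ndarray:
    """Expected histogram of non-synonymous point-mutation counts.

    Non-synonymous counts are the binomial thinning of the non-silent total
    by (1 - indel fraction); a thinned NB stays NB with the same size.
    """
    h = config.hyper_fraction
    k = np.arange(upper + 1)
    pmf = np.zeros_like(k, dtype=float)
    for weight, mean, size, f_indel in (
        (1 - h, config.burden_means[0], config.burden_dispersions[0],
         config.indel_fraction[0]),
        (h, config.burden_means[1], config.burden_dispersions[1],
         config.indel_fraction[1]),
    ):
        mu = mean * (1 - f_indel)
        pmf += weight * stats.nbinom.pmf(k, size, size / (size + mu))
    return config.n_samples * pmf


def true_valley(config: SimulationConfig) -> int | None:
    """Valley of the expected count histogram under the same smoothing
    functional the detector applies; None when the mixture is unimodal."""
    try:
        return valley_of_histogram(expected_nonsyn_histogram(config))
    except ValueError:
        return None


def simulate_somatic(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
) -> tuple[SomaticGeneMatrix, CohortTruth]:
    """Burden counts from the NB mixture plus per-gene logistic indicators.

    logit P(Y_g = 1) = intercept_g + hyper_shift * hyper + sum planted beta * dosage
    """
    rng = config.rng("somatic")
    genes = gene_names(config)
    n = config.n_samples
    known_variants = set(genotypes.variants["id"])
    for eff in config.planted_effects:
        if eff.variant_id not in known_variants:
            raise KeyError(f"planted variant {eff.variant_id!r} not in genotypes")
        if eff.gene not in genes:
            raise KeyError(f"planted gene {eff.gene!r} not among simulated genes")

    hyper = (rng.random(n) < config.hyper_fraction).astype(int)

    # burden counts: NB mixture on the non-silent total, indels split off
    means = np.where(hyper == 1, config.burden_means[1], config.burden_means[0])
    sizes = np.where(hyper == 1, config.burden_dispersions[1],
                     config.burden_dispersions[0])
    f_indel = np.where(hyper == 1, config.indel_fraction[1],
                       config.indel_fraction[0])
    total = rng.negative_binomial(sizes, sizes / (sizes + means))
    indels = rng.binomial(total, f_indel)
    snv = total - indels

    # gene indicators
    intercepts = (logit(config.baseline_carrier_freq)
                  + config.carrier_freq_jitter_sd * rng.standard_normal(len(genes)))
    eta = np.tile(intercepts, (n, 1)) + config.hyper_shift * hyper[:, None]
    for eff in config.planted_effects:
        j = genes.index(eff.gene)
        eta[:, j] += eff.beta * genotypes.dosage(eff.variant_id)
    indicators = (rng.random((n, len(genes))) < expit(eta)).astype(int)

    # classification counts keep the drawn mixture; the SNV total is bumped
    # so a sample mutated in g genes carries at least g non-silent mutations
    nonsyn = snv.copy()
    needed = indicators.sum(axis=1)
    snv = np.maximum(snv, needed - indels)

    samples = genotypes.samples
    som = SomaticGeneMatrix(
        indicators=pd.DataFrame(indicators, index=samples, columns=genes),
        counts=pd.DataFrame(
            {"nonsilent_snv": snv,
             "nonsilent_indel": indels,
             "nonsyn_point": nonsyn},
            index=samples)[COUNT_COLUMNS],
    )
    truth = CohortTruth(
        planted_effects=pd.DataFrame(
            [asdict(e) for e in config.planted_effects],
            columns=["variant_id", "gene", "beta"]),
        hyper_status=pd.Series(hyper, index=samples),
        true_valley=true_valley(config),
        gwas_planted=pd.DataFrame(
            columns=["id", "chrom", "pos", "eaf", "z", "in_cna", "known"]),
        known_loci=pd.DataFrame(columns=["chrom", "pos", "id", "citation"]),
    )
    return som, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(config: SimulationConfig) -> AnnotationBundle:
    """Gene models, VELs, enhancer-gene links and CNA regions.

    Genes are anchored to LD blocks so that, by construction, each rule of
    the functional variant-set builder matches at least one variant:
    an exonic variant, a promoter-window variant 600 bp upstream of the TSS,
    a near (<200 kb) variant inside a VEL, a near variant inside a
    digestive-tissue enhancer linked to the gene, and (when a second block
    shares the chromosome) a distant (>200 kb) variant inside an
    expression-linked enhancer that also lies in a VEL.
    """
    if config.variants_per_block < 5:
        raise ValueError("annotations require variants_per_block >= 5")
    rng = config.rng("annotations")
    layout = variant_layout(config)
    genes = gene_names(config)

    gene_rows, exon_rows, vel_rows, link_rows = [], [], [], []
    for j, gene in enumerate(genes):
        b = j % config.n_blocks
        rnd = j // config.n_blocks
        shift = rnd * 30_000  # later rounds sit downstream of the block
        block = layout[layout["block"] == b]
        chrom = block["chrom"].iloc[0]
        p = block["pos"].to_numpy() + shift
        strand = "+" if j % 2 == 0 else "-"
        if strand == "+":
            tss = int(p[1] + 600)
            start, end = tss, tss + 20_000
            exon_rows += [
                {"gene_id": gene, "chrom": chrom, "start": tss + 800, "end": tss + 1000},
                {"gene_id": gene, "chrom": chrom, "start": tss + 5000, "end": tss + 5200},
            ]
        else:
            tss = int(p[1] - 600)
            start, end = tss - 20_000, tss
            exon_rows += [
                {"gene_id": gene, "chrom": chrom, "start": tss - 1000, "end": tss - 800},
                {"gene_id": gene, "chrom": chrom, "start": tss - 5200, "end": tss - 5000},
            ]
        gene_rows.append({"gene_id": gene, "chrom": chrom, "strand": strand,
                          "tss": tss, "start": start, "end": end})
        if rnd == 0:
            # rule fixtures only for first-round genes (anchored on variants)
            vel_rows.append({"chrom": chrom, "start": int(p[2]) - 50,
                             "end": int(p[2]) + 50})
            link_rows.append({"chrom": chrom, "start": int(p[3]) - 100,
                              "end": int(p[3]) + 100, "gene_id": gene,
                              "tissue": "digestive", "expression_linked": False})
            partner = b + len(_CHROMS) if b + len(_CHROMS) < config.n_blocks \
                else (b - len(_CHROMS) if b - len(_CHROMS) >= 0 else None)
            if partner is not None:
                q0 = int(layout.loc[layout["block"] == partner, "pos"].iloc[0])
                link_rows.append({"chrom": chrom, "start": q0 - 100,
                                  "end": q0 + 100, "gene_id": gene,
                                  "tissue": "other", "expression_linked": True})
                vel_rows.append({"chrom": chrom, "start": q0 - 50, "end": q0 + 50})

    cna_rows = []
    for r in range(config.n_cna_regions):
        b = r % config.n_blocks
        chrom, start = _block_chrom(b), _block_start(b)
        # wrapped rounds shift away from the block so regions never stack
        start += (r // config.n_blocks) * 1_200_000
        span = (config.variants_per_block - 1) * _VARIANT_SPACING
        if r == 0:
            direction = "gain"
        elif r == 1:
            direction = "loss"
        else:
            direction = "gain" if rng.random() < 0.5 else "loss"
        cna_rows.append({
            "chrom": chrom, "start": max(1, start - config.cna_flank),
            "end": start + span + config.cna_flank,
            "label": f"CNA{r:02d}", "direction": direction,
        })

    return AnnotationBundle(
        genes=pd.DataFrame(gene_rows),
        exons=pd.DataFrame(exon_rows),
        vels=pd.DataFrame(vel_rows).drop_duplicates().reset_index(drop=True),
        enhancer_links=pd.DataFrame(link_rows),
        cna_regions=pd.DataFrame(cna_rows),
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def default_planted_loci(config: SimulationConfig,
                         annotations: AnnotationBundle) -> tuple[PlantedLocus, ...]:
    """Six well-separated in-CNA loci (five 'known', one novel) plus two
    signals outside any CNA region."""
    regions = annotations.cna_regions
    loci = []
    zs = [7.0, -8.0, 6.5, 7.5, -9.0, 6.8]
    eafs = [0.31, 0.52, 0.44, 0.81, 0.66, 0.13]
    picked = regions.drop_duplicates("chrom").head(6)
    for k, (_, reg) in enumerate(picked.iterrows()):
        pos = int((reg["start"] + reg["end"]) // 2)
        loci.append(PlantedLocus(
            id=f"lead{k:02d}", chrom=str(reg["chrom"]), pos=pos, eaf=eafs[k],
            z=zs[k], in_cna=True, known=(k < 5)))
    out_chroms = ["7", "8"]
    for k, chrom in enumerate(out_chroms):
        loci.append(PlantedLocus(
            id=f"out{k:02d}", chrom=chrom, pos=30_000_000, eaf=0.25,
            z=6.0, in_cna=False, known=False))
    return tuple(loci)


def simulate_summary_stats(
    config: SimulationConfig, annotations: AnnotationBundle,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-variant EAF, log-OR, SE and p for a large case-control GWAS.

    Returns (stats, planted_truth, known_loci). Null variants draw
    Z ~ N(0,1); planted loci get their configured Z. The log-OR standard
    error follows the case-control information 1 / sqrt(2 p (1-p) n phi(1-phi)).
    """
    rng = config.rng("summary_stats")
    m = config.gwas_n_variants
    chrom = rng.choice(_CHROMS, size=m)
    pos = rng.integers(4_000_000, 12_000_000, size=m)
    eaf = rng.uniform(0.05, 0.95, size=m)
    z = rng.standard_normal(m)
    ids = np.array([f"gw{i:05d}" for i in range(m)])

    planted = config.gwas_planted
    if planted is None:
        planted = default_planted_loci(config, annotations)
    rows = {"chrom": list(chrom), "pos": list(pos), "eaf": list(eaf),
            "z": list(z), "id": list(ids)}
    for locus in planted:
        rows["chrom"].append(locus.chrom)
        rows["pos"].append(locus.pos)
        rows["eaf"].append(locus.eaf)
        rows["z"].append(locus.z)
        rows["id"].append(locus.id)
    if config.gwas_include_cohort_variants:
        layout = variant_layout(config)
        z_cohort = rng.standard_normal(len(layout))
        hit_blocks = set(range(min(config.gwas_cohort_hits, config.n_blocks)))
        first = layout["slot"] == 0
        is_hit = (first & layout["block"].isin(hit_blocks)).to_numpy()
        z_cohort[is_hit] = 5.5 * np.where(np.arange(is_hit.sum()) % 2 == 0, 1, -1)
        rows["chrom"] += list(layout["chrom"])
        rows["pos"] += list(layout["pos"])
        rows["eaf"] += [float(np.mean(config.eaf_range))] * len(layout)
        rows["z"] += list(z_cohort)
        rows["id"] += list(layout["id"])
    df = pd.DataFrame(rows)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    phi = config.gwas_case_fraction
    info = 2 * df["eaf"] * (1 - df["eaf"]) * config.gwas_n * phi * (1 - phi)
    df["se"] = 1.0 / np.sqrt(info)
    df["beta"] = df["z"] * df["se"]
    df["p"] = np.minimum(2 * stats.norm.sf(np.abs(df["z"])), 1.0)
    df["ref"], df["alt"] = "A", "G"
    stats_df = (df[SUMMARY_STAT_COLUMNS]
                .sort_values(["chrom", "pos"]).reset_index(drop=True))

    planted_df = pd.DataFrame([asdict(p) for p in planted],
                              columns=["id", "chrom", "pos", "eaf", "z",
                                       "in_cna", "known"])
    known = planted_df[planted_df["known"].astype(bool)] if len(planted_df) \
        else planted_df
    known_loci = pd.DataFrame({
        "chrom": known.get("chrom", pd.Series(dtype=str)),
        "pos": known.get("pos", pd.Series(dtype=int)),
        "id": known.get("id", pd.Series(dtype=str)),
        "citation": "synthetic-known",
    }).reset_index(drop=True) if len(known) else pd.DataFrame(
        columns=["chrom", "pos", "id", "citation"])
    return stats_df, planted_df, known_loci


# ---------------------------------------------------------------------------
# GRS inputs
# ---------------------------------------------------------------------------

def simulate_grs_weights(config: SimulationConfig,
                         genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-allele log-OR weights for a genetic risk score over a spread of
    variants (one per block, emulating independent known risk loci)."""
    rng = config.rng("grs")
    picks = []
    per_block = max(1, config.n_blocks // max(1, config.n_grs_variants))
    blocks = list(range(0, config.n_blocks, per_block))[: config.n_grs_variants]
    layout = variant_layout(config)
    for b in blocks:
        picks.append(layout.loc[layout["block"] == b, "id"].iloc[0])
    weights = rng.normal(0.0, 0.08, size=len(picks))
    return pd.DataFrame({"variant_id": picks, "effect_allele": "G",
                         "weight": weights})


def default_pathways(config: SimulationConfig) -> dict[str, list[str]]:
    """Named gene sets in the style of the CRC driver pathways."""
    genes = gene_names(config)
    names = ["WNT_signaling", "TGFB", "IGF2_PI3K", "DNA_repair_MMR"]
    size = max(1, min(4, len(genes) // len(names)))
    return {name: genes[i * size:(i + 1) * size]
            for i, name in enumerate(names) if genes[i * size:(i + 1) * size]}


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    somatic, truth = simulate_somatic(config, genotypes, covariates)
    annotations = simulate_annotations(config)
    stats_df, planted_df, known_loci = simulate_summary_stats(config, annotations)
    truth.gwas_planted = planted_df
    truth.known_loci = known_loci
    grs_weights = simulate_grs_weights(config, genotypes)
    pathways = default_pathways(config)
    return SyntheticCohort(
        genotypes=genotypes, covariates=covariates, somatic=somatic,
        annotations=annotations, summary_stats=stats_df,
        grs_weights=grs_weights, pathways=pathways, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every downstream input format; returns the path of each output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": outdir / "dosages.tsv",
        "covariates": outdir / "covariates.tsv",
        "somatic": outdir / "somatic.tsv",
        "summary_stats": outdir / "summary_stats.tsv",
        "grs_weights": outdir / "grs_weights.tsv",
        "pathways": outdir / "pathways.tsv",
        "known_loci": outdir / "known_loci.tsv",
        "annotations": outdir / "annotations",
        "truth_planted": outdir / "truth_planted.tsv",
        "truth_hyper": outdir / "truth_hyper.tsv",
    }
    gio.write_dosages(cohort.genotypes, paths["dosages"])
    gio.write_covariates(cohort.covariates, paths["covariates"])
    gio.write_somatic(cohort.somatic, paths["somatic"])
    gio.write_summary_stats(cohort.summary_stats, paths["summary_stats"])
    gio.write_weights(cohort.grs_weights, paths["grs_weights"])
    gio.write_pathways(cohort.pathways, paths["pathways"])
    gio.write_known_loci(cohort.truth.known_loci, paths["known_loci"])
    gio.write_annotations(cohort.annotations, paths["annotations"])
    gio._write_tsv(cohort.truth.planted_effects, paths["truth_planted"])
    gio._write_tsv(
        cohort.truth.hyper_status.rename("hyper").reset_index()
        .rename(columns={"index": "sample"}),
        paths["truth_hyper"])
    return paths
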