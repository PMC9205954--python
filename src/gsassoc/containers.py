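"""In-memory containers shared across the pipeline.

Coordinate convention: all positions and intervals are 1-based inclusive
(VCF-style). BED input/output is converted at the I/O boundary, never here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "eaf"]

#: columns of a GWAS summary-statistics table (beta is the log odds ratio)
SUMMARY_STAT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "eaf", "beta", "se", "p"]

#: per-sample mutation-burden count columns
COUNT_COLUMNS = ["nonsilent_snv", "nonsilent_indel", "nonsyn_point"]

COVARIATE_PCS = [f"PC{i}" for i in range(1, 11)]


@dataclass
class GenotypeMatrix:
    """Samples x variants imputed dosage matrix, values in [0, 2].

    ``variants`` carries one row per variant with columns
    ``id, chrom, pos, ref, alt, eaf`` in the column order of ``dosages``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"dosage rows ({n}) != samples ({len(self.samples)})")
        if m != len(self.variants):
            raise ValueError(f"dosage cols ({m}) != variants ({len(self.variants)})")
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")
        if np.isnan(self.dosages).any():
            raise ValueError("dosage matrix contains missing values after load")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype data")
        return int(idx[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage vector (length n_samples) for one variant."""
        return self.dosages[:, self.index_of(variant_id)]

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        cols = [self.index_of(v) for v in variant_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[:, cols].copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :].copy(),
        )

    def empirical_eaf(self) -> np.ndarray:
        """Observed effect-allele frequency per variant (mean dosage / 2)."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class SomaticGeneMatrix:
    """Gene-level somatic mutation status plus per-sample burden counts.

    ``indicators``: samples x genes 0/1 frame; entry 1 means the tumor carries
    at least one non-silent SNV or indel in that gene.
    ``counts``: per-sample totals (``nonsilent_snv``, ``nonsilent_indel``,
    ``nonsyn_point``); ``nonsyn_point`` drives hypermutation classification.
    """

    indicators: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.indicators.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("somatic indicators must be 0/1")
        missing = set(COUNT_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if not self.indicators.index.equals(self.counts.index):
            raise ValueError("indicator and count tables index different samples")
        if (self.counts[COUNT_COLUMNS].to_numpy() < 0).any():
            raise ValueError("negative mutation counts")
        # a sample mutated in >=1 gene must carry >=1 non-silent mutation
        total = self.nonsilent_total().to_numpy()
        any_gene = vals.sum(axis=1) if vals.size else np.zeros(len(self.counts))
        if ((any_gene >= 1) & (total < 1)).any():
            raise ValueError("indicator set but total non-silent count is 0")

    @property
    def samples(self) -> list[str]:
        return list(self.indicators.index)

    @property
    def genes(self) -> list[str]:
        return list(self.indicators.columns)

    def nonsilent_total(self) -> pd.Series:
        return self.counts["nonsilent_snv"] + self.counts["nonsilent_indel"]


@dataclass
class AnnotationBundle:
    """Annotation tracks driving variant-set construction.

    All interval frames use 1-based inclusive ``start``/``end``.

    genes:          gene_id, chrom, strand, tss, start, end
    exons:          gene_id, chrom, start, end
    vels:           chrom, start, end           (variant enhancer loci)
    enhancer_links: chrom, start, end, gene_id, tissue, expression_linked
    cna_regions:    chrom, start, end, label, direction in {gain, loss}
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    vels: pd.DataFrame
    enhancer_links: pd.DataFrame
    cna_regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("exons", "vels", "enhancer_links", "cna_regions"):
            df = getattr(self, name)
            if len(df) and (df["start"] > df["end"]).any():
                raise ValueError(f"{name}: interval with start > end")
        if len(self.cna_regions):
            bad = set(self.cna_regions["direction"]) - {"gain", "loss"}
            if bad:
                raise ValueError(f"cna_regions: unknown direction labels {bad}")

    def gene_chrom(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["chrom"].astype(str)))


@dataclass
class MeffResult:
    """Effective number of independent tests, accumulated per chromosome."""

    per_chrom: pd.DataFrame  # chrom, n_variants, meff
    eigenvalues: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.per_chrom["meff"].sum())

    @property
    def n_variants(self) -> int:
        return int(self.per_chrom["n_variants"].sum())


@dataclass(frozen=True)
class ThresholdSpec:
    """Bonferroni-style threshold alpha / (n_outcomes * meff)."""

    alpha: float
    n_outcomes: int
    meff: float

    @property
    def threshold(self) -> float:
        return self.alpha / (self.n_outcomes * self.meff)


@dataclass
class HypermutationCall:
    """Per-sample hypermutation status with the count threshold used."""

    threshold: int
    method: str  # "fixed" or "valley"
    status: pd.Series  # index = samples, values 0/1

    def stratum(self, which: str) -> list[str]:
        """Sample ids in stratum 'non_hyper', 'hyper' or 'combined'."""
        if which == "combined":
            return list(self.status.index)
        if which == "non_hyper":
            return list(self.status.index[self.status == 0])
        if which == "hyper":
            return list(self.status.index[self.status == 1])
        raise ValueError(f"unknown stratum {which!r}")


@dataclass
class VariantSet:
    """(variant, gene) test pairs with the admitting rule(s) as provenance.

    ``pairs`` columns: variant_id, gene, rules (comma-joined rule tags).
    """

    name: str
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.pairs):
            if self.pairs.duplicated(["variant_id", "gene"]).any():
                raise ValueError("duplicate (variant, gene) pairs")
            if (self.pairs["rules"].astype(str).str.len() == 0).any():
                raise ValueError("pair without provenance rule")
        self.pairs = self.pairs.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def variant_ids(self) -> list[str]:
        return sorted(self.pairs["variant_id"].unique())
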