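"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive everywhere (VCF-style).
  BED files (0-based, half-open) are converted at this boundary.
* Every writer emits a single header line starting with ``#`` naming the
  columns; readers parse it back, so write->read is a round trip.
* Genotypes travel either as a dense TSV matrix (variants x samples, the
  primary format) or as a VCF with a per-sample DS dosage field.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SUMMARY_STAT_COLUMNS,
    COUNT_COLUMNS,
    COVARIATE_PCS,
    AnnotationBundle,
    GenotypeMatrix,
    SomaticGeneMatrix,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# generic '#'-headed TSV helpers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: expected '#'-prefixed header line")
        cols = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=cols)
    return df


# ---------------------------------------------------------------------------
# coordinate conversion (the only place BED conventions appear)
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open [start0, end0) -> 1-based inclusive [s, e]."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive [s, e] -> BED 0-based half-open [start0, end0)."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_dosages(gm: GenotypeMatrix, path: str | Path) -> None:
    """Dense TSV: one row per variant, dosage columns named by sample."""
    df = gm.variants.copy()
    dos = pd.DataFrame(gm.dosages.T, columns=gm.samples)
    df = pd.concat([df.reset_index(drop=True), dos.reset_index(drop=True)], axis=1)
    _write_tsv(df, path)


def read_dosages(path: str | Path, maf_min: float = 0.01) -> GenotypeMatrix:
    """Load dosages, mean-impute missing values and apply the MAF filter.

    Variants with min(eaf, 1-eaf) <= ``maf_min`` are excluded (the analysis
    keeps variants with imputed allele frequency strictly greater than the
    cutoff on the minor side). Exclusion and imputation counts are logged.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        gm = _read_dosage_vcf(path)
    else:
        gm = _read_dosage_tsv(path)
    maf = np.minimum(gm.variants["eaf"].to_numpy(), 1 - gm.variants["eaf"].to_numpy())
    keep = maf > maf_min
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("read_dosages: excluded %d/%d variants at MAF <= %g",
                    n_drop, len(keep), maf_min)
    if not keep.any():
        logger.warning("read_dosages: all variants removed by the MAF filter")
    return GenotypeMatrix(
        samples=gm.samples,
        variants=gm.variants.loc[keep].reset_index(drop=True),
        dosages=gm.dosages[:, keep],
    )


def _finalize_dosage_matrix(samples, variants, dosages) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    bad = (dosages < 0) | (dosages > 2)
    if np.nansum(bad):
        i, j = np.argwhere(bad & ~np.isnan(dosages))[0]
        raise ParseError(
            f"dosage {dosages[i, j]} out of [0,2] (sample {samples[i]}, "
            f"variant {variants['id'].iloc[j]})"
        )
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        col_mean = np.nanmean(dosages, axis=0)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = np.take(col_mean, idx[1])
        logger.info("read_dosages: mean-imputed %d missing dosages", n_missing)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = _read_tsv(path)
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "eaf"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in meta_cols]
    # canonical variant order => loading is independent of input row order
    df = df.sort_values(["chrom", "pos", "id"], key=lambda s: s.astype(str)
                        if s.name == "chrom" else s).reset_index(drop=True)
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    dosages = df[samples].to_numpy(dtype=float).T
    return _finalize_dosage_matrix(samples, variants, dosages)


def _read_dosage_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} lacks DS field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        eaf = float(np.nanmean(ds) / 2.0)
        rows.append({
            "id": rec.ID or f"{rec.CHROM}:{rec.POS}_{rec.REF}/{rec.ALT[0]}",
            "chrom": str(rec.CHROM), "pos": int(rec.POS),
            "ref": rec.REF, "alt": rec.ALT[0], "eaf": eaf,
        })
        dosage_cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return _finalize_dosage_matrix(samples, variants, dosages)


def write_dosage_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal sites+DS VCF writer (one DS dosage value per sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, v in gm.variants.iterrows():
            ds = "\t".join(f"{d:.4g}" for d in gm.dosages[:, j])
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                     f"\t.\tPASS\t.\tDS\t{ds}\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    """BED3+ -> frame with 1-based inclusive start/end, sorted on load."""
    extra_cols = extra_cols or []
    names = ["chrom", "start", "end"] + extra_cols
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3 + len(extra_cols):
                raise ParseError(f"{path}:{lineno}: expected >= {3 + len(extra_cols)} fields")
            try:
                s0, e0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if s0 >= e0:
                raise ParseError(f"{path}:{lineno}: start >= end ({s0} >= {e0})")
            s, e = bed_to_internal(s0, e0)
            rows.append([str(parts[0]), s, e] + parts[3:3 + len(extra_cols)])
    df = pd.DataFrame(rows, columns=names)
    if len(df):
        df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_cols: list[str] | None = None) -> None:
    """Write 1-based inclusive intervals back out as BED (0-based half-open)."""
    extra_cols = extra_cols or [c for c in df.columns if c not in ("chrom", "start", "end")]
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            s0, e0 = internal_to_bed(int(r["start"]), int(r["end"]))
            extras = "".join(f"\t{r[c]}" for c in extra_cols)
            fh.write(f"{r['chrom']}\t{s0}\t{e0}{extras}\n")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(cov.reset_index().rename(columns={"index": "sample"}), path)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = ["sample", "age", "sex", "study"] + COVARIATE_PCS
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing covariate columns {sorted(missing)}")
    df = df.set_index("sample").sort_index()
    if df.isna().any().any():
        raise ParseError(f"{path}: missing covariate values")
    return df


# ---------------------------------------------------------------------------
# somatic mutation table
# ---------------------------------------------------------------------------

def write_somatic(som: SomaticGeneMatrix, path: str | Path) -> None:
    """Long-format TSV: one row per (sample, gene), counts repeated per sample."""
    long = (
        som.indicators.stack().rename("indicator").reset_index()
        .rename(columns={"level_0": "sample", "level_1": "gene"})
    )
    long.columns = ["sample", "gene", "indicator"]
    long = long.merge(som.counts.reset_index().rename(columns={"index": "sample"}),
                      on="sample")
    _write_tsv(long, path)


def read_somatic(path: str | Path) -> SomaticGeneMatrix:
    df = _read_tsv(path)
    required = ["sample", "gene", "indicator"] + COUNT_COLUMNS
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing somatic columns {sorted(missing)}")
    indicators = (
        df.pivot(index="sample", columns="gene", values="indicator").astype(int)
    )
    indicators.columns.name = None
    counts = df.drop_duplicates("sample").set_index("sample")[COUNT_COLUMNS].astype(int)
    counts = counts.loc[indicators.index]
    return SomaticGeneMatrix(indicators=indicators, counts=counts)


# ---------------------------------------------------------------------------
# GWAS summary statistics / association results
# ---------------------------------------------------------------------------

def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMMARY_STAT_COLUMNS) - set(stats.columns)
    if missing:
        raise ParseError(f"summary stats missing columns: {sorted(missing)}")
    dups = stats.loc[stats["id"].duplicated(), "id"].tolist()
    if dups:
        raise ParseError(f"duplicate variant ids in summary stats: {dups[:10]}")
    if len(stats) and (((stats["p"] <= 0) | (stats["p"] > 1)).any()):
        raise ParseError("summary stats: p-values must lie in (0, 1]")
    if len(stats) and (stats["se"] <= 0).any():
        raise ParseError("summary stats: standard errors must be positive")
    stats = stats.copy()
    stats["chrom"] = stats["chrom"].astype(str)
    return stats


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(validate_summary_stats(stats)[SUMMARY_STAT_COLUMNS], path)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = validate_summary_stats(_read_tsv(path))
    return df.sort_values(["chrom", "pos", "id"]).reset_index(drop=True)


def write_assoc(results: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(results, path)


def read_assoc(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# weights, pathways, known loci
# ---------------------------------------------------------------------------

def read_weights(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"variant_id", "effect_allele", "weight"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing weight columns {sorted(missing)}")
    if not np.isfinite(df["weight"].to_numpy(dtype=float)).all():
        raise ParseError(f"{path}: non-finite weights")
    return df


def write_weights(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[["variant_id", "effect_allele", "weight"]], path)


def read_pathways(path: str | Path) -> dict[str, list[str]]:
    df = _read_tsv(path)
    missing = {"gene", "pathway"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing pathway columns {sorted(missing)}")
    return {p: sorted(g["gene"]) for p, g in df.groupby("pathway")}


def write_pathways(pathways: dict[str, list[str]], path: str | Path) -> None:
    rows = [(g, p) for p, genes in pathways.items() for g in genes]
    _write_tsv(pd.DataFrame(rows, columns=["gene", "pathway"]), path)


def read_known_loci(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"chrom", "pos", "id"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing known-locus columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_known_loci(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "pos", "id", "citation") if c in df.columns]
    _write_tsv(df[cols], path)


# ---------------------------------------------------------------------------
# annotation bundle (directory of tracks)
# ---------------------------------------------------------------------------

def write_annotations(annot: AnnotationBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(annot.genes, outdir / "genes.tsv")
    write_bed(annot.exons, outdir / "exons.bed", ["gene_id"])
    write_bed(annot.vels, outdir / "vels.bed", [])
    _write_tsv(annot.enhancer_links, outdir / "enhancer_links.tsv")
    write_bed(annot.cna_regions, outdir / "cna_regions.bed", ["label", "direction"])


def read_annotations(indir: str | Path) -> AnnotationBundle:
    indir = Path(indir)
    genes = _read_tsv(indir / "genes.tsv")
    genes["chrom"] = genes["chrom"].astype(str)
    links = _read_tsv(indir / "enhancer_links.tsv")
    links["chrom"] = links["chrom"].astype(str)
    if links["expression_linked"].dtype == object:
        links["expression_linked"] = links["expression_linked"].astype(str) == "True"
    else:
        links["expression_linked"] = links["expression_linked"].astype(bool)
    exons = read_bed(indir / "exons.bed", ["gene_id"])
    vels = read_bed(indir / "vels.bed")
    cna = read_bed(indir / "cna_regions.bed", ["label", "direction"])
    return AnnotationBundle(genes=genes, exons=exons, vels=vels,
                            enhancer_links=links, cna_regions=cna)
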