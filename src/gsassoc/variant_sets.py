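"""Construction of the three germline variant sets tested against somatic genes.

1. ``gwas_suggestive`` - variants suggestively associated with overall CRC
   risk (p < 1e-5 in the large GWAS), paired with every analyzed gene.
2. ``functional`` - variants in putative functional regions of a gene:
   exonic, promoter-proximal (strand-aware), near the gene inside a variant
   enhancer locus (VEL) or a tissue-matched enhancer, or distal inside an
   expression-linked enhancer that is also a VEL.
3. ``cna_region`` - variants inside recurrent somatic copy-number-amplification
   regions, paired with every somatically mutated gene on the same chromosome.

All distance thresholds are inclusive; gene-body distance is measured from
the nearest edge of the union span of the gene's exons.
"""
from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

from .containers import AnnotationBundle, VariantSet

logger = logging.getLogger(__name__)

#: genes on sex chromosomes dropped from the functional analysis by default
#: (no GWAS or functional annotation available there)
DEFAULT_FUNCTIONAL_EXCLUSIONS = ("AMER1", "BCOR", "MXRA5", "USP9X")

DIGESTIVE_IMMUNO_TISSUES = ("digestive", "immunology")


def _interval_trees(df: pd.DataFrame, data_cols: list[str] | None = None
                    ) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over 1-based inclusive start/end."""
    trees: dict[str, IntervalTree] = {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        data = tuple(row[c] for c in data_cols) if data_cols else True
        trees.setdefault(chrom, IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, data)
    return trees


def _hits(trees: dict[str, IntervalTree], chrom: str, pos: int) -> list:
    tree = trees.get(str(chrom))
    return [iv.data for iv in tree[int(pos)]] if tree is not None else []


def _pairs_frame(records: list[tuple[str, str, str]], name: str) -> VariantSet:
    if records:
        df = (pd.DataFrame(records, columns=["variant_id", "gene", "rules"])
              .groupby(["variant_id", "gene"], sort=False)["rules"]
              .apply(lambda r: ",".join(sorted(set(r)))).reset_index())
    else:
        df = pd.DataFrame(columns=["variant_id", "gene", "rules"])
    return VariantSet(name=name, pairs=df)


def build_gwas_set(stats: pd.DataFrame, genes: list[str],
                   p_cut: float = 1e-5) -> VariantSet:
    """Variants with GWAS p strictly below ``p_cut``, paired with every gene."""
    if len(stats) == 0:
        raise ValueError("empty summary statistics")
    if not (0 < p_cut < 1):
        raise ValueError(f"p_cut must be in (0,1), got {p_cut}")
    hits = stats.loc[stats["p"] < p_cut, "id"]
    tag = f"gwas_p<{p_cut:g}"
    records = [(v, g, tag) for v in hits for g in genes]
    return _pairs_frame(records, "gwas_suggestive")


def build_functional_set(
    variants: pd.DataFrame,
    annotations: AnnotationBundle,
    genes: list[str],
    max_dist: int = 200_000,
    promoter_bp: int = 1_000,
    exclude_genes: tuple[str, ...] = DEFAULT_FUNCTIONAL_EXCLUSIONS,
) -> VariantSet:
    """(variant, gene) pairs admitted by any functional-region rule.

    Rules (all thresholds inclusive):
      ``exon``                 variant inside an exon of the gene;
      ``promoter``             within ``promoter_bp`` upstream of the TSS,
                               strand-aware;
      ``vel_near``             within ``max_dist`` of the gene body and
                               inside a VEL;
      ``enhancer_near``        within ``max_dist`` and inside a distal
                               promoter/enhancer linked to the gene in
                               digestive or immunology tissue;
      ``distal_expr_vel``      beyond ``max_dist``, inside an enhancer linked
                               to the gene by expression AND inside a VEL.

    Genes without a gene model are dropped with a logged warning.
    """
    vel_trees = _interval_trees(annotations.vels)
    link_trees = _interval_trees(
        annotations.enhancer_links,
        data_cols=["gene_id", "tissue", "expression_linked"])
    gene_models = annotations.genes.set_index("gene_id")
    exons_by_gene = dict(tuple(annotations.exons.groupby("gene_id")))

    records: list[tuple[str, str, str]] = []
    for gene in genes:
        if gene in exclude_genes:
            logger.warning("functional set: gene %s excluded (exclusion list)", gene)
            continue
        if gene not in gene_models.index:
            logger.warning("functional set: gene %s dropped (no gene model)", gene)
            continue
        model = gene_models.loc[gene]
        chrom, strand, tss = str(model["chrom"]), model["strand"], int(model["tss"])
        exons = exons_by_gene.get(gene)
        if exons is not None and len(exons):
            body_lo = int(exons["start"].min())
            body_hi = int(exons["end"].max())
        else:
            body_lo, body_hi = int(model["start"]), int(model["end"])

        sub = variants[variants["chrom"].astype(str) == chrom]
        for _, v in sub.iterrows():
            pos, vid = int(v["pos"]), v["id"]
            if pos < body_lo:
                dist = body_lo - pos
            elif pos > body_hi:
                dist = pos - body_hi
            else:
                dist = 0
            in_vel = bool(_hits(vel_trees, chrom, pos))
            links = _hits(link_trees, chrom, pos)
            own_links = [l for l in links if l[0] == gene]

            if exons is not None and len(exons) and (
                    (exons["start"] <= pos) & (pos <= exons["end"])).any():
                records.append((vid, gene, "exon"))
            offset = tss - pos if strand == "+" else pos - tss
            if 1 <= offset <= promoter_bp:
                records.append((vid, gene, "promoter"))
            if dist <= max_dist and in_vel:
                records.append((vid, gene, "vel_near"))
            if dist <= max_dist and any(
                    l[1] in DIGESTIVE_IMMUNO_TISSUES for l in own_links):
                records.append((vid, gene, "enhancer_near"))
            if dist > max_dist and in_vel and any(bool(l[2]) for l in own_links):
                records.append((vid, gene, "distal_expr_vel"))
    return _pairs_frame(records, "functional")


def build_cna_set(variants: pd.DataFrame, cna_regions: pd.DataFrame,
                  gene_chroms: dict[str, str]) -> VariantSet:
    """Pair every variant inside a CNA region with every analyzed gene whose
    gene body lies on the same chromosome as that region."""
    if len(cna_regions) == 0:
        raise ValueError("no CNA regions supplied")
    trees = _interval_trees(cna_regions, data_cols=["label"])
    records: list[tuple[str, str, str]] = []
    for _, v in variants.iterrows():
        chrom, pos, vid = str(v["chrom"]), int(v["pos"]), v["id"]
        labels = [l[0] for l in _hits(trees, chrom, pos)]
        if not labels:
            continue
        for gene, gchrom in gene_chroms.items():
            if str(gchrom) == chrom:
                for label in labels:
                    records.append((vid, gene, f"cna:{label}"))
    return _pairs_frame(records, "cna_region")
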