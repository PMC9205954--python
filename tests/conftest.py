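import numpy as np
import pandas as pd
import pytest

from gsassoc.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared by read-only tests."""
    # 24 blocks: chromosomes 1 and 2 carry two LD blocks, so distal
    # (>200 kb) same-chromosome annotation fixtures exist
    cfg = SimulationConfig(seed=11, n_samples=300, n_blocks=24,
                           variants_per_block=5, n_genes=16,
                           gwas_n_variants=1500)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_annotation_bundle(genes, exons, vels, links, regions):
    """Hand-built AnnotationBundle from plain row lists."""
    from gsassoc.containers import AnnotationBundle
    return AnnotationBundle(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "strand",
                                           "tss", "start", "end"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
        vels=pd.DataFrame(vels, columns=["chrom", "start", "end"]),
        enhancer_links=pd.DataFrame(
            links, columns=["chrom", "start", "end", "gene_id", "tissue",
                            "expression_linked"]),
        cna_regions=pd.DataFrame(
            regions, columns=["chrom", "start", "end", "label", "direction"]),
    )
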