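"""Effective number of independent tests (M_eff) from LD, per chromosome.

Correlated variants make a per-variant Bonferroni correction far too strict.
The eigenvalue-based estimator of Li & Ji maps the LD correlation matrix to
an effective test count

    M_eff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]

over eigenvalues lambda_i of the correlation matrix (negative numerical
eigenvalues clipped to 0). Independence gives M_eff = p, perfect LD gives 1.
M_eff is computed chromosome by chromosome and summed; between-chromosome LD
is taken to be zero.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MeffResult, ThresholdSpec


def ld_correlation(genotypes: GenotypeMatrix, chrom: str | None = None) -> np.ndarray:
    """Pearson dosage correlation matrix for the variants of one chromosome.

    Raises on zero-variance variants: those must be removed by the MAF
    filter before LD estimation.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need >= 2 samples to estimate LD")
    mask = np.ones(genotypes.n_variants, dtype=bool)
    if chrom is not None:
        mask = genotypes.variants["chrom"].astype(str).to_numpy() == str(chrom)
    dos = genotypes.dosages[:, mask]
    sd = dos.std(axis=0)
    if (sd == 0).any():
        bad = genotypes.variants.loc[mask, "id"].to_numpy()[sd == 0]
        raise ValueError(f"zero-variance variants (filter by MAF first): {list(bad[:5])}")
    corr = np.corrcoef(dos, rowvar=False)
    corr = np.atleast_2d(corr)
    # enforce exact symmetry and unit diagonal against roundoff
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def meff_li(corr: np.ndarray, return_eigenvalues: bool = False):
    """Li-Ji effective test count of one correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    # round away eigendecomposition noise: floor() must not drop a whole
    # unit when an eigenvalue sits epsilon below an integer
    lam = np.round(lam, 10)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    if return_eigenvalues:
        return meff, lam
    return meff


def meff_total(genotypes: GenotypeMatrix,
               variant_ids: list[str] | None = None) -> MeffResult:
    """Partition variants by chromosome, sum per-chromosome Li-Ji M_eff."""
    gm = genotypes if variant_ids is None else genotypes.subset_variants(
        sorted(set(variant_ids), key=list(variant_ids).index))
    rows, eigs = [], {}
    chroms = gm.variants["chrom"].astype(str)
    for chrom in sorted(chroms.unique()):
        corr = ld_correlation(gm, chrom)
        meff, lam = meff_li(corr, return_eigenvalues=True)
        rows.append({"chrom": chrom, "n_variants": corr.shape[0], "meff": meff})
        eigs[chrom] = lam
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_variants", "meff"])
    return MeffResult(per_chrom=per_chrom, eigenvalues=eigs)


def significance_threshold(alpha: float, n_outcomes: int, meff: float) -> ThresholdSpec:
    """alpha / (n_outcomes * M_eff); n_outcomes is the number of somatic genes
    tested (1 for the CNA-region GWAS re-analysis)."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_outcomes < 1:
        raise ValueError(f"n_outcomes must be >= 1, got {n_outcomes}")
    if meff < 1:
        raise ValueError(f"meff must be >= 1, got {meff}")
    return ThresholdSpec(alpha=alpha, n_outcomes=int(n_outcomes), meff=float(meff))
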