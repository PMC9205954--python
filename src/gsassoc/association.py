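"""Covariate-adjusted logistic association of germline dosages with
gene-level somatic mutation status.

For each (variant, gene) pair the model is

    logit P(Y_gene = 1) = b0 + b1 * dosage + covariates

with covariates age, sex, study indicator contrasts and the top ten PCs;
the combined-stratum analysis additionally adjusts for hypermutation
status. Effects are reported per dosage unit (additive coding, fractional
dosages allowed) with Wald two-sided p-values and 95% CIs.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix, SomaticGeneMatrix, ThresholdSpec, VariantSet
from .somatic import outcome_vector

_Z975 = 1.959963984540054

#: absolute log-OR beyond which a fit is treated as quasi-separated
_BETA_DIVERGED = 15.0


@dataclass
class AssocResult:
    gene: str
    variant: str
    stratum: str
    n: int
    beta: float
    se: float
    OR: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


def make_design(covariates: pd.DataFrame | None,
                samples: list[str] | None = None,
                adjust_hyper: bool = False,
                hyper_status: pd.Series | None = None) -> np.ndarray | None:
    """Covariate design block: age, sex, study contrasts, PCs, optional
    hypermutation indicator. Returns None when no covariates are used."""
    if covariates is None and not adjust_hyper:
        return None
    blocks = []
    if covariates is not None:
        cov = covariates.loc[samples] if samples is not None else covariates
        numeric = [c for c in cov.columns
                   if c not in ("study", "hypermutated") and
                   np.issubdtype(cov[c].dtype, np.number)]
        blocks.append(cov[numeric].to_numpy(dtype=float))
        if "study" in cov.columns:
            dummies = pd.get_dummies(cov["study"], drop_first=True, dtype=float)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy())
    if adjust_hyper:
        if hyper_status is None:
            raise ValueError("adjust_hyper requires hyper_status")
        hs = hyper_status.loc[samples] if samples is not None else hyper_status
        blocks.append(hs.to_numpy(dtype=float)[:, None])
    return np.column_stack(blocks) if blocks else None


def fit_logistic(y: np.ndarray, dosage: np.ndarray,
                 covariates: np.ndarray | None = None,
                 gene: str = "", variant: str = "",
                 stratum: str = "combined") -> AssocResult:
    """Maximum-likelihood logistic fit of one (variant, gene) pair.

    ``covariates`` is a pre-built numeric design block (see ``make_design``).
    Quasi-separated or non-convergent fits are returned flagged
    ``converged=False`` rather than raised.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if y.shape != dosage.shape:
        raise ValueError("outcome and dosage lengths differ")
    n_carrier = int(y.sum())
    if n_carrier == 0 or n_carrier == len(y):
        raise ValueError(
            f"outcome needs >=1 carrier and >=1 non-carrier (got {n_carrier}/{len(y)})")
    cols = [np.ones_like(dosage), dosage]
    if covariates is not None:
        cols.append(covariates)
    X = np.column_stack(cols)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    converged = True
    try:
        res = model.fit(maxiter=200, tol=1e-9)
        beta = float(res.params[1])
        se = float(res.bse[1])
        converged = bool(res.converged) and abs(beta) < _BETA_DIVERGED \
            and np.isfinite(se) and se > 0
    except Exception:
        beta, se, converged = np.nan, np.nan, False
    if converged:
        z = beta / se
        p = float(max(2 * stats.norm.sf(abs(z)), 1e-300))
    else:
        p = np.nan
    with np.errstate(over="ignore"):  # diverged fits may overflow exp()
        return AssocResult(
            gene=gene, variant=variant, stratum=stratum, n=len(y),
            beta=beta, se=se, OR=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z975 * se)),
            ci_high=float(np.exp(beta + _Z975 * se)),
            p=p, converged=converged)


def run_scan(
    genotypes: GenotypeMatrix,
    somatic: SomaticGeneMatrix,
    covariates: pd.DataFrame | None,
    variant_set: VariantSet,
    stratum: str,
    threshold: ThresholdSpec,
    hyper_status: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (variant, gene) pair of a variant set within a stratum.

    ``stratum``: "non_hyper" restricts to non-hypermutated samples;
    "combined" uses everyone and adjusts for hypermutation status.
    Returns (full table sorted by p, significant subset at the threshold).
    The top row of the full table is the scan's most associated pair
    whether or not it is significant.
    """
    if variant_set.n_pairs == 0:
        raise ValueError("variant set has no (variant, gene) pairs")
    if stratum == "combined":
        samples = genotypes.samples
        adjust_hyper = hyper_status is not None
    elif stratum == "non_hyper":
        if hyper_status is None:
            raise ValueError("non_hyper stratum requires hyper_status")
        samples = [s for s in genotypes.samples if hyper_status.loc[s] == 0]
        adjust_hyper = False
    else:
        raise ValueError(f"unknown stratum {stratum!r}")

    design = make_design(covariates, samples, adjust_hyper, hyper_status)
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    rows_idx = np.array([sample_pos[s] for s in samples])

    rows = []
    for gene, group in variant_set.pairs.groupby("gene", sort=False):
        y = outcome_vector(somatic, gene, samples)
        for vid in group["variant_id"]:
            dosage = genotypes.dosage(vid)[rows_idx]
            try:
                res = fit_logistic(y, dosage, design, gene=gene,
                                   variant=vid, stratum=stratum)
            except ValueError:
                res = AssocResult(gene=gene, variant=vid, stratum=stratum,
                                  n=len(y), beta=np.nan, se=np.nan, OR=np.nan,
                                  ci_low=np.nan, ci_high=np.nan, p=np.nan,
                                  converged=False)
            rows.append(res.to_dict())
    table = pd.DataFrame(rows).sort_values(
        "p", na_position="last").reset_index(drop=True)
    significant = table[(table["converged"]) &
                        (table["p"] < threshold.threshold)].reset_index(drop=True)
    return table, significant


def top_hit(table: pd.DataFrame) -> pd.Series:
    """Most associated converged pair of a scan table."""
    ok = table[table["converged"]]
    if len(ok) == 0:
        raise ValueError("no converged fits in scan table")
    return ok.iloc[0]
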