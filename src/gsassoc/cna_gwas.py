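"""CNA-region-restricted re-analysis of GWAS summary statistics.

Restricts overall-CRC-risk summary statistics to recurrent somatic
copy-number-amplification (CNA) regions, applies the M_eff-based
significance threshold, clumps significant variants into 1-Mb lead-SNP
loci, flags known vs novel loci, and tests whether significant loci fall
preferentially in copy-number gain versus loss regions (two-sided Fisher
exact test computed by hypergeometric enumeration).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import ThresholdSpec


def _region_trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, row in regions.iterrows():
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, idx)
    return trees


def restrict_to_regions(stats_df: pd.DataFrame,
                        regions: pd.DataFrame) -> pd.DataFrame:
    """Variants whose position lies inside any CNA region (inclusive
    bounds), annotated with the containing region's label and direction."""
    if len(regions) == 0:
        raise ValueError("no CNA regions supplied")
    trees = _region_trees(regions)
    keep, labels, directions = [], [], []
    for _, v in stats_df.iterrows():
        tree = trees.get(str(v["chrom"]))
        hits = sorted(iv.data for iv in tree[int(v["pos"])]) if tree else []
        if hits:
            keep.append(True)
            labels.append(regions.loc[hits[0], "label"])
            directions.append(regions.loc[hits[0], "direction"])
        else:
            keep.append(False)
    out = stats_df[np.array(keep, dtype=bool)].copy().reset_index(drop=True)
    out["region_label"] = labels
    out["region_direction"] = directions
    return out


def significant_variants(stats_df: pd.DataFrame,
                         threshold: ThresholdSpec | float) -> pd.DataFrame:
    """Rows with p strictly below the threshold."""
    cut = threshold.threshold if isinstance(threshold, ThresholdSpec) else float(threshold)
    return stats_df[stats_df["p"] < cut].reset_index(drop=True)


def lead_snps(significant: pd.DataFrame,
              window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy 1-Mb clumping: repeatedly take the smallest-p remaining
    variant as a lead and drop every remaining variant on the same
    chromosome within +/- window_bp/2 of it. Ties break by (chrom, pos), so
    the result is independent of input row order."""
    if len(significant) == 0:
        return significant.assign(window_start=pd.Series(dtype=int),
                                  window_end=pd.Series(dtype=int))
    df = significant.sort_values(
        ["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    half = window_bp // 2
    taken = np.zeros(len(df), dtype=bool)
    removed = np.zeros(len(df), dtype=bool)
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(len(df)):
        if removed[i]:
            continue
        taken[i] = True
        near = (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= half)
        removed |= near
    leads = df[taken].copy()
    leads["OR"] = np.exp(leads["beta"])
    leads["window_start"] = (leads["pos"] - half).clip(lower=1)
    leads["window_end"] = leads["pos"] + half
    return leads.sort_values(["chrom", "pos"]).reset_index(drop=True)


def flag_known(leads: pd.DataFrame, known_loci: pd.DataFrame,
               radius: int = 1_000_000) -> pd.DataFrame:
    """Mark each lead as known when any supplied known locus lies within
    ``radius`` bp on the same chromosome; otherwise novel."""
    leads = leads.copy()
    flags = []
    for _, lead in leads.iterrows():
        same = known_loci[known_loci["chrom"].astype(str) == str(lead["chrom"])]
        flags.append(bool(len(same) and
                          (np.abs(same["pos"] - lead["pos"]) <= radius).any()))
    leads["known"] = flags
    return leads


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities not
    exceeding the observed table's probability (with the conventional
    1 + 1e-7 tie tolerance).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    rv = stats.hypergeom(n, r1, c1)
    kmin, kmax = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(kmin, kmax + 1)
    pmfs = rv.pmf(ks)
    return float(min(1.0, pmfs[pmfs <= p_obs * (1 + 1e-7)].sum()))


def gain_loss_test(regions: pd.DataFrame, leads: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Do significant loci fall preferentially in gain vs loss regions?

    A region counts as hit when it contains >= 1 lead SNP. Returns the
    two-sided Fisher exact p and the underlying 2x2 table
    (rows gain/loss, columns hit/no-hit).
    """
    dirs = set(regions["direction"])
    if dirs == {"gain"} or dirs == {"loss"} or not dirs:
        raise ValueError("degenerate margins: need both gain and loss regions")
    trees = _region_trees(regions)
    hit = np.zeros(len(regions), dtype=bool)
    for _, lead in leads.iterrows():
        tree = trees.get(str(lead["chrom"]))
        if tree is None:
            continue
        for iv in tree[int(lead["pos"])]:
            hit[regions.index.get_loc(iv.data)] = True
    is_gain = (regions["direction"] == "gain").to_numpy()
    table = np.array([
        [int((is_gain & hit).sum()), int((is_gain & ~hit).sum())],
        [int((~is_gain & hit).sum()), int((~is_gain & ~hit).sum())],
    ])
    counts = pd.DataFrame(table, index=["gain", "loss"], columns=["hit", "no_hit"])
    return fisher_exact_two_sided(table), counts


def plot_manhattan(stats_df: pd.DataFrame, threshold: float,
                   path: str | Path) -> None:
    """Manhattan plot of in-region variants with the significance line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stats_df.copy()
    df["chrom_num"] = pd.to_numeric(df["chrom"], errors="coerce")
    df = df.sort_values(["chrom_num", "pos"])
    offset, ticks, xs = 0, {}, []
    for chrom, grp in df.groupby("chrom_num", sort=True):
        span = grp["pos"].max() - grp["pos"].min() + 1
        xs.append(grp["pos"] - grp["pos"].min() + offset)
        ticks[chrom] = offset + span / 2
        offset += span + span * 0.1
    df["x"] = pd.concat(xs)
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, (chrom, grp) in enumerate(df.groupby("chrom_num", sort=True)):
        ax.scatter(grp["x"], -np.log10(grp["p"]), s=6,
                   color=["#30638e", "#a0a0a0"][i % 2])
    ax.axhline(-np.log10(threshold), color="firebrick", linestyle="--", lw=1)
    ax.set_xticks(list(ticks.values()))
    ax.set_xticklabels([f"{int(c)}" for c in ticks], fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    ax.set_title("CRC risk within somatic CNA regions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
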