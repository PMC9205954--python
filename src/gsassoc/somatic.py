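"""Analysis outcomes derived from the somatic mutation table.

* Hypermutation status from the per-sample non-synonymous point-mutation
  count, either at a fixed threshold (default 23, the headline definition)
  or data-driven at the valley of a bimodal burden histogram.
* Gene inclusion by non-silent mutation frequency within a stratum.
* Per-gene binary outcome vectors for the association models.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import HypermutationCall, SomaticGeneMatrix

#: headline definition: >= 23 non-synonymous point mutations
DEFAULT_HYPER_THRESHOLD = 23


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _local_maxima(s: np.ndarray) -> list[int]:
    """Indices of strict-rise/flat-fall local maxima; edges may qualify."""
    padded = np.concatenate(([-np.inf], s, [-np.inf]))
    return [
        i for i in range(len(s))
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]
    ]


def valley_of_histogram(hist: np.ndarray, smooth_window: int = 5,
                        min_mode_separation: int = 5,
                        min_mode_fraction: float = 0.01) -> int:
    """Valley (count value) between the two dominant modes of a histogram.

    ``hist[k]`` is the mass at count k. The histogram is smoothed with a
    centered moving average, the two highest local maxima at least
    ``min_mode_separation`` counts apart are taken as the modes (a mode must
    reach ``min_mode_fraction`` of the top mode, so far-tail ripples do not
    qualify), and the valley is the argmin strictly between them (ties
    toward the smaller count). Raises ``ValueError`` if no two separated
    modes exist.
    """
    hist = np.asarray(hist, dtype=float)
    smoothed = _moving_average(hist, smooth_window)
    peaks = _local_maxima(smoothed)
    if peaks:
        top = max(smoothed[i] for i in peaks)
        peaks = [i for i in peaks if smoothed[i] >= min_mode_fraction * top]
    if len(peaks) >= 2:
        peaks = sorted(peaks, key=lambda i: smoothed[i], reverse=True)
        first = peaks[0]
        second = next((p for p in peaks[1:]
                       if abs(p - first) >= min_mode_separation), None)
    else:
        second = None
    if len(peaks) < 2 or second is None:
        raise ValueError("no interior valley detected (distribution not bimodal)")
    lo, hi = sorted((peaks[0], second))
    interior = smoothed[lo + 1:hi]
    return int(lo + 1 + np.argmin(interior))  # argmin ties resolve leftward


def call_hypermutation(counts: pd.Series, method: str = "fixed",
                       fixed_threshold: int = DEFAULT_HYPER_THRESHOLD,
                       smooth_window: int = 5,
                       min_mode_separation: int = 5) -> HypermutationCall:
    """Classify samples as hypermutated from non-synonymous point-mutation counts.

    method="fixed": status = count >= fixed_threshold.
    method="valley": threshold located at the interior minimum of the
    smoothed count histogram between its two dominant peaks.
    """
    vals = counts.to_numpy()
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValueError("mutation counts must be non-negative integers")
    vals = vals.astype(int)
    if method == "fixed":
        threshold = int(fixed_threshold)
    elif method == "valley":
        hist = np.bincount(vals)
        threshold = valley_of_histogram(hist, smooth_window, min_mode_separation)
    else:
        raise ValueError(f"unknown method {method!r}")
    status = pd.Series((vals >= threshold).astype(int), index=counts.index)
    return HypermutationCall(threshold=threshold, method=method, status=status)


def filter_genes(somatic: SomaticGeneMatrix, stratum_samples: list[str],
                 min_freq: float = 0.05) -> list[str]:
    """Genes whose non-silent carrier fraction within the stratum is
    at least ``min_freq`` (genes mutated in at least 5% of cases by default)."""
    if len(stratum_samples) == 0:
        raise ValueError("empty stratum")
    sub = somatic.indicators.loc[stratum_samples]
    frac = sub.mean(axis=0)
    return [g for g in somatic.genes if frac[g] >= min_freq and frac[g] > 0]


def outcome_vector(somatic: SomaticGeneMatrix, gene: str,
                   samples: list[str]) -> np.ndarray:
    """0/1 somatic mutation status of one gene, aligned to ``samples``."""
    if gene not in somatic.indicators.columns:
        raise KeyError(f"gene {gene!r} not in somatic table")
    return somatic.indicators.loc[samples, gene].to_numpy(dtype=int)


def burden_summary(somatic: SomaticGeneMatrix,
                   call: HypermutationCall) -> pd.DataFrame:
    """Descriptive mutation-burden statistics by hypermutation stratum."""
    rows = []
    strata = {
        "hyper": call.stratum("hyper"),
        "non_hyper": call.stratum("non_hyper"),
        "combined": call.stratum("combined"),
    }
    total = somatic.nonsilent_total()
    for name, samples in strata.items():
        if not samples:
            continue
        t = total.loc[samples]
        rows.append({
            "stratum": name, "n": len(samples),
            "mean_nonsilent": float(t.mean()), "sd_nonsilent": float(t.std()),
            "median_nonsilent": float(t.median()),
            "min_nonsilent": int(t.min()), "max_nonsilent": int(t.max()),
        })
    return pd.DataFrame(rows)
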