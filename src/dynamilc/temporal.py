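"""Temporal characterization of saliency maps.

For each saliency map, the temporal density counts how many components
at each time point fall in the map's top-p fraction (same signed
selection rule as RAR).  The earth mover's distance between the
normalized density and the uniform density over all T time points
quantifies temporal focality: 0 for perfectly uniform maps, up to
(T−1)/2 for a single point mass at an end of the series.  Group
contrasts use Wilcoxon rank tests (rank-sum for independent groups,
signed-rank for matched cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import SaliencyMap, select_top_fraction

__all__ = [
    "TemporalDensity",
    "temporal_density",
    "emd_to_uniform",
    "wilcoxon_rank",
    "emd_table",
]


@dataclass
class TemporalDensity:
    """Counts of top-salient components per time point, plus the normalized density."""

    counts: np.ndarray  # length T, nonnegative integers summing to round(p·C·T)
    normalized: np.ndarray  # probability vector over time points


def temporal_density(saliency, p: float = 0.05) -> TemporalDensity:
    """Number of components per time point in the saliency map's top-p cells."""
    mask = select_top_fraction(saliency, p).mask
    counts = mask.sum(axis=0).astype(int)
    total = counts.sum()
    normalized = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return TemporalDensity(counts=counts, normalized=normalized)


def emd_to_uniform(density: TemporalDensity) -> float:
    """1-D earth mover's distance to the uniform density on {0, …, T−1}.

    Computed as Σ_t |CDF_density(t) − CDF_uniform(t)| with unit spacing,
    in time-index units.
    """
    counts = np.asarray(density.counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("temporal density has zero total mass")
    T = counts.size
    if np.issubdtype(counts.dtype, np.integer):
        # integer inner terms keep EMD exactly 0 for exactly uniform densities
        inner = np.abs(np.cumsum(counts.astype(np.int64)) * T
                       - int(total) * np.arange(1, T + 1, dtype=np.int64))
        return float(inner.sum() / (total * T))
    cdf = np.cumsum(counts / total)
    uniform_cdf = np.arange(1, T + 1) / T
    return float(np.abs(cdf - uniform_cdf).sum())


def wilcoxon_rank(group_a, group_b, paired: bool = False):
    """Two-sided Wilcoxon rank test.

    Unpaired: rank-sum (Mann–Whitney U).  Paired: signed-rank over matched
    differences.  Completely tied inputs return p = 1 with a warning instead
    of erroring.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
            return 0.0, 1.0
        stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        return float(stat), float(p)
    if min(a.size, b.size) < 5:
        raise ValueError("unpaired test needs at least 5 observations per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all observations tied; returning p = 1", stacklevel=2)
        return float(a.size * b.size / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def emd_table(saliency_maps, groups, p: float = 0.05) -> pd.DataFrame:
    """Per-subject EMD table: subject_id, group, emd."""
    rows = []
    for sal, grp in zip(saliency_maps, groups):
        emd = emd_to_uniform(temporal_density(sal, p))
        sid = sal.subject_id if isinstance(sal, SaliencyMap) else ""
        rows.append({"subject_id": sid, "group": grp, "emd": emd})
    return pd.DataFrame(rows)
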