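"""Rank-test wrappers with explicit small-sample exact behavior.

Both tests switch to the exact null distribution for small samples without
ties (where the normal approximation is unreliable) and to the midrank /
normal-approximation path otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EXACT_MAX_N = 50


def _has_ties(*arrays) -> bool:
    pooled = np.concatenate(arrays)
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U of the first sample)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N
             and not _has_ties(x, y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired samples.

    All-zero differences return (0, 1.0) by convention rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    exact = len(nz) <= _EXACT_MAX_N and not _has_ties(np.abs(nz))
    res = stats.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox",
                         method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)
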