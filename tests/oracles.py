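"""Brute-force statistical oracles shared by the test files."""

import itertools

import numpy as np
import pandas as pd


def brute_force_signed_rank_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    total = 0
    extreme = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            extreme += 1
    return extreme / total


def brute_force_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    mean_u = nx * len(y) / 2
    count = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
        count += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            extreme += 1
    return extreme / count
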