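"""Classification of sex-chromosome windows into evolutionary strata.

The joint coverage / SNP-density logic:

* **old, degenerate stratum** — smoothed log2 male:female coverage below the
  autosomal null's lower bound (Y sequence loss leaves males X-hemizygous;
  at total loss the ratio approaches 0.5, i.e. log2 = -1). Reduced male SNP
  density co-occurring with the coverage loss corroborates the call.
* **young stratum** — coverage inside the null but smoothed male-minus-female
  SNP density above the null's upper bound (the diverged-but-intact Y still
  co-maps to the X, inflating male heterozygosity).
* otherwise **undifferentiated / pseudoautosomal**.

Coverage takes precedence over the SNP signal: a degenerate region perturbs
SNP density too, so the coverage deficit is the marker of old strata.
Per-window labels are merged into contiguous region calls, absorbing runs
shorter than ``min_run`` windows into their flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .winstats import AutosomalNull, moving_average

UNDIFF_PAR = "UNDIFF_PAR"
YOUNG = "YOUNG"
OLD_DEGENERATE = "OLD_DEGENERATE"

LABELS = (UNDIFF_PAR, YOUNG, OLD_DEGENERATE)


@dataclass(frozen=True)
class StratumCall:
    """A contiguous region sharing one stratum label.

    ``support`` is the fraction of member windows whose own (smoothed)
    statistics individually satisfy the region's criterion.
    """

    chrom: str
    start: int
    end: int
    label: str
    support: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown stratum label {self.label!r}")
        if not self.start < self.end:
            raise ValueError("empty stratum interval")


def classify_windows(stats: pd.DataFrame, cov_null: AutosomalNull,
                     snp_null: AutosomalNull, span: int = 11) -> pd.DataFrame:
    """Label each window of ``stats`` (one chromosome, position-ordered).

    Adds columns ``smooth_log2_mf_cov``, ``smooth_mf_snp_diff``, ``label``
    and ``corroborated`` (reduced male SNP density accompanying a coverage
    deficit). Raises if the nulls do not describe the expected statistics.
    """
    if cov_null.statistic != "log2_mf_cov" or snp_null.statistic != "mf_snp_diff":
        raise ValueError(
            "nulls must be built on log2_mf_cov and mf_snp_diff respectively "
            f"(got {cov_null.statistic!r}, {snp_null.statistic!r})")
    stats = stats.sort_values(["chrom", "start"]).reset_index(drop=True)
    cov_s = moving_average(stats.log2_mf_cov, span)
    snp_s = moving_average(stats.mf_snp_diff, span)
    old = np.isfinite(cov_s) & (cov_s < cov_null.boot_lower)
    young = ~old & np.isfinite(snp_s) & (snp_s > snp_null.boot_upper)
    label = np.where(old, OLD_DEGENERATE, np.where(young, YOUNG, UNDIFF_PAR))
    corroborated = old & np.isfinite(snp_s) & (snp_s < snp_null.boot_lower)
    return stats.assign(smooth_log2_mf_cov=cov_s, smooth_mf_snp_diff=snp_s,
                        label=label, corroborated=corroborated)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def _refine_boundary(values: np.ndarray, s: int, b: int, e: int,
                     radius: int) -> int:
    """Least-squares single-changepoint refinement of a run boundary.

    Considers cut points within ``radius`` windows of ``b`` (keeping at
    least one window per side) and returns the cut minimizing the summed
    squared deviation of the *raw* statistic from each side's mean. NaNs
    are ignored.
    """
    lo = max(s + 1, b - radius)
    hi = min(e - 1, b + radius)
    if lo > hi:
        return b
    best, best_cost = b, np.inf
    for c in range(lo, hi + 1):
        left = values[s:c]
        right = values[c:e]
        cost = 0.0
        for seg in (left, right):
            seg = seg[np.isfinite(seg)]
            if len(seg):
                cost += float(np.sum((seg - seg.mean()) ** 2))
        if cost < best_cost:
            best_cost, best = cost, c
    return best


def merge_calls(classified: pd.DataFrame, min_run: int = 13,
                refine_radius: int = 8) -> list[StratumCall]:
    """Merge per-window labels into contiguous region calls.

    Maximal runs of one label become calls; runs shorter than ``min_run``
    windows are absorbed into the longer flanking run (iterated until
    stable). Because false excursions of a span-``s`` moving average persist
    for up to ``s`` windows, ``min_run`` defaults to just above the default
    smoothing span — well below the Mb scale of real strata. Because the
    per-window labels come from *smoothed* tracks, run boundaries drift by
    up to half the smoothing span; each boundary is therefore refined by a
    single-changepoint fit on the raw statistic that distinguishes the two
    flanking labels (coverage ratio when an old stratum is involved, SNP
    difference otherwise). Boundaries are reported at window resolution.
    """
    calls: list[StratumCall] = []
    for chrom, grp in classified.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        labels = grp.label.to_numpy().copy()
        while True:
            runs = _runs(labels)
            if len(runs) <= 1:
                break
            short = [(e - s, k) for k, (s, e, _) in enumerate(runs)
                     if e - s < min_run]
            if not short:
                break
            # absorb the shortest run into its larger neighbor
            _, k = min(short)
            s, e, _ = runs[k]
            left_len = runs[k - 1][1] - runs[k - 1][0] if k > 0 else -1
            right_len = runs[k + 1][1] - runs[k + 1][0] if k + 1 < len(runs) else -1
            donor = runs[k - 1][2] if left_len >= right_len else runs[k + 1][2]
            labels[s:e] = donor
        runs = _runs(labels)
        if refine_radius > 0 and len(runs) > 1:
            cov = grp.log2_mf_cov.to_numpy(dtype=float)
            snp = grp.mf_snp_diff.to_numpy(dtype=float)
            bounds = [0]
            for k in range(len(runs) - 1):
                left_lab, right_lab = runs[k][2], runs[k + 1][2]
                vals = cov if OLD_DEGENERATE in (left_lab, right_lab) else snp
                bounds.append(_refine_boundary(vals, bounds[-1], runs[k][1],
                                               runs[k + 1][1], refine_radius))
            bounds.append(len(labels))
            for k, (_, _, lab) in enumerate(runs):
                labels[bounds[k]:bounds[k + 1]] = lab
        for s, e, lab in _runs(labels):
            member = grp.iloc[s:e]
            sig = (member.label == lab).to_numpy()
            calls.append(StratumCall(chrom=chrom,
                                     start=int(member.start.iloc[0]),
                                     end=int(member.end.iloc[-1]),
                                     label=lab,
                                     support=float(np.mean(sig))))
    return calls


def calls_to_bed(calls: list[StratumCall]) -> pd.DataFrame:
    """BED-style frame (name = label, score = 1000 * support)."""
    return pd.DataFrame({
        "chrom": [c.chrom for c in calls],
        "start": [c.start for c in calls],
        "end": [c.end for c in calls],
        "name": [c.label for c in calls],
        "score": [int(round(1000 * c.support)) for c in calls],
    })
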