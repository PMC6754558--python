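"""Per-window male:female coverage and SNP-density statistics.

The genome is tiled with non-overlapping windows (default 50 kb). For each
window we compute normalized per-sex mean depth, the log2 male:female
coverage ratio, per-sex heterozygous-SNP densities (per kb per individual)
and their male-minus-female difference. Smoothed (moving-average) tracks of
these statistics are compared against a null distribution bootstrapped from
autosomal windows: a window deviating from the null's percentile envelope is
the unit of evidence for sex linkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["chrom", "start", "end", "male_cov", "female_cov",
                  "log2_mf_cov", "male_snp_den", "female_snp_den",
                  "mf_snp_diff"]


@dataclass(frozen=True)
class AutosomalNull:
    """Percentile bootstrap envelope of a window statistic on autosomes.

    ``boot_lower``/``boot_upper`` bound the central ``level`` mass of the
    per-window statistic distribution, estimated by resampling autosomal
    windows; a sex-linked window is flagged when its (smoothed) statistic
    falls outside the envelope.
    """

    statistic: str
    boot_lower: float
    boot_upper: float
    level: float
    n_boot: int
    autosomal_median: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not self.boot_lower <= self.autosomal_median <= self.boot_upper:
            raise ValueError("median must lie inside the bootstrap interval")

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.boot_lower) & (x <= self.boot_upper)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AutosomalNull":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# depth aggregation and normalization


def aggregate_depth(depth: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Overlap-weighted mean depth per window per sample.

    ``depth`` is a long table (chrom, start, end, sample, depth) whose
    intervals may be per-base, bedGraph runs, or already window-shaped.
    Windows with zero covered bases get NaN depth (flagged missing).
    """
    out = []
    for (chrom, sample), grp in depth.groupby(["chrom", "sample"], sort=False):
        win = windows[windows.chrom == chrom]
        if win.empty:
            continue
        wstart = win.start.to_numpy()
        wend = win.end.to_numpy()
        cover = np.zeros(len(win))
        weight = np.zeros(len(win))
        s = grp.start.to_numpy()
        e = grp.end.to_numpy()
        d = grp.depth.to_numpy(dtype=float)
        first = np.searchsorted(wend, s, side="right")
        last = np.searchsorted(wstart, e, side="left")
        for i in range(len(grp)):
            for w in range(first[i], last[i]):
                ov = min(e[i], wend[w]) - max(s[i], wstart[w])
                if ov > 0:
                    cover[w] += d[i] * ov
                    weight[w] += ov
        mean = np.divide(cover, weight, out=np.full(len(win), np.nan),
                         where=weight > 0)
        out.append(pd.DataFrame({"chrom": chrom, "start": wstart, "end": wend,
                                 "sample": sample, "depth": mean}))
    return pd.concat(out, ignore_index=True)


def normalize_samples(depth: pd.DataFrame, autosomes: list[str]) -> pd.DataFrame:
    """Scale each sample so its autosomal median window depth equals 1.

    Removes library-size differences between samples so that a deeper male
    library cannot mimic (or mask) sex linkage. Idempotent.
    """
    depth = depth.copy()
    is_auto = depth.chrom.isin(autosomes)
    if not is_auto.any():
        raise ValueError("no autosomal windows to normalize against")
    med = depth[is_auto].groupby("sample").depth.median()
    if (med <= 0).any():
        bad = med[med <= 0].index.tolist()
        raise ValueError(f"autosomal median depth is zero for samples {bad}")
    depth["depth"] = depth.depth / depth["sample"].map(med)
    return depth


def window_coverage(depth: pd.DataFrame, sex_map: pd.DataFrame) -> pd.DataFrame:
    """Per-window per-sex mean depth from a per-window per-sample table.

    The per-sex value is the mean over individuals of that sex of the
    per-sample window mean. Samples missing from ``sex_map`` are an error.
    """
    known = set(sex_map["sample"])
    unknown = set(depth["sample"]) - known
    if unknown:
        raise ValueError(f"samples with no sex label: {sorted(unknown)}")
    d = depth.merge(sex_map, on="sample")
    per_sex = (d.groupby(["chrom", "start", "end", "sex"]).depth.mean()
                .unstack("sex"))
    per_sex = per_sex.rename(columns={"M": "male_cov", "F": "female_cov"})
    for col in ("male_cov", "female_cov"):
        if col not in per_sex:
            per_sex[col] = np.nan
    return per_sex.reset_index().sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP density


def snp_density(het_sites: pd.DataFrame, windows: pd.DataFrame,
                sex_map: pd.DataFrame) -> pd.DataFrame:
    """Heterozygous sites per kb per individual, by sex, per window.

    ``het_sites`` holds one row per (chrom, pos, sample) heterozygous
    genotype that already passed the variant filters (see
    :func:`xyscan.io.read_vcf_het_sites`).
    """
    if windows.empty:
        raise ValueError("empty window set")
    unknown = set(het_sites["sample"]) - set(sex_map["sample"])
    if unknown:
        raise ValueError(f"samples with no sex label: {sorted(unknown)}")
    n_by_sex = sex_map.sex.value_counts().to_dict()
    out = windows[["chrom", "start", "end"]].copy()
    kb = (out.end - out.start) / 1000.0
    for sex, col in (("M", "male_snp_den"), ("F", "female_snp_den")):
        samples = set(sex_map.loc[sex_map.sex == sex, "sample"])
        sub = het_sites[het_sites["sample"].isin(samples)]
        counts = np.zeros(len(out))
        for chrom, grp in sub.groupby("chrom"):
            mask = (out.chrom == chrom).to_numpy()
            if not mask.any():
                continue
            wstart = out.start.to_numpy()[mask]
            pos = grp.pos.to_numpy()
            idx = np.searchsorted(wstart, pos, side="right") - 1
            wend = out.end.to_numpy()[mask]
            ok = (idx >= 0) & (pos < wend[np.clip(idx, 0, len(wend) - 1)])
            c = np.bincount(idx[ok], minlength=mask.sum())
            counts[mask] += c
        out[col] = counts / kb / max(n_by_sex.get(sex, 0), 1)
    out["mf_snp_diff"] = out.male_snp_den - out.female_snp_den
    return out


# ---------------------------------------------------------------------------
# window statistics table


def compute_window_stats(depth: pd.DataFrame, het_sites: pd.DataFrame,
                         windows: pd.DataFrame, sex_map: pd.DataFrame,
                         autosomes: list[str],
                         normalize: bool = True) -> pd.DataFrame:
    """Assemble the full per-window statistic table (one row per window).

    Columns follow ``WINDOW_COLUMNS``. ``log2_mf_cov`` is NaN for windows
    where either sex has zero or missing coverage (excluded downstream
    rather than imputed).
    """
    if normalize:
        depth = normalize_samples(depth, autosomes)
    cov = window_coverage(depth, sex_map)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cov.male_cov / cov.female_cov
        cov["log2_mf_cov"] = np.where(
            (cov.male_cov > 0) & (cov.female_cov > 0), np.log2(ratio), np.nan)
    den = snp_density(het_sites, windows, sex_map)
    stats = cov.merge(den, on=["chrom", "start", "end"], how="left")
    return stats[WINDOW_COLUMNS].sort_values(["chrom", "start"]).reset_index(drop=True)


def moving_average(values, span: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows.

    NaN entries are ignored (treated as missing, not zero); the output has
    the input's length. ``span`` must be odd and >= 1.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be an odd integer >= 1")
    x = np.asarray(values, dtype=float)
    if span == 1:
        return x.copy()
    ok = np.isfinite(x)
    filled = np.where(ok, x, 0.0)
    kernel = np.ones(span)
    half = span // 2
    # full convolution sliced to the centered span: length-preserving even
    # when the series is shorter than the span
    sums = np.convolve(filled, kernel, mode="full")[half:half + len(x)]
    counts = np.convolve(ok.astype(float), kernel, mode="full")[half:half + len(x)]
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


# ---------------------------------------------------------------------------
# bootstrap null


def bootstrap_autosomal_ci(values, n_boot: int = 1000, level: float = 0.95,
                           seed: int = 0, statistic: str = "statistic"
                           ) -> AutosomalNull:
    """Percentile envelope of a window statistic, bootstrapped from autosomes.

    Each replicate resamples the autosomal windows with replacement and
    takes the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the
    resampled per-window values; the reported bounds are the means of these
    percentile estimates over replicates. Roughly a fraction ``level`` of
    fresh null windows falls inside the interval.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 autosomal windows")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    lo, hi = np.quantile(x[idx], [alpha, 1.0 - alpha], axis=1)
    return AutosomalNull(statistic=statistic,
                         boot_lower=float(lo.mean()),
                         boot_upper=float(hi.mean()),
                         level=level, n_boot=n_boot,
                         autosomal_median=float(np.median(x)))
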