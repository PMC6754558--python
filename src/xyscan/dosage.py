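"""Chromosome-wide dosage-compensation tests on a gene x sample expression matrix.

With a degenerate Y, males carry one expressed X copy against two in
females. Without compensation, X-linked expression in males sits at half
the female level (log2 male:female ~ -1) and below the male autosomal
level; with chromosome-wide compensation both contrasts vanish. Three
tests feed a verdict:

* paired Wilcoxon signed-rank of male vs female per-gene means on the
  nonrecombining X;
* Wilcoxon rank-sum of X-linked vs autosomal per-gene means within males;
* Wilcoxon rank-sum of male:female log2 ratios, ASE X-linked genes vs
  autosomal genes.

Expression values are expected library-normalized upstream (TPM-like); this
module only median-centers samples. Gene labels (autosomal vs sex-linked,
with stratum) come from the strata calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test, signed_rank_test
from .winstats import moving_average

COMPLETE = "COMPLETE"
PARTIAL = "PARTIAL"
ABSENT = "ABSENT"
NOT_APPLICABLE = "NOT_APPLICABLE"

VERDICT_ALPHA = 0.01       # a chromosome-wide verdict demands strong evidence
VERDICT_MEDIAN_TOL = 0.25  # log2 units around 0 (compensated) vs around -1


@dataclass
class DosageReport:
    """Inputs and outcome of the dosage-compensation decision."""

    median_male_x: float
    median_female_x: float
    median_male_auto: float
    median_female_auto: float
    median_x_mf_log2: float
    p_mf_x: float
    p_x_vs_a_male: float
    p_ase_ratio: float | None
    verdict: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def median_center(matrix: pd.DataFrame,
                  ref_genes: list[str] | None = None) -> pd.DataFrame:
    """Equalize sample medians, preserving the overall expression scale.

    Each sample is scaled so all sample medians equal the geometric mean of
    the original medians; expression stays in its input (TPM-like) units so
    absolute floors such as ``min_expr`` keep their meaning. ``ref_genes``
    restricts the median to a reference set — pass the autosomal genes so
    that a genuinely halved sex chromosome in males cannot drag the male
    scaling factor with it.
    """
    ref = matrix if ref_genes is None else matrix.loc[
        [g for g in ref_genes if g in matrix.index]]
    med = ref.median(axis=0)
    if (med <= 0).any():
        raise ValueError("sample with non-positive median expression")
    target = float(np.exp(np.log(med).mean()))
    return matrix / med * target


def filter_expressed(matrix: pd.DataFrame, sex_map: pd.DataFrame,
                     min_expr: float = 1.0) -> pd.DataFrame:
    """Keep genes expressed (>= ``min_expr``) in at least half the samples
    of *each* sex; genes detectable in one sex only are removed."""
    keep = pd.Series(True, index=matrix.index)
    for sex in ("M", "F"):
        cols = sex_map.loc[sex_map.sex == sex, "sample"]
        sub = matrix[cols]
        keep &= (sub >= min_expr).sum(axis=1) >= np.ceil(len(cols) / 2)
    out = matrix[keep]
    if out.empty:
        raise ValueError("no genes pass the expression filter")
    return out


def sex_means(matrix: pd.DataFrame, sex_map: pd.DataFrame) -> pd.DataFrame:
    m_cols = sex_map.loc[sex_map.sex == "M", "sample"]
    f_cols = sex_map.loc[sex_map.sex == "F", "sample"]
    return pd.DataFrame({"male_mean": matrix[m_cols].mean(axis=1),
                         "female_mean": matrix[f_cols].mean(axis=1)})


def mf_log2_per_gene(matrix: pd.DataFrame, sex_map: pd.DataFrame) -> pd.Series:
    """log2(mean male / mean female) per gene; genes with a zero mean in
    either sex are dropped."""
    means = sex_means(matrix, sex_map)
    ok = (means.male_mean > 0) & (means.female_mean > 0)
    means = means[ok]
    return np.log2(means.male_mean / means.female_mean).rename("mf_log2")


def test_mf_x(matrix: pd.DataFrame, sex_map: pd.DataFrame,
              x_genes: list[str]) -> tuple[float, float]:
    """Paired signed-rank of male vs female per-gene means on the X."""
    genes = [g for g in x_genes if g in matrix.index]
    if len(genes) < 6:
        raise ValueError("need >= 6 X-linked genes for the paired test")
    means = sex_means(matrix.loc[genes], sex_map)
    return signed_rank_test(means.male_mean.to_numpy(),
                            means.female_mean.to_numpy())


def test_x_vs_autosomes(matrix: pd.DataFrame, sex_map: pd.DataFrame,
                        x_genes: list[str], auto_genes: list[str],
                        sex: str = "M") -> tuple[float, float]:
    """Rank-sum of X-linked vs autosomal per-gene means within one sex."""
    cols = sex_map.loc[sex_map.sex == sex, "sample"]
    x = matrix.loc[[g for g in x_genes if g in matrix.index], cols].mean(axis=1)
    a = matrix.loc[[g for g in auto_genes if g in matrix.index], cols].mean(axis=1)
    if len(x) < 2 or len(a) < 2:
        raise ValueError("need >= 2 genes per group")
    return rank_sum_test(x.to_numpy(), a.to_numpy())


def test_ase_gene_ratios(mf_log2: pd.Series, ase_x_genes: list[str],
                         auto_genes: list[str]) -> tuple[float, float] | None:
    """Rank-sum of M:F log2 ratios: ASE X-linked genes vs autosomal genes.

    Returns None when no ASE gene survives the expression filter (the
    verdict then treats the test as not applicable).
    """
    x = mf_log2.reindex([g for g in ase_x_genes if g in mf_log2.index]).dropna()
    a = mf_log2.reindex([g for g in auto_genes if g in mf_log2.index]).dropna()
    if len(x) < 2:
        return None
    return rank_sum_test(x.to_numpy(), a.to_numpy())


def sex_bias_classes(matrix: pd.DataFrame, sex_map: pd.DataFrame,
                     x_genes: list[str], auto_genes: list[str],
                     lfc_threshold: float = 1.0, alpha: float = 0.05
                     ) -> dict:
    """Male-biased / female-biased / unbiased gene counts, X vs autosomes.

    A gene is sex-biased when |log2 M/F| >= ``lfc_threshold`` and its
    per-gene rank-sum test (male vs female replicates) survives BH FDR at
    ``alpha``. Returns the 2x3 count table and a chi-square homogeneity
    test of class composition between X and autosomes (df=2 unless a class
    is empty everywhere).
    """
    from scipy import stats as sps

    m_cols = sex_map.loc[sex_map.sex == "M", "sample"]
    f_cols = sex_map.loc[sex_map.sex == "F", "sample"]
    if len(m_cols) < 2 or len(f_cols) < 2:
        raise ValueError("need >= 2 replicates per sex")
    genes = [g for g in list(x_genes) + list(auto_genes) if g in matrix.index]
    lfc = mf_log2_per_gene(matrix.loc[genes], sex_map)
    pvals = {}
    for g in lfc.index:
        _, p = rank_sum_test(matrix.loc[g, m_cols].to_numpy(),
                             matrix.loc[g, f_cols].to_numpy())
        pvals[g] = p
    pseries = pd.Series(pvals)
    q = pd.Series(multipletests(pseries.to_numpy(), method="fdr_bh")[1],
                  index=pseries.index)
    cls = pd.Series("unbiased", index=lfc.index)
    sig = (q < alpha) & (lfc.abs() >= lfc_threshold)
    cls[sig & (lfc > 0)] = "male_biased"
    cls[sig & (lfc < 0)] = "female_biased"
    order = ["male_biased", "female_biased", "unbiased"]
    x_set = set(x_genes)
    counts = pd.DataFrame({
        "X": [int(((cls.index.isin(x_set)) & (cls == c)).sum()) for c in order],
        "autosomes": [int((~cls.index.isin(x_set) & (cls == c)).sum())
                      for c in order],
    }, index=order).T
    table = counts.to_numpy()
    if (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate sex-bias table margins")
    nonzero = table.sum(axis=0) > 0
    if nonzero.sum() < 2:
        # a single occupied class: compositions are identical by construction
        chi2, p, dof = 0.0, 1.0, 0
    else:
        chi2, p, dof, _ = sps.chi2_contingency(table[:, nonzero],
                                               correction=False)
    return {"counts": counts, "chi2": float(chi2), "df": int(dof),
            "p_value": float(p), "classes": cls}


def expression_track(matrix: pd.DataFrame, sex_map: pd.DataFrame,
                     gene_pos: pd.DataFrame, windows: pd.DataFrame,
                     span: int = 11) -> pd.DataFrame:
    """Along-chromosome moving average of per-gene M:F log2 expression.

    ``gene_pos`` maps genes to (chrom, start, end); a gene is assigned to
    the window containing its midpoint. Windows without genes are missing
    (NaN), not zero, and are ignored by the smoother.
    """
    mf = mf_log2_per_gene(matrix, sex_map)
    gp = gene_pos.set_index("gene")
    out = []
    for chrom, win in windows.groupby("chrom", sort=False):
        win = win.sort_values("start").reset_index(drop=True)
        vals = [[] for _ in range(len(win))]
        genes = gp[gp.chrom == chrom]
        wstart = win.start.to_numpy()
        wend = win.end.to_numpy()
        for g, row in genes.iterrows():
            if g not in mf.index:
                continue
            mid = (row.start + row.end) // 2
            idx = np.searchsorted(wstart, mid, side="right") - 1
            if 0 <= idx < len(win) and mid < wend[idx]:
                vals[idx].append(mf[g])
        raw = np.array([np.mean(v) if v else np.nan for v in vals])
        out.append(win.assign(mf_log2=raw,
                              smooth_mf_log2=moving_average(raw, span)))
    return pd.concat(out, ignore_index=True)


def dosage_verdict(matrix: pd.DataFrame, sex_map: pd.DataFrame,
                   x_genes: list[str], auto_genes: list[str],
                   ase_x_genes: list[str] | None = None,
                   has_degenerate_stratum: bool = True,
                   alpha: float = VERDICT_ALPHA,
                   median_tol: float = VERDICT_MEDIAN_TOL) -> DosageReport:
    """Run the three contrasts and classify the compensation state.

    COMPLETE: both primary tests non-significant and the median X-linked
    M:F log2 ratio within ``median_tol`` of 0. ABSENT: both significant
    with the median at or below -(1 - ``median_tol``) (the uncompensated
    halving regime). PARTIAL otherwise; NOT_APPLICABLE when the chromosome
    carries no degenerate stratum (there is nothing to compensate).
    """
    mf = mf_log2_per_gene(matrix, sex_map)
    x_in = [g for g in x_genes if g in matrix.index]
    a_in = [g for g in auto_genes if g in matrix.index]
    if not has_degenerate_stratum or len(x_in) < 6:
        # nothing to compensate (or not enough genes to test it)
        return DosageReport(median_male_x=float("nan"),
                            median_female_x=float("nan"),
                            median_male_auto=float("nan"),
                            median_female_auto=float("nan"),
                            median_x_mf_log2=float("nan"),
                            p_mf_x=float("nan"), p_x_vs_a_male=float("nan"),
                            p_ase_ratio=None, verdict=NOT_APPLICABLE)
    means = sex_means(matrix, sex_map)
    med = {
        "median_male_x": float(means.loc[x_in, "male_mean"].median()),
        "median_female_x": float(means.loc[x_in, "female_mean"].median()),
        "median_male_auto": float(means.loc[a_in, "male_mean"].median()),
        "median_female_auto": float(means.loc[a_in, "female_mean"].median()),
    }
    median_x_ratio = float(mf.reindex(x_in).dropna().median())
    _, p_mf = test_mf_x(matrix, sex_map, x_in)
    _, p_xa = test_x_vs_autosomes(matrix, sex_map, x_in, a_in, sex="M")
    ase_res = (test_ase_gene_ratios(mf, ase_x_genes, a_in)
               if ase_x_genes else None)
    p_ase = None if ase_res is None else ase_res[1]

    if p_mf >= alpha and p_xa >= alpha and abs(median_x_ratio) <= median_tol:
        verdict = COMPLETE
    elif p_mf < alpha and p_xa < alpha and median_x_ratio <= -(1 - median_tol):
        verdict = ABSENT
    else:
        verdict = PARTIAL
    return DosageReport(**med, median_x_mf_log2=median_x_ratio,
                        p_mf_x=float(p_mf), p_x_vs_a_male=float(p_xa),
                        p_ase_ratio=p_ase, verdict=verdict)
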