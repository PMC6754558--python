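"""Allele-specific expression (ASE) from RNA-seq allele counts.

In a male with a degenerate Y, sex-linked genes either lose their
heterozygous sites altogether (Y copy deleted: the X is hemizygous) or, if
a Y copy survives but is transcriptionally down-regulated, show skewed read
support toward the X allele. We therefore (i) call usable heterozygous
sites, (ii) pool counts per gene into a major allele frequency, (iii) test
each gene's pooled counts against the balanced 0.5 expectation with an
exact binomial test under Benjamini–Hochberg FDR control, and (iv) ask
whether ASE is enriched on the sex chromosome relative to the autosomes
(Pearson chi-square) and whether the major-allele-frequency distributions
differ (Wilcoxon rank-sum).

Counts are pooled across a gene's sites in the orientation of the input
table and folded to the major allele once, at the gene level; even so, the
folded frequency sits slightly above 0.5 for balanced genes by sampling
alone, and the calibration tests quantify that inflation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test


def call_het_sites(counts: pd.DataFrame, min_depth: int = 10,
                   min_minor: int = 2) -> pd.DataFrame:
    """Filter site-level allele counts to usable heterozygous sites.

    Retains sites with total depth >= ``min_depth`` and minor-allele count
    >= ``min_minor`` — a site with all reads on one allele looks hemizygous
    (or homozygous) rather than heterozygous and is dropped. An empty result
    is allowed.
    """
    total = counts.count_a + counts.count_b
    minor = np.minimum(counts.count_a, counts.count_b)
    return counts[(total >= min_depth) & (minor >= min_minor)].reset_index(drop=True)


def genes_with_het_sites(all_genes: pd.Series | list[str],
                         called: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into with/without callable het sites (per sample)."""
    rows = []
    have = called.groupby("sample").gene.apply(set) if len(called) else {}
    for sample in (called["sample"].unique() if len(called) else []):
        got = have[sample]
        for g in all_genes:
            rows.append((sample, g, g in got))
    return pd.DataFrame(rows, columns=["sample", "gene", "has_het"])


def gene_major_allele_frequency(called: pd.DataFrame) -> pd.DataFrame:
    """Pool counts per (gene, sample); the major allele is defined on the
    pooled totals.

    Sites are summed in the orientation of the count table (allele A is
    consistent within a gene, e.g. the reference haplotype), and the gene's
    major allele frequency is ``max(A, B) / (A + B)`` — >= 0.5 by
    construction. Folding each *site* to its own major before pooling would
    bias the frequency far above 0.5 under balanced expression (and break
    the calibration of the downstream binomial test), so the fold happens
    once, at the gene level. Genes with zero pooled reads are dropped.
    """
    if called.empty:
        return pd.DataFrame(columns=["gene", "chrom", "sample", "n_sites",
                                     "total_major", "total_minor",
                                     "major_allele_freq"])
    agg = (called.groupby(["gene", "chrom", "sample"], sort=False)
                 .agg(n_sites=("site", "size"), total_a=("count_a", "sum"),
                      total_b=("count_b", "sum"))
                 .reset_index())
    agg = agg[(agg.total_a + agg.total_b) > 0]
    agg["total_major"] = np.maximum(agg.total_a, agg.total_b)
    agg["total_minor"] = np.minimum(agg.total_a, agg.total_b)
    agg["major_allele_freq"] = agg.total_major / (agg.total_major
                                                  + agg.total_minor)
    return agg.drop(columns=["total_a", "total_b"]).reset_index(drop=True)


def ase_test(gene_table: pd.DataFrame, null_p: float = 0.5,
             alpha: float = 0.05, min_depth: int = 10) -> pd.DataFrame:
    """Exact two-sided binomial test of pooled counts against ``null_p``.

    Adds ``p_value``, BH-adjusted ``q_value`` and ``is_ase`` (q < alpha)
    to the per-(gene, sample) table from
    :func:`gene_major_allele_frequency`. Genes with pooled depth below
    ``min_depth`` are not tested (NaN p/q, is_ase False).
    """
    if not 0 < null_p < 1:
        raise ValueError("null_p must be in (0, 1)")
    out = gene_table.copy()
    total = (out.total_major + out.total_minor).to_numpy()
    testable = total >= min_depth
    pvals = np.full(len(out), np.nan)
    for i in np.flatnonzero(testable):
        pvals[i] = stats.binomtest(int(out.total_major.iloc[i]),
                                   int(total[i]), null_p).pvalue
    qvals = np.full(len(out), np.nan)
    if testable.any():
        qvals[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    out["p_value"] = pvals
    out["q_value"] = qvals
    out["is_ase"] = (out.q_value < alpha).fillna(False)
    return out


def ase_enrichment(sex_linked: pd.DataFrame | tuple[int, int],
                   autosomal: pd.DataFrame | tuple[int, int]
                   ) -> dict[str, float]:
    """Pearson chi-square (df=1, no continuity correction) for an excess of
    ASE on the sex chromosome.

    Accepts either tested tables carrying an ``is_ase`` column or raw
    ``(n_ase, n_not_ase)`` pairs. The test unit is whatever the caller
    aggregated — sites or genes.
    """
    def pair(x):
        if isinstance(x, pd.DataFrame):
            ase = int(x.is_ase.sum())
            return ase, int(len(x) - ase)
        return int(x[0]), int(x[1])

    a, b = pair(sex_linked)
    c, d = pair(autosomal)
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p_value": float(p),
            "sex_linked_ase": a, "sex_linked_total": a + b,
            "autosomal_ase": c, "autosomal_total": c + d}


def compare_maf_distributions(sex_linked_maf, autosomal_maf) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum on major-allele-frequency values."""
    x = np.asarray(sex_linked_maf, dtype=float)
    y = np.asarray(autosomal_maf, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 genes per group")
    stat, p = rank_sum_test(x, y)
    return {"statistic": float(stat), "p_value": float(p),
            "sex_linked_median": float(np.median(x)),
            "autosomal_median": float(np.median(y))}
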