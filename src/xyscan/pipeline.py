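"""End-to-end stages tying simulate → scan → classify → kmers → ase → dosage.

Each stage reads/writes plain-text artifacts (TSV/BED/VCF/JSON) in an output
directory and appends one JSON-lines record per stage run (parameters,
seeds, row counts) to ``log.jsonl``, so a whole analysis is reproducible
from the directory alone. The command-line interface in
:mod:`xyscan.cli` and the numbered analysis drivers are thin wrappers over
these functions.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import dosage as dosage_mod
from . import io as xio
from . import kmers as kmers_mod
from . import strata as strata_mod
from . import winstats
from .simdata import (SEX_CHROM, SimConfig, SimTruth, build_truth,
                      simulate_dna_coverage, simulate_genomes, simulate_rna,
                      simulate_snps, tile_windows)


def _log(outdir: Path, stage: str, **fields) -> None:
    rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    with open(outdir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------


def run_simulate(config: SimConfig, outdir: str | Path,
                 with_genomes: bool = False) -> SimTruth:
    """Generate one synthetic dataset and write all pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_truth(config)

    cov = simulate_dna_coverage(config, truth)
    xio.write_tsv(cov, outdir / "coverage.tsv")
    hets = simulate_snps(config, truth)
    xio.write_vcf(hets, list(config.samples["sample"]), outdir / "snps.vcf",
                  contigs=config.chromosomes)
    counts, expr = simulate_rna(config, truth)
    xio.write_tsv(counts, outdir / "allele_counts.tsv")
    xio.write_tsv(expr, outdir / "expression.tsv", index=True)
    xio.write_tsv(config.samples, outdir / "sex_map.tsv")
    xio.write_bed(truth.genes, outdir / "genes.bed",
                  extra_cols=["gene", "stratum"])
    xio.write_bed(truth.windows, outdir / "truth_windows.bed",
                  extra_cols=["label"])
    xio.config_to_yaml(config, outdir / "config.yaml")
    if with_genomes:
        seqs, _ = simulate_genomes(config, truth)
        xio.write_fasta(seqs, outdir / "genomes.fasta")
    _log(outdir, "simulate", seed=config.seed, n_windows=len(truth.windows),
         n_genes=len(truth.genes), compensation=config.compensation)
    return truth


# ---------------------------------------------------------------------------


def scan_windows(coverage: pd.DataFrame, het_sites: pd.DataFrame,
                 sex_map: pd.DataFrame, window_size: int = 50_000,
                 sex_chrom: str = SEX_CHROM, orientation: str = "XY",
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 span: int = 11
                 ) -> tuple[pd.DataFrame, winstats.AutosomalNull,
                            winstats.AutosomalNull]:
    """Window statistics plus the two autosomal bootstrap nulls.

    The nulls are bootstrapped from the *smoothed* autosomal tracks
    (moving average of ``span`` windows within each autosome) because the
    classifier compares smoothed sex-chromosome windows against them —
    envelope and test statistic must be built the same way.
    ``orientation="ZW"`` swaps the sex labels so that the statistic is
    always heterogametic-over-homogametic.
    """
    if orientation not in ("XY", "ZW"):
        raise ValueError("orientation must be XY or ZW")
    if orientation == "ZW":
        sex_map = sex_map.assign(sex=sex_map.sex.map({"M": "F", "F": "M"}))
    chrom_ext = coverage.groupby("chrom").end.max()
    windows = pd.concat([
        pd.DataFrame({"chrom": chrom,
                      "start": np.arange(0, ext, window_size),
                      "end": np.minimum(np.arange(0, ext, window_size)
                                        + window_size, ext)})
        for chrom, ext in chrom_ext.items()], ignore_index=True)
    wdepth = winstats.aggregate_depth(coverage, windows)
    autosomes = [c for c in chrom_ext.index if c != sex_chrom]
    stats = winstats.compute_window_stats(wdepth, het_sites, windows, sex_map,
                                          autosomes)
    auto = stats[stats.chrom != sex_chrom]
    smooth_cov, smooth_snp = [], []
    for _, grp in auto.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        smooth_cov.append(winstats.moving_average(grp.log2_mf_cov, span))
        smooth_snp.append(winstats.moving_average(grp.mf_snp_diff, span))
    cov_null = winstats.bootstrap_autosomal_ci(
        np.concatenate(smooth_cov), n_boot=n_boot, level=level,
        seed=seed, statistic="log2_mf_cov")
    snp_null = winstats.bootstrap_autosomal_ci(
        np.concatenate(smooth_snp), n_boot=n_boot, level=level,
        seed=seed + 1, statistic="mf_snp_diff")
    return stats, cov_null, snp_null


def run_scan(outdir: str | Path, window_size: int = 50_000,
             sex_chrom: str = SEX_CHROM, orientation: str = "XY",
             n_boot: int = 1000, level: float = 0.95, seed: int = 0,
             min_depth: int = 10, min_gq: int = 20) -> pd.DataFrame:
    """File-level scan stage over a simulate (or user-supplied) directory."""
    outdir = Path(outdir)
    coverage = xio.read_tsv(outdir / "coverage.tsv")
    sex_map = xio.read_sex_map(outdir / "sex_map.tsv")
    hets = xio.read_vcf_het_sites(outdir / "snps.vcf", min_depth=min_depth,
                                  min_gq=min_gq)
    stats, cov_null, snp_null = scan_windows(
        coverage, hets, sex_map, window_size=window_size, sex_chrom=sex_chrom,
        orientation=orientation, n_boot=n_boot, level=level, seed=seed)
    xio.write_tsv(stats, outdir / "window_stats.tsv")
    cov_null.to_json(outdir / "null_cov.json")
    snp_null.to_json(outdir / "null_snp.json")
    _log(outdir, "scan", window_size=window_size, n_boot=n_boot, level=level,
         seed=seed, n_windows=len(stats))
    return stats


# ---------------------------------------------------------------------------


def run_classify(outdir: str | Path, sex_chrom: str = SEX_CHROM,
                 span: int = 11, min_run: int = 13) -> list[strata_mod.StratumCall]:
    outdir = Path(outdir)
    stats = xio.read_tsv(outdir / "window_stats.tsv")
    cov_null = winstats.AutosomalNull.from_json(outdir / "null_cov.json")
    snp_null = winstats.AutosomalNull.from_json(outdir / "null_snp.json")
    sex_stats = stats[stats.chrom == sex_chrom]
    classified = strata_mod.classify_windows(sex_stats, cov_null, snp_null,
                                             span=span)
    calls = strata_mod.merge_calls(classified, min_run=min_run)
    xio.write_tsv(classified, outdir / "window_labels.tsv")
    bed = strata_mod.calls_to_bed(calls)
    xio.write_bed(bed, outdir / "strata.bed", extra_cols=["name", "score"])
    _log(outdir, "classify", span=span, min_run=min_run, n_calls=len(calls))
    return calls


# ---------------------------------------------------------------------------


def run_kmers(sample_files: dict[str, tuple[str, str | Path]], k: int = 31,
              min_count: int = 2, species: str = "",
              outdir: str | Path | None = None) -> kmers_mod.SexSpecificResult:
    """Per-sample k-mer counting and sex-specific set computation.

    ``sample_files`` maps sample id -> (sex, FASTA/FASTQ path).
    """
    males, females = [], []
    for sample, (sex, path) in sample_files.items():
        ks = kmers_mod.count_kmers(path, k=k, min_count=min_count,
                                   sample=sample, sex=sex)
        (males if sex == "M" else females).append(ks)
    result = kmers_mod.sex_specific(males, females, species=species)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, s in (("y_mers", result.y_mers),
                        ("female_unique", result.female_unique)):
            (outdir / f"{name}.txt").write_text(
                "".join(km + "\n" for km in sorted(s)))
        ratio, flag = kmers_mod.compare_sex_specific_burden(result)
        summary = {"species": species, "k": k, "min_count": min_count,
                   "n_y_mers": result.n_y_mers,
                   "n_female_unique": result.n_female_unique,
                   "female_to_male_ratio": ratio, "y_loss_signature": flag}
        (outdir / "kmer_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        _log(outdir, "kmers", **summary)
    return result


# ---------------------------------------------------------------------------


def gene_locations(outdir: Path) -> pd.DataFrame:
    return xio.read_bed(outdir / "genes.bed", names=["gene", "stratum"])


def _genes_under(genes: pd.DataFrame, calls_bed: pd.DataFrame,
                 sex_chrom: str, labels: tuple[str, ...]) -> list[str]:
    picked = calls_bed[(calls_bed.chrom == sex_chrom)
                       & calls_bed.name.isin(labels)]
    out = []
    for g in genes.itertuples(index=False):
        if g.chrom != sex_chrom:
            continue
        mid = (g.start + g.end) // 2
        if ((picked.start <= mid) & (mid < picked.end)).any():
            out.append(g.gene)
    return out


def _sex_linked_genes(genes: pd.DataFrame, calls_bed: pd.DataFrame,
                      sex_chrom: str) -> tuple[list[str], list[str]]:
    """Split genes into nonrecombining sex-linked vs autosomal using the
    strata calls (genes under an UNDIFF_PAR call behave autosomally)."""
    sex_linked = _genes_under(genes, calls_bed, sex_chrom,
                              (strata_mod.YOUNG, strata_mod.OLD_DEGENERATE))
    autosomal = list(genes.loc[genes.chrom != sex_chrom, "gene"])
    return sex_linked, autosomal


def run_ase(outdir: str | Path, sex_chrom: str = SEX_CHROM,
            min_depth: int = 10, min_minor: int = 2, alpha: float = 0.05
            ) -> dict:
    """Het-site calling, per-gene ASE tests, sex-chromosome enrichment."""
    outdir = Path(outdir)
    counts = xio.read_tsv(outdir / "allele_counts.tsv")
    sex_map = xio.read_sex_map(outdir / "sex_map.tsv")
    genes = gene_locations(outdir)
    calls_bed = xio.read_bed(outdir / "strata.bed", names=["name", "score"])
    sex_linked, autosomal = _sex_linked_genes(genes, calls_bed, sex_chrom)

    males = set(sex_map.loc[sex_map.sex == "M", "sample"])
    called = ase_mod.call_het_sites(counts, min_depth=min_depth,
                                    min_minor=min_minor)
    gene_tab = ase_mod.gene_major_allele_frequency(called)
    tested = ase_mod.ase_test(gene_tab, alpha=alpha, min_depth=min_depth)
    xio.write_tsv(tested, outdir / "gene_ase.tsv")

    male_tested = tested[tested["sample"].isin(males)]
    # site-level enrichment unit (the default): a site inherits its gene's call
    called_m = called[called["sample"].isin(males)].merge(
        male_tested[["gene", "sample", "is_ase"]], on=["gene", "sample"],
        how="inner")
    sl_sites = called_m[called_m.gene.isin(sex_linked)]
    au_sites = called_m[called_m.gene.isin(autosomal)]
    enrichment = ase_mod.ase_enrichment(
        (int(sl_sites.is_ase.sum()), int((~sl_sites.is_ase).sum())),
        (int(au_sites.is_ase.sum()), int((~au_sites.is_ase).sum())))
    maf = ase_mod.compare_maf_distributions(
        male_tested.loc[male_tested.gene.isin(sex_linked), "major_allele_freq"],
        male_tested.loc[male_tested.gene.isin(autosomal), "major_allele_freq"])

    ase_x_genes = sorted(set(
        male_tested.loc[male_tested.is_ase
                        & male_tested.gene.isin(sex_linked), "gene"]))
    summary = {"enrichment": enrichment, "maf_comparison": maf,
               "n_sex_linked_genes": len(sex_linked),
               "n_sex_linked_with_het_in_males": int(
                   male_tested.loc[male_tested.gene.isin(sex_linked), "gene"]
                   .nunique()),
               "ase_x_genes": ase_x_genes}
    (outdir / "ase_summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n")
    _log(outdir, "ase", min_depth=min_depth, min_minor=min_minor, alpha=alpha,
         chi2=enrichment["chi2"], n_ase_x=len(ase_x_genes))
    return summary


# ---------------------------------------------------------------------------


def run_dosage(outdir: str | Path, sex_chrom: str = SEX_CHROM,
               min_expr: float = 1.0) -> dosage_mod.DosageReport:
    outdir = Path(outdir)
    expr = xio.read_expression(outdir / "expression.tsv")
    sex_map = xio.read_sex_map(outdir / "sex_map.tsv")
    genes = gene_locations(outdir)
    calls_bed = xio.read_bed(outdir / "strata.bed", names=["name", "score"])
    # dose only differs where the Y copy is degenerate, so the compensation
    # contrasts are run on genes under OLD_DEGENERATE calls
    sex_linked = _genes_under(genes, calls_bed, sex_chrom,
                              (strata_mod.OLD_DEGENERATE,))
    autosomal = list(genes.loc[genes.chrom != sex_chrom, "gene"])
    has_degen = (calls_bed.name == strata_mod.OLD_DEGENERATE).any()
    ase_x = []
    ase_path = outdir / "ase_summary.json"
    if ase_path.exists():
        ase_x = json.loads(ase_path.read_text()).get("ase_x_genes", [])

    matrix = dosage_mod.median_center(expr, ref_genes=autosomal)
    matrix = dosage_mod.filter_expressed(matrix, sex_map, min_expr=min_expr)
    report = dosage_mod.dosage_verdict(matrix, sex_map, sex_linked, autosomal,
                                       ase_x_genes=ase_x,
                                       has_degenerate_stratum=bool(has_degen))
    report.to_json(outdir / "dosage_report.json")
    track = dosage_mod.expression_track(
        matrix, sex_map, genes, tile_windows_from_bed(outdir))
    xio.write_tsv(track, outdir / "expression_track.tsv")
    _log(outdir, "dosage", verdict=report.verdict, p_mf_x=report.p_mf_x,
         p_x_vs_a_male=report.p_x_vs_a_male)
    return report


def tile_windows_from_bed(outdir: Path) -> pd.DataFrame:
    truth = xio.read_bed(outdir / "truth_windows.bed", names=["label"])
    return truth[["chrom", "start", "end"]]


# ---------------------------------------------------------------------------


def run_report(outdir: str | Path) -> str:
    """Human-readable summary of every stage found in the directory."""
    outdir = Path(outdir)
    lines = ["xyscan run summary", "=" * 60]
    strata_path = outdir / "strata.bed"
    if strata_path.exists():
        bed = xio.read_bed(strata_path, names=["name", "score"])
        lines.append("\nStratum calls (chrom start end label support/1000):")
        for r in bed.itertuples(index=False):
            lines.append(f"  {r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}")
    kp = outdir / "kmer_summary.json"
    if kp.exists():
        d = json.loads(kp.read_text())
        lines.append(f"\nK-mers (k={d['k']}): {d['n_y_mers']} Y-mers, "
                     f"{d['n_female_unique']} female-unique "
                     f"(F:M ratio {d['female_to_male_ratio']:.2f}"
                     f"{', Y-loss signature' if d['y_loss_signature'] else ''})")
    ap = outdir / "ase_summary.json"
    if ap.exists():
        d = json.loads(ap.read_text())
        e = d["enrichment"]
        lines.append(
            f"\nASE: chi2({e['df']}) = {e['chi2']:.3f}, p = {e['p_value']:.3g}; "
            f"{e['sex_linked_ase']}/{e['sex_linked_total']} sex-linked vs "
            f"{e['autosomal_ase']}/{e['autosomal_total']} autosomal ASE sites")
        lines.append(
            f"     {d['n_sex_linked_with_het_in_males']} of "
            f"{d['n_sex_linked_genes']} sex-linked genes retain male het sites")
    dp = outdir / "dosage_report.json"
    if dp.exists():
        d = json.loads(dp.read_text())
        lines.append(
            f"\nDosage compensation: {d['verdict']} "
            f"(median X M:F log2 = {d['median_x_mf_log2']:.3f}, "
            f"p_mf_x = {d['p_mf_x']:.3g}, p_x_vs_a = {d['p_x_vs_a_male']:.3g})")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text
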