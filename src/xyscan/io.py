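"""Readers and writers for the formats the pipeline consumes and produces.

Conventions: genomic intervals are 0-based half-open everywhere in memory
(BED-compatible); VCF positions are converted to 0-based on read and back to
1-based on write. Plain-text and gzip inputs are both accepted.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import SimConfig, StratumSpec


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def iter_sequences(path: str | Path) -> Iterable[str]:
    """Yield raw sequences from a FASTA or FASTQ file (gzip allowed)."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# VCF


def write_vcf(het_table: pd.DataFrame, samples: list[str], path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write a multi-sample VCF 4.2 from a heterozygous-site table.

    ``het_table`` columns: chrom, pos (0-based), sample, gt, dp, gq. Samples
    not listed at a site are emitted as homozygous reference. REF/ALT are
    placeholder alleles: downstream density computations use genotypes only.
    """
    by_site: dict[tuple[str, int], dict[str, tuple[str, int, int]]] = {}
    for row in het_table.itertuples(index=False):
        by_site.setdefault((row.chrom, int(row.pos)), {})[row.sample] = (
            row.gt, int(row.dp), int(row.gq))
    default_dp = int(het_table.dp.median()) if len(het_table) else 30
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos) in sorted(by_site, key=lambda k: (k[0], k[1])):
            calls = by_site[(chrom, pos)]
            fields = []
            for s in samples:
                gt, dp, gq = calls.get(s, ("0/0", default_dp, 99))
                fields.append(f"{gt}:{dp}:{gq}")
            fh.write(f"{chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t"
                     + "\t".join(fields) + "\n")


def read_vcf_het_sites(path: str | Path, min_depth: int = 10,
                       min_gq: int = 20) -> pd.DataFrame:
    """Heterozygous biallelic-SNV genotypes from a VCF.

    Returns a table with columns chrom, pos (0-based), sample for every
    genotype that is heterozygous and passes the depth / quality filters.
    Multiallelic records and non-SNVs are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, samps = [], [], []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        try:
            dps = var.format("DP")
        except KeyError:
            dps = None
        try:
            gqs = var.gt_quals
        except Exception:
            gqs = None
        for i, s in enumerate(samples):
            if gts[i] != 1:
                continue
            if dps is not None and int(dps[i][0]) < min_depth:
                continue
            if gqs is not None and gqs[i] >= 0 and gqs[i] < min_gq:
                continue
            chroms.append(var.CHROM)
            poss.append(var.POS - 1)
            samps.append(s)
    vcf.close()
    return pd.DataFrame({"chrom": chroms, "pos": poss, "sample": samps})


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = (base + extra)[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sex_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: sample, sex (M/F). Header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sample", "sex"], dtype=str)
    if df.iloc[0].tolist() == ["sample", "sex"]:
        df = df.iloc[1:].reset_index(drop=True)
    bad = set(df.sex) - {"M", "F"}
    if bad:
        raise ValueError(f"unknown sex labels {sorted(bad)}; expected M/F")
    return df


# ---------------------------------------------------------------------------
# config


def config_to_yaml(config: SimConfig, path: str | Path) -> None:
    d = {k: v for k, v in vars(config).items() if k != "strata"}
    d["strata"] = [vars(s) for s in config.strata]
    for k, v in list(d.items()):
        if isinstance(v, (np.integer,)):
            d[k] = int(v)
        elif isinstance(v, (np.floating,)):
            d[k] = float(v)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    strata = d.pop("strata", None)
    if strata is not None:
        d["strata"] = [StratumSpec(**s) for s in strata]
    return SimConfig(**d)
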