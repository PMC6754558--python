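"""Synthetic XY-system data generator with recorded ground truth.

Emulates the genomic signatures of sex-chromosome differentiation in a
male-heterogametic (XY) system at three stages:

* an undifferentiated / pseudoautosomal state (PAR) in which X and Y still
  recombine — coverage and SNP density behave autosomally in both sexes;
* a *young* stratum: recombination recently suppressed, the Y copy intact
  but diverged — male reads from the Y still co-map to the X, so males show
  **elevated SNP density** at fixed X–Y differences with **no coverage loss**;
* an *old, degenerate* stratum: large-scale Y sequence loss leaves males
  effectively X-hemizygous — **reduced male coverage** (down to half at total
  loss) and **reduced male SNP density** over the deleted intervals.

On top of the DNA signals the generator emits RNA-seq-like per-site allele
counts (to probe Y gene-activity decay through allele-specific expression)
and a gene × sample expression matrix with or without chromosome-wide dosage
compensation. Every stochastic choice is recorded in a :class:`SimTruth`
so downstream inference can be scored against the truth.

All coordinates are 0-based half-open (BED convention). All outputs are
deterministic functions of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROM = "chrX"

# independent random streams per operation, so outputs do not depend on the
# order in which the simulate_* functions are called
_STREAM_GENOME = 1
_STREAM_COVERAGE = 2
_STREAM_SNP = 3
_STREAM_RNA = 4
_STREAM_READS = 5
_STREAM_TRUTH = 6

PAR = "PAR"
YOUNG = "young"
OLD = "old"


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class StratumSpec:
    """One block of the sex chromosome with a common recombination history.

    Parameters
    ----------
    start, end
        0-based half-open interval on the sex chromosome, in bp.
    kind
        ``"PAR"`` (recombining, X == Y), ``"young"`` (nonrecombining,
        intact diverged Y) or ``"old"`` (nonrecombining, degenerate Y).
    xy_divergence
        Density of fixed X–Y differences per bp (young/old only).
    y_loss
        Fraction of the Y copy of this interval deleted or diverged beyond
        mapping (old only).
    y_silenced_fraction
        Fraction of *surviving* Y gene copies that are transcriptionally
        silent (old only).
    """

    start: int
    end: int
    kind: str = PAR
    xy_divergence: float = 0.0
    y_loss: float = 0.0
    y_silenced_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (PAR, YOUNG, OLD):
            raise ConfigError(f"unknown stratum kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ConfigError(f"bad stratum interval [{self.start}, {self.end})")
        for name in ("xy_divergence", "y_loss", "y_silenced_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.kind == PAR and (self.xy_divergence or self.y_loss):
            raise ConfigError("PAR stratum must have xy_divergence = y_loss = 0")
        if self.kind != OLD and self.y_loss:
            raise ConfigError("y_loss is only meaningful for old strata")


def default_strata(sex_chrom_length: int) -> list[StratumSpec]:
    """PAR / young / old thirds — the canonical test chromosome."""
    third = sex_chrom_length // 3
    return [
        StratumSpec(0, third, PAR),
        StratumSpec(third, 2 * third, YOUNG, xy_divergence=0.005),
        StratumSpec(2 * third, sex_chrom_length, OLD, xy_divergence=0.005,
                    y_loss=0.9, y_silenced_fraction=0.5),
    ]


@dataclass
class SimConfig:
    """Parameters of one synthetic XY dataset.

    ``haploid_depth`` is the mean sequencing depth contributed by one
    chromosome copy, so autosomal (diploid) depth has mean ``2 * haploid_depth``
    in both sexes. ``depth_dispersion`` is the negative-binomial size
    parameter for window read counts (smaller = noisier).
    ``polymorphism_rate`` is the per-bp heterozygosity of one diploid
    individual.
    """

    seed: int = 0
    n_autosomes: int = 2
    chrom_length: int = 5_000_000
    sex_chrom_length: int = 15_000_000
    strata: list[StratumSpec] | None = None
    haploid_depth: float = 20.0
    depth_dispersion: float = 10.0
    polymorphism_rate: float = 0.001
    n_males: int = 3
    n_females: int = 3
    n_genes_per_chrom: int = 120
    gene_length: int = 1_000
    rna_depth: float = 40.0
    rna_sites_per_gene: int = 5
    ase_fraction: float = 0.8
    ase_theta: float = 0.8
    expression_noise_sd: float = 0.25
    compensation: bool = False
    kmer_error_rate: float = 0.0
    read_length: int = 100
    window_size: int = 50_000

    def __post_init__(self) -> None:
        if self.strata is None:
            self.strata = default_strata(self.sex_chrom_length)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.haploid_depth <= 0:
            raise ConfigError("haploid_depth must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigError("depth_dispersion must be > 0")
        if self.rna_depth <= 0:
            raise ConfigError("rna_depth must be > 0")
        if self.polymorphism_rate < 0:
            raise ConfigError("polymorphism_rate must be >= 0")
        if self.n_males < 1 or self.n_females < 1:
            raise ConfigError("need at least one individual of each sex")
        if not 0.5 <= self.ase_theta <= 1.0:
            raise ConfigError("ase_theta is an X-allele fraction in [0.5, 1]")
        strata = sorted(self.strata, key=lambda s: s.start)
        pos = 0
        for s in strata:
            if s.start != pos:
                raise ConfigError(
                    f"strata must tile [0, {self.sex_chrom_length}) without gaps "
                    f"or overlaps; found boundary mismatch at {s.start} (expected {pos})"
                )
            pos = s.end
        if pos != self.sex_chrom_length:
            raise ConfigError(
                f"strata end at {pos}, not sex_chrom_length={self.sex_chrom_length}"
            )
        self.strata = strata

    # -- chromosome bookkeeping ----------------------------------------
    @property
    def autosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)]

    @property
    def chromosomes(self) -> dict[str, int]:
        lens = {c: self.chrom_length for c in self.autosomes}
        lens[SEX_CHROM] = self.sex_chrom_length
        return lens

    @property
    def samples(self) -> pd.DataFrame:
        ids = [f"M{i + 1}" for i in range(self.n_males)] + [
            f"F{i + 1}" for i in range(self.n_females)
        ]
        sexes = ["M"] * self.n_males + ["F"] * self.n_females
        return pd.DataFrame({"sample": ids, "sex": sexes})

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def stratum_at(self, pos: int) -> StratumSpec:
        for s in self.strata:
            if s.start <= pos < s.end:
                return s
        raise ValueError(f"position {pos} outside the sex chromosome")


def reticulata_like(length: int = 26_000_000, **kwargs) -> SimConfig:
    """Largely homomorphic XY: big PAR, a short young stratum next to a
    small old stratum (guppy-like)."""
    mb = length / 26
    strata = [
        StratumSpec(0, int(15 * mb), PAR),
        StratumSpec(int(15 * mb), int(17 * mb), YOUNG, xy_divergence=0.005),
        StratumSpec(int(17 * mb), int(20 * mb), OLD, xy_divergence=0.005,
                    y_loss=0.9, y_silenced_fraction=0.5),
        StratumSpec(int(20 * mb), length, PAR),
    ]
    return SimConfig(sex_chrom_length=length, strata=strata, **kwargs)


def wingei_like(length: int = 26_000_000, **kwargs) -> SimConfig:
    """Nonrecombining across most of the chromosome: a large young stratum,
    the shared old stratum, and a residual far-end PAR."""
    mb = length / 26
    strata = [
        StratumSpec(0, int(17 * mb), YOUNG, xy_divergence=0.005),
        StratumSpec(int(17 * mb), int(20 * mb), OLD, xy_divergence=0.005,
                    y_loss=0.9, y_silenced_fraction=0.5),
        StratumSpec(int(20 * mb), length, PAR),
    ]
    return SimConfig(sex_chrom_length=length, strata=strata, **kwargs)


def picta_like(length: int = 26_000_000, compensation: bool = True,
               **kwargs) -> SimConfig:
    """Fully degenerate system: the whole chromosome old and Y-depleted
    except a limited far-end PAR; chromosome-wide dosage compensation on by
    default (the observed state)."""
    mb = length / 26
    strata = [
        StratumSpec(0, int(24 * mb), OLD, xy_divergence=0.005,
                    y_loss=0.9, y_silenced_fraction=0.5),
        StratumSpec(int(24 * mb), length, PAR),
    ]
    return SimConfig(sex_chrom_length=length, strata=strata,
                     compensation=compensation, **kwargs)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    config: SimConfig
    windows: pd.DataFrame            # chrom, start, end, label (autosomal -> "autosome")
    genes: pd.DataFrame              # gene, chrom, start, end, stratum, y_deleted, y_silenced, ase, theta
    xy_divergent_sites: np.ndarray   # positions on the sex chromosome
    y_deleted_intervals: list[tuple[int, int]]
    compensation: bool

    @property
    def y_deleted_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes.y_deleted, "gene"])

    @property
    def y_silenced_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes.y_silenced, "gene"])

    @property
    def ase_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes.ase, "gene"])

    @property
    def sex_window_labels(self) -> pd.DataFrame:
        return self.windows[self.windows.chrom == SEX_CHROM].reset_index(drop=True)


# ---------------------------------------------------------------------------
# truth construction


def tile_windows(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping windows tiling every chromosome."""
    rows = []
    for chrom, length in config.chromosomes.items():
        starts = np.arange(0, length, config.window_size)
        ends = np.minimum(starts + config.window_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _window_label(config: SimConfig, start: int, end: int) -> str:
    mid = (start + end) // 2
    return config.stratum_at(mid).kind


def build_truth(config: SimConfig) -> SimTruth:
    """Draw gene placement and Y-fate labels; label every window.

    Window labels on the sex chromosome follow the stratum containing the
    window midpoint (strata are window-aligned whenever their boundaries are
    multiples of ``window_size``).
    """
    rng = config.rng(_STREAM_TRUTH)
    windows = tile_windows(config)
    labels = []
    for chrom, start, end in windows[["chrom", "start", "end"]].itertuples(index=False):
        if chrom == SEX_CHROM:
            labels.append(_window_label(config, start, end))
        else:
            labels.append("autosome")
    windows = windows.assign(label=labels)

    # genes: uniform placement, fixed count per chromosome
    gene_rows = []
    for chrom, length in config.chromosomes.items():
        starts = np.sort(
            rng.integers(0, max(1, length - config.gene_length),
                         size=config.n_genes_per_chrom)
        )
        for j, s in enumerate(starts):
            gene_rows.append((f"{chrom}_g{j + 1:04d}", chrom, int(s),
                              int(s) + config.gene_length))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])

    stratum, deleted, silenced, ase, theta = [], [], [], [], []
    for g in genes.itertuples(index=False):
        if g.chrom != SEX_CHROM:
            stratum.append("autosome")
            deleted.append(False); silenced.append(False); ase.append(False)
            theta.append(0.5)
            continue
        spec = config.stratum_at((g.start + g.end) // 2)
        stratum.append(spec.kind)
        if spec.kind != OLD:
            deleted.append(False); silenced.append(False); ase.append(False)
            theta.append(0.5)
            continue
        is_del = bool(rng.random() < spec.y_loss)
        is_sil = bool((not is_del) and rng.random() < spec.y_silenced_fraction)
        is_ase = bool((not is_del) and (not is_sil)
                      and rng.random() < config.ase_fraction)
        deleted.append(is_del); silenced.append(is_sil); ase.append(is_ase)
        theta.append(1.0 if is_sil else (config.ase_theta if is_ase else 0.5))
    genes = genes.assign(stratum=stratum, y_deleted=deleted,
                         y_silenced=silenced, ase=ase, theta=theta)

    # fixed X–Y differences in nonrecombining strata
    div_sites = []
    for s in config.strata:
        if s.kind == PAR or s.xy_divergence <= 0:
            continue
        n = rng.binomial(s.end - s.start, s.xy_divergence)
        div_sites.append(rng.choice(s.end - s.start, size=n, replace=False) + s.start)
    xy_divergent = (np.sort(np.concatenate(div_sites))
                    if div_sites else np.empty(0, dtype=int))

    # old-stratum deletion: one contiguous block covering y_loss of the stratum
    del_ivals = []
    for s in config.strata:
        if s.kind != OLD or s.y_loss <= 0:
            continue
        span = int(round(s.y_loss * (s.end - s.start)))
        offset = int(rng.integers(0, (s.end - s.start) - span + 1))
        del_ivals.append((s.start + offset, s.start + offset + span))

    return SimTruth(config=config, windows=windows, genes=genes,
                    xy_divergent_sites=xy_divergent,
                    y_deleted_intervals=del_ivals,
                    compensation=config.compensation)


# ---------------------------------------------------------------------------
# genomes


def simulate_genomes(config: SimConfig, truth: SimTruth | None = None
                     ) -> tuple[dict[str, str], SimTruth]:
    """Reference haplotypes: one pair per autosome, one X and one Y.

    The Y equals the X except at the fixed divergent sites (substituted base)
    and over the old-stratum deleted intervals (sequence removed). Autosomal
    haplotype pairs differ at background heterozygous sites at the
    polymorphism rate.
    """
    if truth is None:
        truth = build_truth(config)
    rng = config.rng(_STREAM_GENOME)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out: dict[str, str] = {}

    def random_seq(n: int) -> np.ndarray:
        return bases[rng.integers(0, 4, size=n)]

    def mutate(seq: np.ndarray, pos: np.ndarray) -> np.ndarray:
        seq = seq.copy()
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=len(pos))
        idx = np.searchsorted(bases, seq[pos])
        seq[pos] = bases[(idx + shift) % 4]
        return seq

    for chrom in config.autosomes:
        hap1 = random_seq(config.chrom_length)
        n_het = rng.binomial(config.chrom_length, config.polymorphism_rate)
        het = rng.choice(config.chrom_length, size=n_het, replace=False)
        hap2 = mutate(hap1, het)
        out[f"{chrom}_hap1"] = hap1.tobytes().decode()
        out[f"{chrom}_hap2"] = hap2.tobytes().decode()

    x = random_seq(config.sex_chrom_length)
    y = mutate(x, truth.xy_divergent_sites.astype(int)) \
        if len(truth.xy_divergent_sites) else x.copy()
    keep = np.ones(config.sex_chrom_length, dtype=bool)
    for s, e in truth.y_deleted_intervals:
        keep[s:e] = False
    out["chrX"] = x.tobytes().decode()
    out["chrY"] = y[keep].tobytes().decode()
    return out, truth


# ---------------------------------------------------------------------------
# DNA coverage


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Gamma–Poisson (negative binomial) draws with the given mean and size."""
    lam = rng.gamma(shape=dispersion, scale=np.asarray(mean) / dispersion)
    return rng.poisson(lam)


def male_x_multiplier(label: str, y_loss: float) -> float:
    """Expected male X-mapped copy factor: 1 + m_w.

    In PAR and young strata Y reads co-map to the X (m_w = 1); in old strata
    the deleted fraction of the Y contributes nothing (m_w = 1 - y_loss).
    """
    if label == OLD:
        return 2.0 - y_loss
    return 2.0


def simulate_dna_coverage(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Per-window per-sample mean depth (long table).

    Female windows have mean ``2 * haploid_depth`` everywhere; male sex-linked
    windows have mean ``haploid_depth * (1 + m_w)`` with ``m_w`` as in
    :func:`male_x_multiplier`. Counts are negative-binomial at the configured
    dispersion (applied to total bases per window, reported as mean depth).
    """
    rng = config.rng(_STREAM_COVERAGE)
    windows = truth.windows
    frames = []
    wlen = (windows.end - windows.start).to_numpy()
    is_sex = (windows.chrom == SEX_CHROM).to_numpy()
    # per-window male multiplier
    mult = np.full(len(windows), 2.0)
    for i, row in enumerate(windows.itertuples(index=False)):
        if is_sex[i] and row.label == OLD:
            spec = config.stratum_at((row.start + row.end) // 2)
            mult[i] = 2.0 - spec.y_loss
    for sample, sex in config.samples.itertuples(index=False):
        mean_depth = config.haploid_depth * (mult if sex == "M" else 2.0)
        total = _nb_counts(rng, mean_depth * wlen, config.depth_dispersion)
        frames.append(pd.DataFrame({
            "chrom": windows.chrom, "start": windows.start, "end": windows.end,
            "sample": sample, "depth": total / wlen,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# SNPs


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in intervals:
        mask |= (pos >= s) & (pos < e)
    return mask


def simulate_snps(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Heterozygous-site table for all samples (one row per sample × site).

    Background heterozygosity at the polymorphism rate in both sexes on all
    chromosomes. Males are additionally heterozygous at every fixed X–Y
    divergent site outside deleted intervals (Y reads co-map to the X), and
    lose background heterozygosity over old-stratum deleted intervals
    (hemizygous X). Columns: chrom, pos, sample, gt, dp, gq.
    """
    rng = config.rng(_STREAM_SNP)
    rows = []
    deleted = truth.y_deleted_intervals
    for sample, sex in config.samples.itertuples(index=False):
        for chrom, length in config.chromosomes.items():
            n = rng.binomial(length, config.polymorphism_rate)
            pos = np.sort(rng.choice(length, size=n, replace=False))
            if chrom == SEX_CHROM and sex == "M":
                # hemizygous over deleted Y intervals: no background hets there
                pos = pos[~_in_intervals(pos, deleted)]
                div = truth.xy_divergent_sites
                div = div[~_in_intervals(div, deleted)]
                pos = np.unique(np.concatenate([pos, div]))
            dp = rng.poisson(2 * config.haploid_depth, size=len(pos))
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "sample": sample,
                "gt": "0/1", "dp": dp, "gq": 99,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# RNA: allele counts and expression


def simulate_rna(config: SimConfig, truth: SimTruth
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele counts at heterozygous sites plus a gene × sample expression matrix.

    Allele counts: per retained het site, reads split Binomial(n, theta) with
    theta the gene's X-allele fraction (0.5 balanced; ``ase_theta`` for
    partially imbalanced genes; 1.0 for genes whose Y copy is silent, which
    therefore yield no *callable* het site). Males have no sites at all for
    genes whose Y copy is deleted (X-hemizygous). Site read depth is Poisson
    at ``rna_depth``.

    Expression: per-gene lognormal baseline shared by the sexes; without
    compensation the male level of a sex-linked gene is scaled by
    ``0.5 / theta`` (0.5 for a silent Y, intermediate for partial ASE);
    with chromosome-wide compensation male and female levels are equal.
    """
    rng = config.rng(_STREAM_RNA)
    samples = config.samples
    count_rows = []
    for g in truth.genes.itertuples(index=False):
        site_pos = g.start + np.sort(
            rng.choice(max(g.end - g.start, config.rna_sites_per_gene),
                       size=config.rna_sites_per_gene, replace=False))
        for sample, sex in samples.itertuples(index=False):
            if g.chrom == SEX_CHROM and sex == "M":
                if g.stratum == OLD and g.y_deleted:
                    continue  # hemizygous: no het sites to count
                theta = g.theta
            else:
                theta = 0.5
            n = rng.poisson(config.rna_depth, size=config.rna_sites_per_gene)
            a = rng.binomial(n, theta)
            for p, ni, ai in zip(site_pos, n, a):
                count_rows.append((g.gene, g.chrom, int(p), sample,
                                   int(ai), int(ni - ai)))
    counts = pd.DataFrame(
        count_rows,
        columns=["gene", "chrom", "site", "sample", "count_a", "count_b"])

    base = 2.0 ** rng.normal(4.0, 1.0, size=len(truth.genes))
    expr = {}
    male_factor = np.ones(len(truth.genes))
    if not config.compensation:
        sex_linked = (truth.genes.chrom == SEX_CHROM).to_numpy()
        theta = truth.genes.theta.to_numpy()
        degenerate = sex_linked & (
            truth.genes.y_deleted.to_numpy() | (theta > 0.5))
        male_factor = np.where(degenerate, 0.5 / np.where(degenerate, theta, 1.0), 1.0)
        male_factor = np.where(sex_linked & truth.genes.y_deleted.to_numpy(),
                               0.5, male_factor)
    for sample, sex in samples.itertuples(index=False):
        level = base * (male_factor if sex == "M" else 1.0)
        noise = 2.0 ** rng.normal(0.0, config.expression_noise_sd, size=len(base))
        expr[sample] = level * noise
    expression = pd.DataFrame(expr, index=truth.genes.gene)
    expression.index.name = "gene"
    return counts, expression


# ---------------------------------------------------------------------------
# reads


def emit_reads(sequences: dict[str, str], depth: float, error_rate: float,
               seed: int, read_length: int = 100) -> list[tuple[str, str]]:
    """Uniform-coverage error-injected reads from a set of sequences.

    Returns ``(read_id, sequence)`` pairs. Read starts are evenly spaced
    (true uniform coverage: at depth >= read_length / (read_length - k + 1)
    every genomic k-mer is covered by an error-free read), strands are
    random, and substitution errors are injected at ``error_rate``.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError("error_rate must be in [0, 1)")
    rng = np.random.default_rng([int(seed), _STREAM_READS])
    comp = str.maketrans("ACGT", "TGCA")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads: list[tuple[str, str]] = []
    for name, seq in sequences.items():
        L = len(seq)
        if L < read_length:
            continue
        n_reads = int(np.ceil(depth * L / read_length))
        # two interleaved tiling passes: uniform coverage with every
        # position (termini included) hit by >= 2 reads once depth allows
        n1 = n_reads // 2
        starts = np.concatenate([
            np.round(np.linspace(0, L - read_length, max(n1, 1))),
            np.round(np.linspace(0, L - read_length, max(n_reads - n1, 1))),
        ]).astype(int)
        strands = rng.integers(0, 2, size=n_reads)
        for i, (s, rc) in enumerate(zip(starts, strands)):
            r = seq[s:s + read_length]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(read_length) < error_rate)
                if len(errs):
                    arr = np.frombuffer(r.encode(), dtype="S1").copy()
                    shift = rng.integers(1, 4, size=len(errs))
                    idx = np.searchsorted(bases, arr[errs])
                    arr[errs] = bases[(idx + shift) % 4]
                    r = arr.tobytes().decode()
            if rc:
                r = r.translate(comp)[::-1]
            reads.append((f"{name}_read{i}", r))
    return reads
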