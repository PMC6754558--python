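"""Simulator correctness: sequence structure, coverage/SNP/RNA expectations,
read emission, and determinism."""

import numpy as np
import pandas as pd
import pytest

from xyscan.simdata import (OLD, PAR, SEX_CHROM, YOUNG, ConfigError,
                            SimConfig, StratumSpec, build_truth, emit_reads,
                            simulate_dna_coverage, simulate_genomes,
                            simulate_rna, simulate_snps)


def _cfg(strata, sex_len, **kw):
    defaults = dict(seed=7, n_autosomes=1, chrom_length=100_000,
                    sex_chrom_length=sex_len, strata=strata,
                    n_genes_per_chrom=20, window_size=5_000)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_overlapping_strata_rejected(self):
        with pytest.raises(ConfigError):
            _cfg([StratumSpec(0, 60_000, PAR), StratumSpec(50_000, 100_000, PAR)],
                 100_000)

    def test_gap_in_tiling_rejected(self):
        with pytest.raises(ConfigError):
            _cfg([StratumSpec(0, 40_000, PAR), StratumSpec(50_000, 100_000, PAR)],
                 100_000)

    def test_par_with_divergence_rejected(self):
        with pytest.raises(ConfigError):
            StratumSpec(0, 10_000, PAR, xy_divergence=0.01)

    @pytest.mark.parametrize("field,value", [
        ("haploid_depth", 0.0), ("rna_depth", -1.0),
        ("polymorphism_rate", -0.1), ("n_males", 0), ("depth_dispersion", 0.0),
    ])
    def test_bad_rates_rejected(self, field, value):
        with pytest.raises(ConfigError):
            _cfg([StratumSpec(0, 100_000, PAR)], 100_000, **{field: value})


class TestGenomes:
    def test_all_par_y_identical_to_x(self):
        cfg = _cfg([StratumSpec(0, 50_000, PAR)], 50_000)
        seqs, _ = simulate_genomes(cfg)
        assert seqs["chrY"] == seqs["chrX"]

    def test_total_loss_removes_old_interval(self):
        cfg = _cfg([StratumSpec(0, 30_000, PAR),
                    StratumSpec(30_000, 50_000, OLD, y_loss=1.0)], 50_000)
        seqs, truth = simulate_genomes(cfg)
        assert truth.y_deleted_intervals == [(30_000, 50_000)]
        assert seqs["chrY"] == seqs["chrX"][:30_000]

    def test_young_divergence_matches_binomial(self):
        d, L = 0.01, 1_000_000
        cfg = _cfg([StratumSpec(0, L, YOUNG, xy_divergence=d)], L)
        seqs, _ = simulate_genomes(cfg)
        x = np.frombuffer(seqs["chrX"].encode(), dtype="S1")
        y = np.frombuffer(seqs["chrY"].encode(), dtype="S1")
        mismatches = int((x != y).sum())
        sd = np.sqrt(L * d * (1 - d))
        assert abs(mismatches - L * d) < 3 * sd

    def test_autosome_haplotypes_differ_at_polymorphism_rate(self):
        cfg = _cfg([StratumSpec(0, 5_000, PAR)], 5_000,
                   chrom_length=1_000_000, polymorphism_rate=0.002)
        seqs, _ = simulate_genomes(cfg)
        h1 = np.frombuffer(seqs["chr1_hap1"].encode(), dtype="S1")
        h2 = np.frombuffer(seqs["chr1_hap2"].encode(), dtype="S1")
        n = int((h1 != h2).sum())
        sd = np.sqrt(1e6 * 0.002)
        assert abs(n - 2000) < 4 * sd


class TestCoverage:
    def test_par_window_expectation(self):
        cfg = _cfg([StratumSpec(0, 5_000_000, PAR)], 5_000_000)
        truth = build_truth(cfg)
        cov = simulate_dna_coverage(cfg, truth)
        sex = cov[cov.chrom == SEX_CHROM].merge(cfg.samples, on="sample")
        means = sex.groupby("sex").depth.mean()
        assert means["M"] == pytest.approx(40, rel=0.02)
        assert means["F"] == pytest.approx(40, rel=0.02)

    def test_total_loss_halves_male_coverage(self):
        L = 5_000_000  # 1000 windows of 5 kb
        cfg = _cfg([StratumSpec(0, L, OLD, y_loss=1.0)], L)
        truth = build_truth(cfg)
        cov = simulate_dna_coverage(cfg, truth)
        sex = cov[cov.chrom == SEX_CHROM].merge(cfg.samples, on="sample")
        per_window = (sex.groupby(["start", "sex"]).depth.mean()
                         .unstack("sex"))
        ratio = (per_window.M / per_window.F).mean()
        assert 0.47 <= ratio <= 0.53

    def test_partial_loss_expectation(self):
        L = 5_000_000
        cfg = _cfg([StratumSpec(0, L, OLD, y_loss=0.4)], L)
        truth = build_truth(cfg)
        cov = simulate_dna_coverage(cfg, truth)
        sex = cov[cov.chrom == SEX_CHROM].merge(cfg.samples, on="sample")
        means = sex.groupby("sex").depth.mean()
        assert means["M"] / means["F"] == pytest.approx(1.6 / 2.0, abs=0.02)


@pytest.fixture(scope="module")
def thirds():
    L = 3_000_000
    cfg = _cfg([StratumSpec(0, 1_000_000, PAR),
                StratumSpec(1_000_000, 2_000_000, YOUNG,
                            xy_divergence=0.002),
                StratumSpec(2_000_000, L, OLD, xy_divergence=0.002,
                            y_loss=1.0)], L,
               chrom_length=500_000, polymorphism_rate=0.001)
    truth = build_truth(cfg)
    return cfg, truth, simulate_snps(cfg, truth)


class TestSnps:
    @staticmethod
    def _density(hets, cfg, sex, lo, hi):
        samples = set(cfg.samples.loc[cfg.samples.sex == sex, "sample"])
        sub = hets[(hets.chrom == SEX_CHROM) & hets["sample"].isin(samples)
                   & (hets.pos >= lo) & (hets.pos < hi)]
        return len(sub) / len(samples) / (hi - lo)

    def test_par_density_matches_background(self, thirds):
        cfg, _, hets = thirds
        for sex in "MF":
            den = self._density(hets, cfg, sex, 0, 1_000_000)
            assert den == pytest.approx(0.001, rel=0.15)

    def test_young_male_density_elevated_by_divergence(self, thirds):
        cfg, _, hets = thirds
        male = self._density(hets, cfg, "M", 1_000_000, 2_000_000)
        female = self._density(hets, cfg, "F", 1_000_000, 2_000_000)
        assert male == pytest.approx(0.003, rel=0.1)
        assert female == pytest.approx(0.001, rel=0.15)

    def test_old_total_loss_removes_male_heterozygosity(self, thirds):
        cfg, truth, hets = thirds
        assert truth.y_deleted_intervals == [(2_000_000, 3_000_000)]
        assert self._density(hets, cfg, "M", 2_000_000, 3_000_000) == 0.0
        female = self._density(hets, cfg, "F", 2_000_000, 3_000_000)
        assert female == pytest.approx(0.001, rel=0.15)


class TestRna:
    def test_balanced_gene_fraction_near_half(self, small_config, small_truth):
        counts, _ = simulate_rna(small_config, small_truth)
        auto = counts[counts.chrom != SEX_CHROM]
        frac = auto.count_a.sum() / (auto.count_a.sum() + auto.count_b.sum())
        n = auto.count_a.sum() + auto.count_b.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_silenced_genes_have_no_callable_male_het_sites(
            self, small_config, small_truth):
        from xyscan.ase import call_het_sites
        counts, _ = simulate_rna(small_config, small_truth)
        males = set(small_config.samples.loc[
            small_config.samples.sex == "M", "sample"])
        called = call_het_sites(counts[counts["sample"].isin(males)])
        assert small_truth.y_silenced_genes  # regime exercised
        assert not (set(called.gene) & small_truth.y_silenced_genes)

    def test_deleted_genes_emit_no_male_sites(self, small_config, small_truth):
        counts, _ = simulate_rna(small_config, small_truth)
        males = set(small_config.samples.loc[
            small_config.samples.sex == "M", "sample"])
        male_counts = counts[counts["sample"].isin(males)]
        assert not (set(male_counts.gene) & small_truth.y_deleted_genes)

    def test_uncompensated_degenerate_expression_halved(self):
        L = 3_000_000
        cfg = _cfg([StratumSpec(0, L, OLD, xy_divergence=0.002, y_loss=1.0)],
                   L, n_genes_per_chrom=200, compensation=False)
        truth = build_truth(cfg)
        _, expr = simulate_rna(cfg, truth)
        sex_map = cfg.samples
        m = expr[sex_map.loc[sex_map.sex == "M", "sample"]].mean(axis=1)
        f = expr[sex_map.loc[sex_map.sex == "F", "sample"]].mean(axis=1)
        x_genes = truth.genes.loc[truth.genes.chrom == SEX_CHROM, "gene"]
        med = (m[x_genes] / f[x_genes]).median()
        assert med == pytest.approx(0.5, abs=0.07)

    def test_compensation_restores_male_level(self):
        cfg = SimConfig(seed=11, chrom_length=2_000_000,
                        sex_chrom_length=3_000_000, n_genes_per_chrom=60,
                        compensation=True)
        truth = build_truth(cfg)
        _, expr = simulate_rna(cfg, truth)
        sm = cfg.samples
        m = expr[sm.loc[sm.sex == "M", "sample"]].mean(axis=1)
        f = expr[sm.loc[sm.sex == "F", "sample"]].mean(axis=1)
        deleted = list(truth.y_deleted_genes)
        assert np.median(np.log2(m[deleted] / f[deleted])) == pytest.approx(
            0.0, abs=0.2)


GENOME_LEN = 10_000


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(3)
    return {"toy": "".join(rng.choice(list("ACGT"), GENOME_LEN))}


class TestReads:
    def test_deterministic_given_seed(self, genome):
        r1 = emit_reads(genome, depth=5, error_rate=0.0, seed=4)
        r2 = emit_reads(genome, depth=5, error_rate=0.0, seed=4)
        assert r1 == r2
        r3 = emit_reads(genome, depth=5, error_rate=0.0, seed=5)
        assert r1 != r3

    def test_every_genomic_kmer_recovered_at_depth_30(self, genome):
        from xyscan.kmers import count_kmers, iter_kmers
        reads = emit_reads(genome, depth=30, error_rate=0.0, seed=4)
        observed = count_kmers([seq for _, seq in reads], k=31, min_count=1)
        genomic = set(iter_kmers(genome["toy"], 31))
        assert genomic <= observed.kmers

    def test_total_bases_near_target_depth(self, genome):
        reads = emit_reads(genome, depth=30, error_rate=0.0, seed=4)
        total = sum(len(seq) for _, seq in reads)
        assert abs(total - 30 * GENOME_LEN) / (30 * GENOME_LEN) < 0.05

    def test_error_rate_injects_mismatches(self, genome):
        clean = dict(emit_reads(genome, depth=3, error_rate=0.0, seed=4))
        noisy = dict(emit_reads(genome, depth=3, error_rate=0.05, seed=4))
        diffs = sum(a != b
                    for rid in clean
                    for a, b in zip(clean[rid], noisy[rid]))
        total = sum(len(s) for s in clean.values())
        assert diffs / total == pytest.approx(0.05, rel=0.25)

    def test_invalid_depth_rejected(self, genome):
        with pytest.raises(ConfigError):
            emit_reads(genome, depth=0, error_rate=0.0, seed=1)


class TestDeterminism:
    def test_all_outputs_reproducible(self, small_config, small_truth):
        cov1 = simulate_dna_coverage(small_config, small_truth)
        cov2 = simulate_dna_coverage(small_config, small_truth)
        pd.testing.assert_frame_equal(cov1, cov2)
        c1, e1 = simulate_rna(small_config, small_truth)
        c2, e2 = simulate_rna(small_config, small_truth)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)
        t2 = build_truth(small_config)
        pd.testing.assert_frame_equal(small_truth.genes, t2.genes)
        assert np.array_equal(small_truth.xy_divergent_sites,
                              t2.xy_divergent_sites)

    def test_window_labels_tile_sex_chromosome(self, small_config, small_truth):
        labels = small_truth.sex_window_labels
        assert labels.start.iloc[0] == 0
        assert labels.end.iloc[-1] == small_config.sex_chrom_length
        assert (labels.start.iloc[1:].to_numpy()
                == labels.end.iloc[:-1].to_numpy()).all()
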