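# Simulation configuration template for `xyscan simulate --config ...`.
# Any field omitted falls back to the package default shown here.

seed: 0                    # master seed; every output is deterministic in it
n_autosomes: 2             # autosomes provide the null for normalization/bootstraps
chrom_length: 5000000      # autosome length (bp)
sex_chrom_length: 15000000 # sex chromosome length (bp)

# Strata must tile [0, sex_chrom_length) without gaps or overlaps.
# kind: PAR (recombining), young (intact diverged Y), old (degenerate Y).
# xy_divergence: fixed X-Y differences per bp (young/old).
# y_loss: fraction of the Y copy deleted (old only).
# y_silenced_fraction: fraction of surviving Y gene copies silenced (old only).
strata:
  - {start: 0,        end: 5000000,  kind: PAR}
  - {start: 5000000,  end: 10000000, kind: young, xy_divergence: 0.005}
  - {start: 10000000, end: 15000000, kind: old, xy_divergence: 0.005,
     y_loss: 0.9, y_silenced_fraction: 0.5}

haploid_depth: 20.0        # mean depth per chromosome copy (diploid mean = 2x)
depth_dispersion: 10.0     # negative-binomial size for window read counts
polymorphism_rate: 0.001   # heterozygous sites per bp per individual
n_males: 3
n_females: 3

n_genes_per_chrom: 120     # genes placed uniformly per chromosome
gene_length: 1000          # bp
rna_depth: 40.0            # mean RNA reads per heterozygous site
rna_sites_per_gene: 5
ase_fraction: 0.8          # surviving active Y genes with partial imbalance
ase_theta: 0.8             # X-allele transcription fraction of those genes
expression_noise_sd: 0.25  # per-replicate lognormal noise, log2 units
compensation: false        # chromosome-wide dosage compensation on/off

kmer_error_rate: 0.0       # substitution error rate for emitted reads
read_length: 100
window_size: 50000         # window tiling used by coverage simulation
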