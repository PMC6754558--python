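# Methods

This note documents the models and procedures implemented in `xyscan`, the
choices behind their defaults, what the synthetic-data generator does and
does not emulate, and the known limitations.

## 1. The data-generating model (`xyscan.simdata`)

The simulator emits the downstream products a mapping pipeline would
produce for a sexed resequencing + RNA-seq study of an XY system, at the
level of summary tables rather than reads (reads are emitted only for the
k-mer analysis). The sex chromosome is tiled by strata, each with a
recombination history:

| stratum | Y copy | male coverage factor | male het density |
|---|---|---|---|
| PAR / undifferentiated | identical to X | 2λ (X+Y co-map) | π |
| young | intact, diverged at density *d* | 2λ | π + d |
| old, degenerate | fraction *y_loss* deleted; of survivors, *y_silenced_fraction* transcriptionally silent | λ·(2 − y_loss) | ≈ 0 over deleted intervals, π + d elsewhere |

**Coverage.** Per-window read totals are Gamma–Poisson (negative binomial)
with mean `depth × window length` and dispersion (size) `depth_dispersion`.
Defaults: haploid depth λ = 20 (autosomal diploid depth 40, the order of
magnitude of a well-powered resequencing study), dispersion 10 (per-window
CV ≈ 0.32 — deliberately noisy, so the bootstrap null is stressed rather
than flattered). Female window means are 2λ everywhere; the male factor
follows the table. The published studies report only fold-coverage totals,
so λ, the dispersion, and π below are package parameters chosen for test
power at desk scale and documented here once.

**Heterozygous sites.** Each individual carries background heterozygosity
at rate π = 0.001/bp (a typical vertebrate-scale value) on every
chromosome. Males are additionally heterozygous at every fixed X–Y
difference outside deleted intervals — the young-stratum signature — and
lose *all* heterozygosity over deleted intervals (one X, nothing to be
heterozygous against). X–Y fixed differences are placed binomially at
density d (default 0.005/bp in nonrecombining strata). Sites are written as
a multi-sample VCF 4.2 with GT/DP/GQ.

**Sequence level vs window level.** `simulate_genomes` deletes one
contiguous block covering `y_loss` of each old stratum from the Y
haplotype, while `simulate_dna_coverage` applies the male factor
`2 − y_loss` uniformly across the stratum's windows. The two outputs are
separate artifacts (sequences feed the k-mer module; the depth table feeds
the scan) and are not required to be base-compatible; the SNP table uses
the explicit deleted block.

**RNA.** For each gene the generator draws `rna_sites_per_gene` (default 5)
heterozygous sites; per site, read depth is Poisson(`rna_depth` = 40) and
the X-allele count Binomial(n, θ) with θ the gene's X-allele transcription
fraction: 0.5 for balanced genes, `ase_theta` = 0.8 for partially
imbalanced survivors (a fraction `ase_fraction` = 0.8 of surviving,
non-silenced old-stratum genes), and 1.0 for genes with a silent Y copy —
which therefore never yield a *callable* het site, matching the behavior of
het-calling from RNA. Genes whose Y copy is deleted produce no male sites
at all. Expression is a per-gene lognormal baseline (2^N(4,1), so a
TPM-like scale with median ≈ 16) shared by the sexes, times lognormal noise
(σ = 0.25 log2 units per replicate); without compensation the male level of
a sex-linked gene is scaled by `0.5/θ` (0.5 for deleted or silent Y,
intermediate for partial ASE), with compensation it equals the female
level. Gene placement is uniform at random with a fixed count per
chromosome; all fates are recorded in `SimTruth`.

**Reads.** `emit_reads` tiles each sequence with evenly spaced read starts
in two interleaved passes (uniform coverage; every genomic k-mer is covered
by ≥ 2 error-free reads once depth permits), random strand, substitution
errors at `kmer_error_rate`. This is deliberately idealized: no indels,
quality values constant.

Every operation derives its RNG from `(seed, operation id)`, so outputs are
byte-identical across runs and independent of call order.

What the generator does **not** emulate: mapping bias and mapping-quality
loss (young-stratum Y reads are assumed to co-map to the X perfectly —
mapping loss enters only through `y_loss`), indels and structural noise,
population-level variation in the divergent sites (fixed differences are
shared by all males), linkage, selection, and GC or repeat structure.
Passing tests therefore demonstrate correctness of the inference given the
model's idealizations, not robustness to alignment artifacts in real data.

## 2. Window scan and the bootstrap null (`winstats`)

Depth tables of arbitrary granularity (per-base to bedGraph runs) are
aggregated to non-overlapping windows by overlap-weighted means; windows
with no covered bases are missing, not zero. Each sample is rescaled so its
autosomal median window depth is 1 — sequencing-effort differences
otherwise mimic sex linkage — and the per-sex value of a window is the mean
over individuals of that sex. The 50 kb default window balances resolution
against per-window counting noise at the default depths; the moving-average
span of 11 windows (550 kb) is small relative to the Mb scale of strata.

The null envelope is a percentile bootstrap over autosomal windows: each
replicate resamples the windows with replacement and records the
`(1−level)/2` and `1−(1−level)/2` percentiles of the resampled values; the
reported bounds are the means over replicates. This is an envelope for the
*per-window statistic*, so about `level` of fresh null windows fall inside
it — the property the calibration tests measure. Because the classifier
thresholds *smoothed* tracks, the pipeline builds the envelope from
smoothed autosomal windows (smoothing applied within each autosome): the
null and the tested statistic must be constructed identically, otherwise
the envelope is far too wide for the smoothed track and old strata with
moderate `y_loss` (log2 ratio ≈ −0.86 at y_loss = 0.9) sit inside it.

Zero-coverage windows are excluded from ratios and from the bootstrap
rather than imputed (avoids −∞). SNP-density inputs pass through
configurable variant filters (biallelic SNVs, DP ≥ 10, GQ ≥ 20 — standard
hard filters). The statistic orientation is heterogametic-over-homogametic;
a ZW flag swaps the sex labels so the same machinery scans ZW candidates.

## 3. Stratum classification (`strata`)

Coverage takes precedence: a window below the coverage envelope is
`OLD_DEGENERATE` regardless of its SNP signal (degeneration also perturbs
SNP density — depressed male density co-occurring with the coverage deficit
is recorded as corroboration, not used as a separate trigger). Otherwise
SNP excess gives `YOUNG`, else `UNDIFF_PAR`.

Merging absorbs label runs shorter than `min_run` into their flanks. The
default is 13 windows, just above the smoothing span: a false excursion of
a span-11 moving average persists for up to ~11 windows, so a smaller
threshold (say 5) regularly promotes smoother-scale noise into calls on a
1000-window chromosome, while real strata are tens of windows long.
Because smoothing also drags apparent boundaries by up to half a span, each
merged boundary is refined by a least-squares single-changepoint fit on the
*raw* statistic that separates the two flanking labels (coverage when an
old stratum is involved, SNP difference otherwise), within ±8 windows. On
the default simulated chromosome this recovers boundaries to within one to
two windows.

Known limitation: a young stratum much shorter than ~2 smoothing spans and
adjacent to an old stratum can be partially annexed by the old call (the
coverage signal bleeds across the boundary before refinement); the
reticulata-like analysis shows this regime. No formal changepoint model
(HMM/segmentation) is attempted, and old strata are not subdivided by age.

## 4. K-mers (`kmers`)

Canonical (strand-collapsed, lexicographic-minimum) k-mers with odd k in
[11, 63]; default k = 31, min multiplicity 2 to suppress sequencing errors.
"Sex-specific" uses the strictest rule: present in the intersection of all
samples of one sex and absent from the union of the other. Counting is
in-memory hashed sets, correct by construction at desk scale (≤ ~10⁷
distinct k-mers); it makes no attempt at probabilistic or disk-backed
counting for full genomes. The female-unique : Y-mer burden ratio is
flagged as a Y-loss signature above 1.5 (the empirically motivated regime
is ≈ 2); a zero Y-mer count reports an infinite ratio with the flag rather
than raising.

## 5. Allele-specific expression (`ase`)

Het-site calling keeps sites with total depth ≥ 10 and minor count ≥ 2 —
a site with all reads on one allele looks hemizygous, not heterozygous.
Counts are pooled per gene **in the orientation of the input table** (the
A allele is consistent within a gene) and folded to the major allele once,
at the gene level. Folding each site separately would inflate the null:
with 5 sites of depth ~40, per-site folding pushes the median "major
allele frequency" of perfectly balanced genes to ≈ 0.56 and the binomial
test's type-I error to ≈ 0.3, whereas the gene-level fold leaves the test
exactly calibrated (the two-sided binomial p at 0.5 is symmetric in
k ↔ n−k) and the median frequency at ≈ 0.53 — the inflation is pure
sampling and is quantified by the calibration tests. The cost is that
opposite-direction imbalance at different sites of one gene cancels; with
unphased data this is the conservative direction.

The ASE test is an exact two-sided binomial test of the pooled counts
against 0.5, BH-corrected per sample group, `is_ase` at q < 0.05. The
sex-chromosome enrichment χ² (df = 1, no continuity correction) defaults to
the site-level 2×2 table (sites inherit their gene's call), with gene-level
pairs accepted too. Rank-sum comparisons use exact p-values for group sizes
≤ 50 without ties, midrank/normal approximation otherwise.

## 6. Dosage compensation (`dosage`)

Expression is expected library-normalized upstream (TPM-like); the module
only equalizes sample medians, computing the scaling from **autosomal**
genes. Scaling on all genes is wrong in exactly the situation of interest:
when a large sex-linked fraction is halved in males, a whole-matrix median
drags male scale factors up and shrinks a true −1 log2 deficit toward −0.6.

Contrasts: paired Wilcoxon signed-rank of per-gene male vs female means on
the degenerate X; Wilcoxon rank-sum of X vs autosomal per-gene means within
males; rank-sum of per-gene M:F log2 ratios for ASE X genes vs autosomal
genes. The tested X gene set is the genes under `OLD_DEGENERATE` calls:
young-stratum genes still have two active copies and only dilute the dose
signal. The verdict rule: `COMPLETE` if both primary tests are
non-significant at α = 0.01 *and* the median X M:F log2 ratio is within
±0.25 of 0; `ABSENT` if both are significant and the median is at or below
−0.75; `PARTIAL` otherwise; `NOT_APPLICABLE` without a degenerate stratum
(or fewer than 6 testable X genes). The ±0.25 tolerance separates the
compensated (≈ 0) from the uncompensated (≈ −1) regime with margin. α =
0.01 rather than 0.05 because the verdict combines two tests whose false
positives would otherwise misclassify ~10% of genuinely compensated
datasets; with hundreds of genes the power loss against a true halving is
nil. With ~3 replicates per sex the per-gene means share each sample's
normalization error, so the paired test can react to sample-level noise;
this is a real limitation of small designs, visible as occasional `PARTIAL`
verdicts on compensated truth (2/20 replicates at defaults).

Sex-bias classes use |log2 M/F| ≥ 1 and per-gene rank-sum q < 0.05. Note
the exact rank-sum cannot reach significance below ~5 replicates per sex
(the smallest p at 3v3 is 0.1); the class machinery is meaningful only for
designs with enough replication.

## 7. Problem sizes

Tests and the acceptance script run everything at desk scale chosen for
statistical resolution: 600–1000 windows of 50 kb per scanned chromosome,
2000–4000 autosomal null windows, 500–2000 genes for calibration, 20
replicate seeds for verdict recovery, and ≤ 100 kb genomes for exhaustive
k-mer enumeration checks. These sizes give Monte-Carlo error well inside
every asserted tolerance while the full suite completes in about a minute.
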