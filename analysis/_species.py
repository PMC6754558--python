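"""Shared desk-scale study designs for the numbered analysis scripts.

Three XY systems spanning the observed range of sex-chromosome
differentiation, all sharing one ancestral chromosome 'plan':

* ``reticulata``-like — largely recombining: big PAR, short young stratum,
  small old stratum.
* ``wingei``-like — nonrecombining along most of the chromosome: large
  young stratum plus the shared old stratum.
* ``picta``-like — fully degenerate: the whole chromosome old and
  Y-depleted except a limited far-end PAR, with chromosome-wide dosage
  compensation.

Chromosome sizes are scaled down (13 Mb sex chromosome, two 10 Mb
autosomes) so every script runs in seconds while keeping hundreds of
windows per chromosome.
"""

from pathlib import Path

from xyscan.simdata import picta_like, reticulata_like, wingei_like

SIM_ROOT = Path("scratch/sims")
RESULTS = Path("results")

SEED = 2024


def species_configs():
    kw = dict(length=13_000_000, chrom_length=10_000_000,
              n_genes_per_chrom=240, seed=SEED)
    return {
        "reticulata": reticulata_like(**kw),
        "wingei": wingei_like(**{**kw, "seed": SEED + 1}),
        "picta": picta_like(**{**kw, "seed": SEED + 2}),  # compensated
    }


def sim_dir(species: str) -> Path:
    return SIM_ROOT / species
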