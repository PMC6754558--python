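"""Sex-specific k-mer (Y-mer) analysis within and across species.

Builds three species' worth of sexed read sets from small synthetic
genomes that share an ancestral Y-specific sequence: two species carry the
intact ancestral Y block plus species-specific Y sequence, while the
picta-like species retains only a small remnant of it (large-scale Y
loss). Females carry two X haplotypes; males are X-hemizygous for one of
them. Counts male-unique (Y-mer) and female-unique k-mers per species, the
cross-species Venn partition of Y-mers, and the female:male specific-k-mer
burden ratio whose excess over 1 flags Y loss.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd
from _species import RESULTS, SIM_ROOT

from xyscan import pipeline
from xyscan import io as xio
from xyscan.kmers import compare_sex_specific_burden, cross_species_shared
from xyscan.simdata import emit_reads

K = 31
SEED = 77


def build_genomes(rng):
    x_a = "".join(rng.choice(list("ACGT"), 20_000))
    # second X haplotype segregating in the population: 1% divergence
    arr = np.array(list(x_a))
    sites = rng.choice(len(arr), 200, replace=False)
    for i in sites:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    x_b = "".join(arr)
    anc_y = "".join(rng.choice(list("ACGT"), 5_000))  # ancestral Y-specific
    genomes = {}
    for sp, y_anc_kept, y_private in (("reticulata", 5_000, 3_000),
                                      ("wingei", 5_000, 3_000),
                                      ("picta", 500, 300)):
        y = anc_y[:y_anc_kept] + "".join(rng.choice(list("ACGT"), y_private))
        genomes[sp] = {"male": x_a + "N" + y, "female": x_a + "N" + x_b}
    return genomes


def main():
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    genomes = build_genomes(rng)
    rows, y_mer_sets = [], {}
    for sp, g in genomes.items():
        d = SIM_ROOT / "kmers" / sp
        d.mkdir(parents=True, exist_ok=True)
        files = {}
        for i, sex in enumerate(["M", "M", "F", "F"]):
            sample = f"{sex}{i % 2 + 1}"
            path = d / f"{sample}.fastq"
            reads = emit_reads({"g": g["male" if sex == "M" else "female"]},
                               depth=10, error_rate=0.0,
                               seed=SEED * 100 + len(rows) * 10 + i)
            xio.write_fastq(reads, path)
            files[sample] = (sex, path)
        res = pipeline.run_kmers(files, k=K, min_count=2, species=sp,
                                 outdir=d)
        ratio, flag = compare_sex_specific_burden(res)
        y_mer_sets[sp] = res.y_mers
        rows.append({"species": sp, "y_mers": res.n_y_mers,
                     "female_unique": res.n_female_unique,
                     "female_to_male_ratio": round(ratio, 2),
                     "y_loss_signature": flag})
        print(f"{sp}: {res.n_y_mers} Y-mers, {res.n_female_unique} "
              f"female-unique (F:M = {ratio:.2f}"
              f"{', Y-loss signature' if flag else ''})")

    venn = cross_species_shared(y_mer_sets)
    print("\nShared Y-mers (Venn partition):")
    venn_rows = []
    for subset, count in sorted(venn.items(), key=lambda kv: (-len(kv[0]),
                                                              kv[0])):
        print(f"  {'+'.join(subset):35s} {count}")
        venn_rows.append({"species_subset": "+".join(subset), "count": count})

    pd.DataFrame(rows).to_csv(RESULTS / "kmer_counts.tsv", sep="\t",
                              index=False)
    pd.DataFrame(venn_rows).to_csv(RESULTS / "kmer_venn.tsv", sep="\t",
                                   index=False)
    print(f"\nwrote {RESULTS / 'kmer_counts.tsv'} and "
          f"{RESULTS / 'kmer_venn.tsv'}")


if __name__ == "__main__":
    main()
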