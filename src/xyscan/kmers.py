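"""Sex-specific k-mer ("Y-mer") analysis.

A Y-mer is a canonical k-mer present in every male sample and absent from
every female sample of a species: in an XY system such k-mers mark
Y-specific sequence. The converse, female-unique k-mers, mark X sequence
diverged or lost on the X-bearing reads of males; an excess of female-unique
over male-unique k-mers is the signature of large-scale Y loss. Sets are
compared across species as a Venn partition to ask whether the Y (or its
remnants) is shared.

Counting is in-memory hashed sets over canonical (strand-collapsed) k-mers,
intended for desk-scale inputs (up to ~1e7 distinct k-mers), with a minimum
multiplicity filter to suppress sequencing errors.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from . import io as xio

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class KmerParameterError(ValueError):
    pass


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerSet:
    """Canonical k-mers of one sample passing a min-count filter."""

    sample: str
    sex: str
    k: int
    kmers: frozenset[str]
    min_count: int = 1

    @property
    def total_distinct(self) -> int:
        return len(self.kmers)


@dataclass
class SexSpecificResult:
    """Male-unique (Y-mer) and female-unique k-mer sets of one species."""

    species: str
    k: int
    y_mers: frozenset[str]
    female_unique: frozenset[str]

    def __post_init__(self) -> None:
        if self.y_mers & self.female_unique:
            raise ValueError("y_mers and female_unique must be disjoint")

    @property
    def n_y_mers(self) -> int:
        return len(self.y_mers)

    @property
    def n_female_unique(self) -> int:
        return len(self.female_unique)


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise KmerParameterError("k must be odd (unambiguous canonicalization)")
    if not 11 <= k <= 63:
        raise KmerParameterError("k must be in [11, 63]")


def iter_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of one sequence; k-mers with ambiguous bases skipped."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= _VALID:
            yield canonical(kmer)


def count_kmers(sequences: Iterable[str] | str | Path, k: int = 31,
                min_count: int = 2, sample: str = "", sex: str = "") -> KmerSet:
    """Count canonical k-mers from sequences or a FASTA/FASTQ path.

    Retains k-mers with multiplicity >= ``min_count`` (multiplicity is
    summed over canonical form, i.e. over both strands).
    """
    _check_k(k)
    if isinstance(sequences, (str, Path)):
        sequences = xio.iter_sequences(sequences)
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(iter_kmers(seq, k))
    kept = frozenset(km for km, c in counts.items() if c >= min_count)
    return KmerSet(sample=sample, sex=sex, k=k, kmers=kept, min_count=min_count)


def sex_specific(male_sets: list[KmerSet], female_sets: list[KmerSet],
                 species: str = "") -> SexSpecificResult:
    """Strict sex-specific sets: present in *every* sample of one sex and
    absent from *every* sample of the other.

    ``y_mers = intersection(males) - union(females)``;
    ``female_unique = intersection(females) - union(males)``.
    """
    if not male_sets or not female_sets:
        raise ValueError("need at least one k-mer set per sex")
    ks = {s.k for s in male_sets} | {s.k for s in female_sets}
    if len(ks) != 1:
        raise KmerParameterError(f"mixed k across samples: {sorted(ks)}")
    k = ks.pop()
    male_core = frozenset.intersection(*(s.kmers for s in male_sets))
    female_core = frozenset.intersection(*(s.kmers for s in female_sets))
    male_any = frozenset.union(*(s.kmers for s in male_sets))
    female_any = frozenset.union(*(s.kmers for s in female_sets))
    return SexSpecificResult(species=species, k=k,
                             y_mers=male_core - female_any,
                             female_unique=female_core - male_any)


def cross_species_shared(sets_by_species: dict[str, frozenset[str] | set[str]]
                         ) -> dict[tuple[str, ...], int]:
    """Venn partition of sex-specific k-mer sets across species.

    For every non-empty subset S of species, the count of k-mers present in
    exactly the species of S. Counts sum to the size of the union.
    """
    if len(sets_by_species) < 2:
        raise ValueError("need at least 2 species")
    species = sorted(sets_by_species)
    partition: dict[tuple[str, ...], int] = {}
    for r in range(1, len(species) + 1):
        for subset in itertools.combinations(species, r):
            inside = frozenset.intersection(
                *(frozenset(sets_by_species[s]) for s in subset))
            outside = frozenset().union(
                *(frozenset(sets_by_species[s])
                  for s in species if s not in subset))
            partition[subset] = len(inside - outside)
    return partition


def compare_sex_specific_burden(result: SexSpecificResult,
                                threshold: float = 1.5
                                ) -> tuple[float, bool]:
    """Female-unique : Y-mer count ratio and a Y-loss flag.

    A ratio well above 1 (around 2 in a heavily Y-depleted system) indicates that
    much of the Y is missing: males then lack Y-mers for regions where the
    X still carries divergent, female-detectable sequence. A zero Y-mer
    count yields an infinite ratio (flagged), not an exception.
    """
    if result.n_y_mers == 0:
        return float("inf"), True
    ratio = result.n_female_unique / result.n_y_mers
    return ratio, ratio > threshold
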