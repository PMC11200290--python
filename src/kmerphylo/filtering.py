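"""Detection and removal of k-mers that stem from missing regions.

A k-mer present in one species but absent from another may be absent
because of a handful of substitutions or small indels, or because the
whole region is missing from that species (incomplete assembly, large
deletion). The two cases are distinguished *without alignment* by
looking at the k-mer's substrings of a smaller length k: after a few
point changes most substrings still occur somewhere in the species,
whereas a missing region takes out long runs of substrings together.

For each candidate k-mer (present in >= 1 species, absent from >= 1)
and each species where it is absent, the number of its m = K - k + 1
length-k substrings whose canonical form is absent from that species'
substring table is counted. If that number strictly exceeds m / Th for
some species, the k-mer is attributed to a missing region and discarded
from every species' table before distance construction; otherwise it is
retained. Th is defined as (total substrings) / (missing substrings),
with default Th = 2, i.e. discard when more than half the substrings
are missing.

Substring presence is tested against the species' full k-length table,
not just near the locus — the method stays alignment-free. This is also
why very short substrings (k < 7) are unreliable: they reappear by
chance elsewhere in the genome and mask true missing regions, hence the
floor in :func:`substring_length`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .kmers import KmerCountTable, canonical
from .seqio import GAP, AlignmentBlock

__all__ = [
    "FilterConfig",
    "FilterReport",
    "substring_length",
    "candidate_kmers",
    "missing_substring_count",
    "filter_kmers",
    "label_by_alignment",
    "sensitivity_specificity",
]


def substring_length(K: int) -> int:
    """Default substring length k = max(K - floor(K/5), 7).

    Empirically, substrings about 20% shorter than K discriminate well,
    but below 7 bases chance occurrences elsewhere in the sequence make
    the absence signal unreliable, hence the floor.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    return max(K - K // 5, 7)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the missing-region filter.

    Attributes
    ----------
    K : int
        Length of the k-mers used for phylogeny estimation.
    k : int
        Substring length; defaults to ``substring_length(K)``.
    Th : float
        Threshold ratio total-substrings / missing-substrings. A
        candidate is discarded when its missing-substring count in some
        species strictly exceeds m / Th. Default 2.
    """

    K: int
    k: int = None  # type: ignore[assignment]
    Th: float = 2.0

    def __post_init__(self) -> None:
        if self.k is None:
            object.__setattr__(self, "k", substring_length(self.K))
        if self.k >= self.K:
            raise ValueError(
                f"substring length k={self.k} must be strictly smaller than K={self.K}"
            )
        if self.k < 1:
            raise ValueError(f"substring length must be >= 1, got {self.k}")
        if self.Th <= 0:
            raise ValueError(f"threshold Th must be positive, got {self.Th}")

    @property
    def m(self) -> int:
        """Number of length-k substrings of a length-K k-mer."""
        return self.K - self.k + 1


@dataclass
class FilterReport:
    """Keep/discard decisions for every candidate k-mer."""

    config: FilterConfig
    candidates: set[str] = field(default_factory=set)
    discarded: set[str] = field(default_factory=set)
    # per candidate: species with the highest missing-substring count
    worst_species: dict[str, str] = field(default_factory=dict)
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def kept(self) -> set[str]:
        return self.candidates - self.discarded

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "kmer": kmer,
                "status": "discarded" if kmer in self.discarded else "kept",
                "worst_species": self.worst_species.get(kmer, ""),
                "missing_count": self.missing_counts.get(kmer, 0),
                "m": self.config.m,
            }
            for kmer in sorted(self.candidates)
        ]
        return pd.DataFrame(
            rows, columns=["kmer", "status", "worst_species", "missing_count", "m"]
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def candidate_kmers(tables: KmerCountTable) -> set[str]:
    """k-mers present in at least one species and absent from at least one.

    Only these can carry a missing-region signal; k-mers present in all
    species are never examined or discarded.
    """
    if len(tables.counts) < 2:
        raise ValueError("candidate detection requires at least 2 species")
    return tables.union_kmers() - tables.intersection_kmers()


def missing_substring_count(
    kmer: str, species_substrings: Mapping[str, int] | set, k: int
) -> int:
    """How many of the k-mer's length-k substrings are absent in a species.

    ``species_substrings`` is that species' canonical count table (or
    key set) at substring length ``k``. Returns a value in [0, m] with
    m = len(kmer) - k + 1.
    """
    if k >= len(kmer):
        raise ValueError(f"substring length {k} must be < k-mer length {len(kmer)}")
    return sum(
        1
        for i in range(len(kmer) - k + 1)
        if canonical(kmer[i : i + k]) not in species_substrings
    )


def filter_kmers(
    tables: KmerCountTable,
    substring_tables: KmerCountTable,
    config: FilterConfig,
) -> tuple[KmerCountTable, FilterReport]:
    """Remove k-mers attributed to missing regions from all species.

    ``substring_tables`` must be counted from the same sequences at
    length ``config.k``. A candidate flagged in any species is removed
    from every species' table so that all pairwise distances are
    computed over a consistent k-mer vocabulary; retained k-mers keep
    their original counts.
    """
    if tables.K != config.K:
        raise ValueError(f"tables at K={tables.K} but config.K={config.K}")
    if substring_tables.K != config.k:
        raise ValueError(
            f"substring tables at K={substring_tables.K} but config.k={config.k}"
        )
    if set(tables.counts) != set(substring_tables.counts):
        raise ValueError("tables and substring_tables cover different species")

    report = FilterReport(config=config)
    report.candidates = candidate_kmers(tables)
    cutoff = config.m / config.Th
    for kmer in report.candidates:
        worst_sp, worst = "", -1
        for sp, counts in tables.counts.items():
            if kmer in counts:
                continue
            missing = missing_substring_count(kmer, substring_tables.counts[sp], config.k)
            if missing > worst:
                worst_sp, worst = sp, missing
        report.worst_species[kmer] = worst_sp
        report.missing_counts[kmer] = worst
        if worst > cutoff:  # strict: ties (e.g. exactly m/2 at Th=2) are kept
            report.discarded.add(kmer)

    filtered_counts = {
        sp: {kmer: c for kmer, c in counts.items() if kmer not in report.discarded}
        for sp, counts in tables.counts.items()
    }
    filtered = replace(tables, counts=filtered_counts, lengths=dict(tables.lengths))
    return filtered, report


def label_by_alignment(
    alignment: AlignmentBlock, K: int, species: list[str] | None = None
) -> dict[str, set[str]]:
    """Ground-truth "missing" labels for k-mers from an MSA.

    For every occurrence of a k-mer in a species A, its K ungapped
    positions are mapped to alignment columns; for every other species
    B the gap characters of B in those columns are counted. If the gap
    count strictly exceeds K/3 for some occurrence, the (k-mer, B) pair
    is labelled as missing-region; otherwise the absence (if any) is
    attributed to substitutions/indels.

    Returns a map canonical k-mer -> set of species labelled missing
    for it (k-mers never labelled for any species map to empty sets
    only if encountered; absent keys mean "not missing anywhere").
    """
    if species is None:
        species = alignment.species
    gap_flags = {
        sp: np.frombuffer(alignment.rows[sp].encode(), dtype=np.uint8) == ord(GAP)
        for sp in species
    }
    labels: dict[str, set[str]] = {}
    threshold = K / 3.0
    for sp_a in species:
        row = alignment.rows[sp_a]
        cols = np.array([j for j, ch in enumerate(row) if ch != GAP], dtype=np.int64)
        seq = alignment.ungapped(sp_a)
        for i in range(len(seq) - K + 1):
            window = seq[i : i + K]
            if any(ch not in "ACGT" for ch in window):
                continue
            span = cols[i : i + K]
            kmer = canonical(window)
            for sp_b in species:
                if sp_b == sp_a:
                    continue
                gaps = int(gap_flags[sp_b][span].sum())
                if gaps > threshold:
                    labels.setdefault(kmer, set()).add(sp_b)
    return labels


def sensitivity_specificity(
    labels: dict[str, set[str]], report: FilterReport
) -> tuple[float, float]:
    """Score the filter against ground-truth labels, in percent.

    A k-mer counts as labelled-missing if it is labelled missing for at
    least one species. Sensitivity is the fraction of labelled-missing
    candidates that were discarded; specificity the fraction of
    labelled-not-missing candidates that were kept. Returns (0, 100)
    conventionally when a denominator is empty.
    """
    missing = {k for k, sps in labels.items() if sps} & report.candidates
    not_missing = report.candidates - missing
    sens = 100.0 * len(missing & report.discarded) / len(missing) if missing else 0.0
    spec = (
        100.0 * len(not_missing - report.discarded) / len(not_missing)
        if not_missing
        else 100.0
    )
    return sens, spec
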