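"""Canonical k-mer counting.

DNA sequences may come from either strand, so a k-mer and its reverse
complement are the same observation. Counts are therefore aggregated
under the *canonical* form: the lexicographically smaller of the k-mer
and its reverse complement (e.g. ``TCGAC`` is stored under ``GTCGA``).

Tables are sparse maps from canonical k-mer to count; a dense 4**K
vector is never materialised, which keeps long k-mer lengths feasible.
All distance computations downstream iterate over key unions, which is
mathematically identical because absent-in-both terms vanish.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .seqio import SequenceRecord

__all__ = [
    "reverse_complement",
    "canonical",
    "count_kmers",
    "KmerCountTable",
    "presence_matrix",
    "write_count_table",
    "read_count_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile(r"[ACGT]+")
_VALID = re.compile(r"[ACGT]*\Z")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not _VALID.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"reverse_complement: non-ACGT character(s) {bad} in {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """The lexicographically smaller of ``s`` and its reverse complement."""
    rc = reverse_complement(s)
    return s if s <= rc else rc


@dataclass
class KmerCountTable:
    """Per-species sparse canonical k-mer counts at a fixed length K.

    Attributes
    ----------
    K : int
        k-mer length.
    counts : dict
        ``species_id -> {canonical k-mer -> count >= 1}``. Absent k-mers
        are simply not stored; their count is 0 by convention.
    lengths : dict
        ``species_id -> total ungapped sequence length`` (sum over
        contigs). Needed by length-normalised distance measures.
    """

    K: int
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.counts)

    def union_kmers(self) -> set[str]:
        out: set[str] = set()
        for table in self.counts.values():
            out.update(table)
        return out

    def intersection_kmers(self) -> set[str]:
        tables = list(self.counts.values())
        if not tables:
            return set()
        out = set(tables[0])
        for table in tables[1:]:
            out.intersection_update(table)
        return out


def _count_one(sequence: str, K: int, into: dict[str, int]) -> None:
    # windows containing non-ACGT characters are skipped entirely, so
    # counting runs independently inside each maximal ACGT run
    for match in _ACGT_RUN.finditer(sequence):
        run = match.group()
        if len(run) < K:
            continue
        rc_run = run.translate(_COMPLEMENT)[::-1]
        n = len(run)
        for i in range(n - K + 1):
            fwd = run[i : i + K]
            rev = rc_run[n - K - i : n - i]
            kmer = fwd if fwd <= rev else rev
            into[kmer] = into.get(kmer, 0) + 1


def count_kmers(records: Iterable[SequenceRecord], K: int) -> KmerCountTable:
    """Count canonical k-mers of length ``K`` for each species.

    A sliding window of width K moves in steps of 1; every window made
    only of A/C/G/T contributes 1 to the count of its canonical form.
    Records sharing a ``species_id`` are treated as contigs of one
    species: their counts are pooled but windows never span a record
    boundary.
    """
    if K <= 0:
        raise ValueError(f"k-mer length must be positive, got K={K}")
    table = KmerCountTable(K=K)
    for rec in records:
        per_species = table.counts.setdefault(rec.species_id, {})
        _count_one(rec.sequence, K, per_species)
        table.lengths[rec.species_id] = table.lengths.get(rec.species_id, 0) + rec.n
    return table


def presence_matrix(table: KmerCountTable) -> pd.DataFrame:
    """Boolean presence/absence matrix: union of k-mers x species.

    Rows are sorted lexicographically for deterministic order.
    """
    kmers = sorted(table.union_kmers())
    data = {
        sp: [kmer in counts for kmer in kmers]
        for sp, counts in table.counts.items()
    }
    return pd.DataFrame(data, index=kmers, dtype=bool)


def write_count_table(counts: Mapping[str, int], path) -> None:
    """Dump one species' counts as TSV with columns ``kmer``, ``count``.

    This is the on-disk interchange format for count tables.
    """
    df = pd.DataFrame(sorted(counts.items()), columns=["kmer", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
    return dict(zip(df["kmer"], df["count"]))
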