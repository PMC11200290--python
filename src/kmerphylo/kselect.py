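"""Entropy-based selection of the k-mer length.

For each candidate length K the presence/absence of every distinct
canonical k-mer across the species is summarised by the binary Shannon
entropy of its presence fraction, and the per-k-mer average is the
profile value H(K). Small K gives k-mers present everywhere (entropy
0); very large K gives k-mers private to single species (entropy of a
1/n-vs-rest split); moderate K captures shared-by-subsets structure and
maximises the average. The selected K is the argmax, ties broken toward
the smaller length.

Entropy is computed in bits (log base 2) so that each k-mer's term lies
in [0, 1]; the "average" divides the total by the number m of distinct
k-mers, which makes profiles comparable across K where m varies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import count_kmers
from .seqio import SequenceRecord

__all__ = ["kmer_entropy", "entropy_profile", "EntropyProfile"]


def kmer_entropy(p: float) -> float:
    """Binary entropy -(p log2 p + (1-p) log2 (1-p)), with 0 log 0 := 0.

    ``p`` is the fraction of species in which a k-mer is present.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"presence fraction must be in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    return float(-(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p)))


@dataclass
class EntropyProfile:
    """Average presence/absence entropy for each candidate K."""

    table: pd.DataFrame  # columns: K, m, average_entropy, selected

    @property
    def selected_K(self) -> int:
        return int(self.table.loc[self.table["selected"], "K"].iloc[0])

    def average_entropy(self, K: int) -> float:
        row = self.table.loc[self.table["K"] == K, "average_entropy"]
        if row.empty:
            raise KeyError(f"K={K} not in profile")
        return float(row.iloc[0])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _average_entropy(records: Sequence[SequenceRecord], K: int, n_species: int) -> tuple[int, float]:
    table = count_kmers(records, K)
    occupancy = Counter()
    for counts in table.counts.values():
        occupancy.update(counts.keys())
    m = len(occupancy)
    if m == 0:
        return 0, 0.0
    # histogram over "present in j of n species", j = 1..n
    hist = np.bincount(np.fromiter(occupancy.values(), dtype=np.int64), minlength=n_species + 1)
    p = np.arange(n_species + 1) / n_species
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    h = np.nan_to_num(h)
    return m, float(np.dot(hist, h) / m)


def entropy_profile(
    records: Iterable[SequenceRecord], K_min: int = 6, K_max: int = 18
) -> EntropyProfile:
    """Compute the average-entropy profile over ``K_min..K_max``.

    Requires at least two species; presence fractions over a single
    species are always degenerate, so entropy is undefined there.
    """
    records = list(records)
    n_species = len({r.species_id for r in records})
    if n_species < 2:
        raise ValueError("entropy profile requires at least 2 species")
    if not 1 <= K_min <= K_max:
        raise ValueError(f"invalid K range [{K_min}, {K_max}]")
    rows = []
    for K in range(K_min, K_max + 1):
        m, avg = _average_entropy(records, K, n_species)
        rows.append({"K": K, "m": m, "average_entropy": avg})
    df = pd.DataFrame(rows)
    best = int(df["average_entropy"].idxmax())  # first index at max -> smaller K on ties
    df["selected"] = [i == best for i in range(len(df))]
    return EntropyProfile(df)
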