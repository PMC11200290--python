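"""Pairwise species distances from k-mer count tables.

Three measures over the count vectors q, s of two species Q, S (indexed
by canonical k-mer; absent means count 0):

* squared Euclidean:  d_E = sum_i (q_i - s_i)^2
* Mahalanobis-style:  d_M = sum_i ((q_i - s_i) / sigma_i)^2, where
  sigma_i is the population standard deviation of k-mer i's counts
  across all species in the dataset (absent = 0); terms with
  sigma_i = 0 contribute 0 (all species then have identical counts).
* fractional common k-mer count:
  d_FC = | log( eps + sum_i min(q_i, s_i) / (min(n, m) - K + 1) ) |
  where n, m are the two (ungapped) sequence lengths, so the shared
  count is normalised by the number of k-mer windows of the shorter
  sequence. eps only guards log(0); natural log by default.

All sums run over the sparse union of stored k-mers, which equals the
dense sum over all 4**K possibilities because absent-in-both terms are
zero in every measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .kmers import KmerCountTable

__all__ = [
    "DistanceConfig",
    "DistanceMatrix",
    "euclidean_sq",
    "mahalanobis",
    "fractional_common",
    "distance_matrix",
    "METRICS",
]

METRICS = ("euclidean", "mahalanobis", "fractional")


@dataclass(frozen=True)
class DistanceConfig:
    """epsilon guards log(0) in the fractional measure; natural log."""

    epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def euclidean_sq(Q: Mapping[str, int], S: Mapping[str, int]) -> float:
    total = 0.0
    for kmer in Q.keys() | S.keys():
        d = Q.get(kmer, 0) - S.get(kmer, 0)
        total += d * d
    return total


def _sigma_per_kmer(all_tables: KmerCountTable) -> dict[str, float]:
    species = all_tables.species
    n = len(species)
    if n < 2:
        raise ValueError("Mahalanobis sigma needs at least 2 species")
    sums: dict[str, float] = {}
    sqsums: dict[str, float] = {}
    for counts in all_tables.counts.values():
        for kmer, c in counts.items():
            sums[kmer] = sums.get(kmer, 0.0) + c
            sqsums[kmer] = sqsums.get(kmer, 0.0) + c * c
    out = {}
    for kmer, s in sums.items():
        var = sqsums[kmer] / n - (s / n) ** 2
        out[kmer] = math.sqrt(max(var, 0.0))
    return out


def mahalanobis(
    Q: Mapping[str, int],
    S: Mapping[str, int],
    all_tables: KmerCountTable,
    sigma: dict[str, float] | None = None,
) -> float:
    """Variance-scaled squared distance; sigma may be precomputed."""
    if sigma is None:
        sigma = _sigma_per_kmer(all_tables)
    total = 0.0
    for kmer in Q.keys() | S.keys():
        d = Q.get(kmer, 0) - S.get(kmer, 0)
        if d == 0:
            continue
        sig = sigma.get(kmer, 0.0)
        if sig == 0.0:
            continue  # all species equal for this k-mer => d would be 0 anyway
        total += (d / sig) ** 2
    return total


def fractional_common(
    Q: Mapping[str, int],
    S: Mapping[str, int],
    n: int,
    m_len: int,
    K: int,
    config: DistanceConfig = DistanceConfig(),
) -> float:
    """|log(eps + shared-kmer fraction)| of two species.

    ``n`` and ``m_len`` are the two species' ungapped sequence lengths;
    the denominator min(n, m_len) - K + 1 is the window count of the
    shorter sequence, so identical sequences give a fraction of 1 and a
    distance of |log(1 + eps)| ~ 0.
    """
    denom = min(n, m_len) - K + 1
    if denom < 1:
        raise ValueError(
            f"shortest sequence (length {min(n, m_len)}) is shorter than K={K}"
        )
    shared = 0
    small, large = (Q, S) if len(Q) <= len(S) else (S, Q)
    for kmer, c in small.items():
        other = large.get(kmer, 0)
        if other:
            shared += min(c, other)
    return abs(math.log(config.epsilon + shared / denom))


def distance_matrix(
    tables: KmerCountTable,
    metric: str = "fractional",
    config: DistanceConfig = DistanceConfig(),
) -> DistanceMatrix:
    """Apply one metric to every unordered species pair.

    Labels follow the input species order.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    species = tables.species
    n = len(species)
    values = np.zeros((n, n))
    sigma = _sigma_per_kmer(tables) if metric == "mahalanobis" else None
    for (i, a), (j, b) in combinations(enumerate(species), 2):
        Q, S = tables.counts[a], tables.counts[b]
        if metric == "euclidean":
            d = euclidean_sq(Q, S)
        elif metric == "mahalanobis":
            d = mahalanobis(Q, S, tables, sigma=sigma)
        else:
            d = fractional_common(
                Q, S, tables.lengths[a], tables.lengths[b], tables.K, config
            )
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=species, values=values, metric=metric)
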