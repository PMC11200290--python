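"""Synthetic datasets: sequences evolved down a known tree, with
planted missing regions and recorded ground truth.

The generator emulates the setting the missing-region filter is built
for: several related sequences descend from a common ancestor through
point substitutions (uniform replacement among the other three bases,
per-site change probability equal to the branch length) and optional
small indels (Poisson events along the branch, geometric lengths).
Contiguous deletions of configurable length are then planted at
uniformly random locations in chosen species, and every deleted
interval is recorded in that species' own pre-deletion coordinates so
the filter can be scored against exact truth.

Everything is driven by one integer seed; identical configurations
produce byte-identical FASTA and truth files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmers import canonical
from .phylogeny import tree_from_newick_string
from .seqio import SequenceRecord

__all__ = [
    "SimulationConfig",
    "MissingRegionTruth",
    "evolve_sequences",
    "plant_deletions",
    "truth_missing_kmers",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Attributes
    ----------
    tree : str
        Newick with branch lengths in expected substitutions per site.
    root_length : int
        Length of the ancestral sequence (default 20 kb).
    gc : float
        GC content of the ancestral sequence.
    indel_rate : float
        Small-indel events per site per unit branch length (0 disables
        indels); a zero-length branch therefore never mutates.
    indel_mean_length : float
        Mean of the geometric indel-length distribution.
    deletion_lengths : mapping
        ``species_id -> list of lengths`` of missing regions to plant;
        empty mapping plants nothing. Typical study grid: 200, 500,
        1000, 2000.
    seed : int
        RNG seed; fixed seed means byte-identical outputs.
    """

    tree: str
    root_length: int = 20_000
    gc: float = 0.5
    indel_rate: float = 0.0
    indel_mean_length: float = 3.0
    deletion_lengths: Mapping[str, Sequence[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        for sp, lengths in self.deletion_lengths.items():
            for L in lengths:
                if L < 0 or L >= self.root_length:
                    raise ValueError(
                        f"deletion length {L} for {sp!r} must be in [0, root_length)"
                    )


@dataclass
class MissingRegionTruth:
    """Deleted intervals per species, 0-based half-open, in that
    species' own pre-deletion coordinates; plus the generating tree."""

    intervals: dict[str, list[tuple[int, int]]]
    tree: str

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tstart\tend\n")
            for sp in sorted(self.intervals):
                for start, end in self.intervals[sp]:
                    fh.write(f"{sp}\t{start}\t{end}\n")


def _mutate(seq: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p_sub, uniformly among the
    other three bases."""
    if p_sub <= 0:
        return seq.copy()
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p_sub)[0]
    if hit.size:
        offsets = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + offsets) % 4
    return out


def _apply_indels(
    seq: np.ndarray, rate: float, mean_len: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return seq
    n_events = rng.poisson(rate * len(seq))  # rate already scaled by branch length
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / max(mean_len, 1.0)))
        pos = int(rng.integers(0, len(seq) + 1))
        if rng.random() < 0.5 and len(seq) > length:  # deletion
            seq = np.concatenate([seq[:pos], seq[pos + length :]])
        else:  # insertion of random bases
            ins = rng.integers(0, 4, size=length).astype(seq.dtype)
            seq = np.concatenate([seq[:pos], ins, seq[pos:]])
    return seq


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def evolve_sequences(config: SimulationConfig) -> list[SequenceRecord]:
    """Evolve the root sequence down the tree; leaves are returned in
    Newick order, before any deletion is planted."""
    rng = np.random.default_rng(config.seed)
    tree = tree_from_newick_string(config.tree)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    root_seq = rng.choice(4, size=config.root_length, p=p).astype(np.uint8)

    leaves: list[SequenceRecord] = []

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seq = _mutate(seq, bl, rng)
            child_seq = _apply_indels(
                child_seq, config.indel_rate * bl, config.indel_mean_length, rng
            )
            if child.is_leaf():
                leaves.append(SequenceRecord(child.taxon.label, _decode(child_seq)))
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_seq)
    return leaves


def plant_deletions(
    records: Iterable[SequenceRecord],
    deletion_lengths: Mapping[str, Sequence[int]],
    seed: int,
    tree: str = "",
) -> tuple[list[SequenceRecord], MissingRegionTruth]:
    """Remove contiguous regions at uniformly random locations.

    Intervals within one species are drawn without overlap (rejection
    sampling) and recorded in pre-deletion coordinates; the returned
    records have the regions excised.
    """
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    truth = MissingRegionTruth(intervals={}, tree=tree)
    for rec in records:
        lengths = list(deletion_lengths.get(rec.species_id, []))
        if sum(lengths) >= rec.n:
            raise ValueError(
                f"total deletion length {sum(lengths)} >= sequence length "
                f"{rec.n} for {rec.species_id!r}"
            )
        intervals: list[tuple[int, int]] = []
        for L in lengths:
            if L == 0:
                continue
            for _ in range(1000):
                start = int(rng.integers(0, rec.n - L + 1))
                cand = (start, start + L)
                if all(cand[1] <= s or cand[0] >= e for s, e in intervals):
                    intervals.append(cand)
                    break
            else:  # pragma: no cover - pathological packing only
                raise RuntimeError(
                    f"could not place a {L}-base deletion in {rec.species_id!r}"
                )
        intervals.sort()
        truth.intervals[rec.species_id] = intervals
        seq = rec.sequence
        for start, end in reversed(intervals):
            seq = seq[:start] + seq[end:]
        out.append(SequenceRecord(rec.species_id, seq) if seq else rec)
    return out, truth


def truth_missing_kmers(
    record: SequenceRecord,
    intervals: Sequence[tuple[int, int]],
    K: int,
    within: bool = False,
) -> set[str]:
    """Ground-truth missing k-mers of one species' pre-deletion sequence.

    Returns the canonical k-mers every occurrence of which overlaps a
    deleted interval (``within=True`` demands each occurrence lie
    entirely inside an interval) — exactly the k-mers whose absence
    after deletion is attributable to the missing region rather than to
    chance.
    """
    if not intervals:
        return set()
    occurrences: dict[str, list[int]] = {}
    seq = record.sequence
    for i in range(record.n - K + 1):
        window = seq[i : i + K]
        if any(ch not in "ACGT" for ch in window):
            continue
        occurrences.setdefault(canonical(window), []).append(i)

    def hit(i: int) -> bool:
        if within:
            return any(s <= i and i + K <= e for s, e in intervals)
        return any(i < e and i + K > s for s, e in intervals)

    return {kmer for kmer, pos in occurrences.items() if all(hit(i) for i in pos)}


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], MissingRegionTruth]:
    """Convenience wrapper: evolve, then plant the configured deletions.

    Returns (pre-deletion records, post-deletion records, truth).
    """
    pre = evolve_sequences(config)
    post, truth = plant_deletions(
        pre, config.deletion_lengths, seed=config.seed + 1, tree=config.tree
    )
    return pre, post, truth
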