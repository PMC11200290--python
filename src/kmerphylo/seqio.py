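"""Sequence, alignment, tree and matrix I/O.

Ingestion is permissive but canonicalising: sequences are uppercased on
load, ``U`` is mapped to ``T``, and only IUPAC nucleotide codes are
accepted. Non-ACGT ambiguity codes are retained in the record; k-mer
counting skips windows containing them, so the policy lives in one
place downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import dendropy
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .distances import DistanceMatrix

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "write_phylip",
    "write_distance_tsv",
]

IUPAC_CODES = set("ACGTNRYSWKMBDHV")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One species' (ungapped) nucleotide sequence."""

    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.species_id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.species_id!r}: non-IUPAC character(s) {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        """Sequence length."""
        return len(self.sequence)


def _normalise(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The species id is the first whitespace-delimited token of the
    header. Lowercase is accepted and uppercased; wrapped lines are
    concatenated. Duplicate ids, empty files and non-IUPAC characters
    are rejected with a message naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate species id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, _normalise(str(entry.seq))))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass
class AlignmentBlock:
    """A multiple sequence alignment: one gapped row per species.

    All rows have equal length (the number of alignment columns); the
    gap character is ``-``. Removing gaps from a row recovers the
    species' ungapped sequence.
    """

    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {sp: len(row) for sp, row in self.rows.items()}
        if len(set(widths.values())) > 1:
            shortest = min(widths, key=widths.get)
            longest = max(widths, key=widths.get)
            raise ValueError(
                "ragged alignment: row "
                f"{shortest!r} has {widths[shortest]} columns but "
                f"{longest!r} has {widths[longest]}"
            )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, species_id: str) -> str:
        return self.rows[species_id].replace(GAP, "")


def read_alignment(path) -> AlignmentBlock:
    """Read an aligned FASTA file; rows must all have equal length."""
    path = Path(path)
    rows: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in rows:
            raise ValueError(f"{path}: duplicate species id {entry.id!r}")
        rows[entry.id] = _normalise(str(entry.seq))
    if not rows:
        raise ValueError(f"{path}: no alignment rows found")
    return AlignmentBlock(rows)


def write_alignment(block: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for sp, row in block.rows.items():
            fh.write(f">{sp}\n{row}\n")


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree file into an (unrooted) dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("leaf labels must be unique")
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def write_phylip(matrix: "DistanceMatrix", path) -> None:
    """Write a distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            cells = " ".join(f"{x:.6f}" for x in row)
            fh.write(f"{label:<10s} {cells}\n")


def write_distance_tsv(matrix: "DistanceMatrix", path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t")
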