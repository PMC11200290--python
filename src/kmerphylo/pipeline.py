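"""End-to-end workflow: count -> select K -> filter -> distance -> NJ.

The pipeline mirrors how alignment-free distance phylogenies are built
in practice, with the missing-region filter inserted between counting
and distance construction. Every run can write its artifacts (count
tables, entropy profile, filter report, distance matrices, trees) and
a JSON manifest sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import seqio
from .distances import DistanceConfig, DistanceMatrix, distance_matrix
from .filtering import FilterConfig, FilterReport, filter_kmers, substring_length
from .kmers import KmerCountTable, count_kmers
from .kselect import EntropyProfile, entropy_profile
from .phylogeny import PhyloTree, neighbor_joining, rf_distance
from .seqio import SequenceRecord

logger = logging.getLogger("kmerphylo")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_run"]


@dataclass
class PipelineConfig:
    """Fully explicit description of one pipeline run."""

    K: int | str = "auto"  # fixed length, or "auto" for entropy selection
    k_range: tuple[int, int] = (6, 18)  # candidate range when K == "auto"
    filter_enabled: bool = True
    substring_k: int | None = None  # override for the filter substring length
    Th: float = 2.0
    metric: str = "fractional"
    epsilon: float = 1e-10
    outdir: Path | None = None

    def manifest(self) -> dict:
        return {
            "K": self.K,
            "k_range": list(self.k_range),
            "filter_enabled": self.filter_enabled,
            "substring_k": self.substring_k,
            "Th": self.Th,
            "metric": self.metric,
            "epsilon": self.epsilon,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    K: int
    tables: KmerCountTable
    filtered_tables: KmerCountTable
    distances: DistanceMatrix
    tree: PhyloTree
    unfiltered_distances: DistanceMatrix
    unfiltered_tree: PhyloTree
    filter_report: FilterReport | None = None
    entropy: EntropyProfile | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    records: Sequence[SequenceRecord], config: PipelineConfig
) -> PipelineResult:
    """Run the full workflow on in-memory records.

    Stages: canonical k-mer counting; optional entropy-based selection
    of K; missing-region filtering (when enabled); distance matrix;
    Neighbor Joining. The unfiltered distance matrix and tree are
    always computed as well (with filtering disabled they *are* the
    result), so before/after comparisons come for free.
    """
    if len(records) < 3:
        raise ValueError("pipeline needs at least 3 species for a non-trivial tree")

    entropy = None
    if config.K == "auto":
        lo, hi = config.k_range
        entropy = entropy_profile(records, lo, hi)
        K = entropy.selected_K
        logger.info("select-k: chose K=%d over [%d, %d]", K, lo, hi)
    else:
        K = int(config.K)

    tables = count_kmers(records, K)
    logger.info(
        "count: %d species, %d distinct canonical %d-mers",
        len(tables.species), len(tables.union_kmers()), K,
    )

    dconfig = DistanceConfig(epsilon=config.epsilon)
    unfiltered_distances = distance_matrix(tables, config.metric, dconfig)
    unfiltered_tree = neighbor_joining(unfiltered_distances)

    report = None
    if config.filter_enabled:
        k_small = config.substring_k or substring_length(K)
        fconfig = FilterConfig(K=K, k=k_small, Th=config.Th)
        subtables = count_kmers(records, k_small)
        filtered_tables, report = filter_kmers(tables, subtables, fconfig)
        logger.info(
            "filter: %d candidates, %d discarded (K=%d, k=%d, Th=%g)",
            report.n_candidates, report.n_discarded, K, k_small, config.Th,
        )
        distances = distance_matrix(filtered_tables, config.metric, dconfig)
        tree = neighbor_joining(distances)
    else:
        filtered_tables = tables
        distances = unfiltered_distances
        tree = unfiltered_tree

    manifest = config.manifest()
    manifest["selected_K"] = K
    manifest["species"] = [r.species_id for r in records]

    result = PipelineResult(
        config=config,
        K=K,
        tables=tables,
        filtered_tables=filtered_tables,
        distances=distances,
        tree=tree,
        unfiltered_distances=unfiltered_distances,
        unfiltered_tree=unfiltered_tree,
        filter_report=report,
        entropy=entropy,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_artifacts(result, Path(config.outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seqio.write_newick(result.tree, outdir / "tree.nwk")
    seqio.write_newick(result.unfiltered_tree, outdir / "tree_unfiltered.nwk")
    seqio.write_phylip(result.distances, outdir / "distances.phylip")
    seqio.write_distance_tsv(result.distances, outdir / "distances.tsv")
    if result.filter_report is not None:
        result.filter_report.write_tsv(outdir / "filter_report.tsv")
    if result.entropy is not None:
        result.entropy.write_tsv(outdir / "entropy_profile.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def evaluate_run(
    result: PipelineResult,
    reference: PhyloTree,
    truth_missing: set[str] | None = None,
    rooted: bool = False,
) -> dict:
    """Score a run against a reference tree (and optional k-mer truth).

    Reports the RF distance of the filtered and unfiltered trees to the
    reference, and, when a ground-truth set of missing-region k-mers is
    supplied, the filter's sensitivity (truth k-mers discarded) and
    specificity (non-truth candidates kept), in percent.
    """
    report = {
        "rf_after_filtering": rf_distance(result.tree, reference, rooted=rooted),
        "rf_before_filtering": rf_distance(
            result.unfiltered_tree, reference, rooted=rooted
        ),
    }
    if truth_missing is not None and result.filter_report is not None:
        fr = result.filter_report
        truth = truth_missing & fr.candidates
        other = fr.candidates - truth
        report["filter_sensitivity_pct"] = (
            100.0 * len(truth & fr.discarded) / len(truth) if truth else 0.0
        )
        report["filter_specificity_pct"] = (
            100.0 * len(other - fr.discarded) / len(other) if other else 100.0
        )
    return report
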