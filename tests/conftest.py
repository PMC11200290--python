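"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from collections import Counter

import pytest
from hypothesis import HealthCheck, settings

from Bio.Seq import Seq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def naive_canonical_counts(sequence: str, K: int) -> dict[str, int]:
    """Sliding-window canonical k-mer counter built on Bio.Seq.

    Deliberately independent of the package's counting code: windows
    are enumerated one by one, reverse complements come from biopython,
    and non-ACGT windows are skipped.
    """
    counts: Counter[str] = Counter()
    for i in range(len(sequence) - K + 1):
        window = sequence[i : i + K]
        if any(ch not in "ACGT" for ch in window):
            continue
        rc = str(Seq(window).reverse_complement())
        counts[min(window, rc)] += 1
    return dict(counts)


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_additive_tree(n_leaves: int, rng: random.Random):
    """Random binary tree with positive edge lengths plus its exact
    leaf-to-leaf path-length matrix (the additivity oracle).

    Returns (newick string, labels, {frozenset({a, b}): distance}).
    Built by random sequential joins; distances are accumulated leaf
    depths, entirely independent of any tree library.
    """
    labels = [f"T{i}" for i in range(1, n_leaves + 1)]
    clusters = [(label, {label: 0.0}) for label in labels]
    dist: dict[frozenset, float] = {}
    while len(clusters) > 1:
        i, j = rng.sample(range(len(clusters)), 2)
        (nwk_a, depth_a) = clusters[i]
        (nwk_b, depth_b) = clusters[j]
        la = rng.uniform(0.1, 1.0)
        lb = rng.uniform(0.1, 1.0)
        for x, dx in depth_a.items():
            for y, dy in depth_b.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in depth_a.items()}
        merged.update({y: dy + lb for y, dy in depth_b.items()})
        newick = f"({nwk_a}:{la:.10f},{nwk_b}:{lb:.10f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((newick, merged))
    return clusters[0][0] + ";", labels, dist


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240604)
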