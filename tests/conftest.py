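"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from phylopipe.density_filters import Dataset, GeneGroup
from phylopipe.genbank_io import SeqEntry
from phylopipe.overlap_clique import OverlapGraph


def make_entry(
    species: str,
    residues: str = "ACGTACGTACGT",
    gene: str = "COX1",
    family: str = "Apidae",
    record_id: str | None = None,
    alphabet: str = "nucleotide",
    **kw,
) -> SeqEntry:
    return SeqEntry(
        species=species,
        family=family,
        record_id=record_id or f"id_{species}_{gene}",
        gene_label=gene,
        alphabet=alphabet,
        residues=residues,
        **kw,
    )


def make_group(
    gene: str, species_to_residues: dict[str, str], aligned: bool = False, **kw
) -> GeneGroup:
    entries = tuple(
        make_entry(sp, res, gene=gene, **kw) for sp, res in species_to_residues.items()
    )
    return GeneGroup(gene, entries, aligned=aligned)


def graph_from_edges(nodes, edges, gene: str = "G", threshold: int = 1) -> OverlapGraph:
    return OverlapGraph(
        gene_label=gene,
        nodes=tuple(nodes),
        edges=frozenset(frozenset(e) for e in edges),
        threshold=threshold,
    )


def random_graph(seed: int, max_n: int = 15):
    """Seeded Erdos-Renyi-style graph as (nodes, edges)."""
    rng = random.Random(seed)
    n = rng.randint(2, max_n)
    p = rng.uniform(0.2, 0.8)
    nodes = [f"s{i:02d}" for i in range(n)]
    edges = [
        (u, v) for u, v in itertools.combinations(nodes, 2) if rng.random() < p
    ]
    return nodes, edges


def brute_force_max_clique(nodes, edges) -> set:
    """Exhaustive subset enumeration, largest first (oracle; n <= ~12)."""
    eset = {frozenset(e) for e in edges}
    for r in range(len(nodes), 0, -1):
        for comb in itertools.combinations(sorted(nodes), r):
            if all(frozenset((u, v)) in eset for u, v in itertools.combinations(comb, 2)):
                return set(comb)
    return set()


def longest_common_substring(a: str, b: str) -> int:
    """Dynamic-programming oracle for the orientation-check threshold."""
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def random_dna(seed: int, n: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def simple_dataset() -> Dataset:
    """Two genes over four species plus one 3-species gene."""
    g1 = make_group("COX1", {f"Sp_{i}": "ACGT" * 30 for i in range(1, 5)})
    g2 = make_group("RRNS", {f"Sp_{i}": "ACGT" * 20 for i in range(1, 5)})
    g3 = make_group("ND2", {f"Sp_{i}": "ACGT" * 10 for i in range(1, 4)})
    return Dataset((g1, g2, g3))
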