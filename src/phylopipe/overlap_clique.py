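"""Pairwise-overlap graphs and exact maximum-clique species selection.

For each gene alignment we ask for the largest set of species whose
sequences all mutually overlap in at least a threshold number of aligned
positions (default 100).  Casting species as vertices and sufficient
pairwise overlap as edges turns this into a maximum-clique problem, solved
exactly by a branch-and-bound search with a greedy-coloring bound.  Species
outside the first clique are offered a second chance through a second
maximum clique on the remaining vertices; everything else is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from phylopipe.density_filters import GeneGroup
from phylopipe.genbank_io import SeqEntry

logger = logging.getLogger(__name__)

OVERLAP_THRESHOLD = 100
EXACT_NODE_LIMIT = 2000

_MISSING = {
    "nucleotide": set("-?NX"),
    "amino_acid": set("-?X"),
}


def pairwise_overlap(a: SeqEntry, b: SeqEntry) -> int:
    """Count alignment columns where both rows carry a comparable residue.

    Gap and missing symbols ('-', '?', and N/X for nucleotides, X for amino
    acids) do not count as overlap.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"aligned lengths differ: {a.header} ({len(a.residues)}) vs "
            f"{b.header} ({len(b.residues)})"
        )
    missing_a = _MISSING[a.alphabet]
    missing_b = _MISSING[b.alphabet]
    return sum(
        1
        for x, y in zip(a.residues, b.residues)
        if x not in missing_a and y not in missing_b
    )


@dataclass(frozen=True)
class OverlapGraph:
    """Species graph of one gene; an edge means sufficient aligned overlap."""

    gene_label: str
    nodes: tuple[str, ...]
    edges: frozenset[frozenset]
    threshold: int
    overlap_counts: dict = field(default_factory=dict, compare=False)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj


@dataclass(frozen=True)
class CliqueResult:
    """First and second maximum cliques plus the discarded residual."""

    first: frozenset[str]
    second: frozenset[str]
    residual: frozenset[str]


def build_overlap_graph(group: GeneGroup, threshold: int = OVERLAP_THRESHOLD) -> OverlapGraph:
    if not group.aligned:
        raise ValueError(f"group {group.gene_label} must be aligned to measure overlap")
    entries = sorted(group.entries, key=lambda e: e.species)
    edges: set[frozenset] = set()
    counts: dict[frozenset, int] = {}
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            n = pairwise_overlap(a, b)
            pair = frozenset((a.species, b.species))
            counts[pair] = n
            if n >= threshold:
                edges.add(pair)
    return OverlapGraph(
        gene_label=group.gene_label,
        nodes=tuple(e.species for e in entries),
        edges=frozenset(edges),
        threshold=threshold,
        overlap_counts=counts,
    )


# ---------------------------------------------------------------------------
# exact branch and bound (Tomita-style greedy-coloring bound)

def _coloring(P: set, adj: dict) -> tuple[list, list]:
    """Greedy color classes over P; returns vertices ordered by color and
    the per-vertex color number, an upper bound on the clique size in the
    prefix ending at that vertex."""
    classes: list[set] = []
    color_of: dict = {}
    for v in sorted(P, key=lambda u: (-len(adj[u] & P), u)):
        for ci, cl in enumerate(classes):
            if not (adj[v] & cl):
                cl.add(v)
                color_of[v] = ci + 1
                break
        else:
            classes.append({v})
            color_of[v] = len(classes)
    order = sorted(P, key=lambda v: (color_of[v], v))
    bounds = [color_of[v] for v in order]
    return order, bounds


def _expand(size: int, P: set, adj: dict, best: list) -> None:
    order, bounds = _coloring(P, adj)
    for i in range(len(order) - 1, -1, -1):
        if size + bounds[i] <= best[0]:
            return
        v = order[i]
        new_p = {u for u in order[:i] if u in adj[v]}
        if new_p:
            _expand(size + 1, new_p, adj, best)
        elif size + 1 > best[0]:
            best[0] = size + 1


def _max_clique_size(nodes: set, adj: dict) -> int:
    best = [0]
    if nodes:
        _expand(0, set(nodes), adj, best)
    return best[0]


def _greedy_clique(nodes: list, adj: dict) -> set:
    clique: set = set()
    for v in sorted(nodes, key=lambda u: (-len(adj[u]), u)):
        if adj[v] >= clique:
            clique.add(v)
    return clique


def maximum_clique(g: OverlapGraph, exact_limit: int = EXACT_NODE_LIMIT) -> frozenset[str]:
    """A maximum-cardinality clique of the overlap graph.

    Exact branch-and-bound up to ``exact_limit`` vertices; among equal-size
    maxima the lexicographically smallest sorted species tuple is returned,
    built by greedily fixing the smallest feasible vertex at each level.
    Above the limit a degree-greedy heuristic is used (always a genuine
    clique, maximality not guaranteed) and a warning is logged.
    """
    adj = g.adjacency()
    nodes = sorted(g.nodes)
    if not nodes:
        return frozenset()
    if len(nodes) > exact_limit:
        logger.warning(
            "graph %s has %d nodes > exact limit %d: greedy heuristic clique",
            g.gene_label, len(nodes), exact_limit,
        )
        return frozenset(_greedy_clique(nodes, adj))
    k = _max_clique_size(set(nodes), adj)
    clique: list[str] = []
    candidates = set(nodes)
    while len(clique) < k:
        for v in sorted(candidates):
            rest = {u for u in candidates if u in adj[v] and u > v}
            need = k - len(clique) - 1
            if _max_clique_size(rest, adj) >= need:
                clique.append(v)
                candidates = rest
                break
        else:  # pragma: no cover - k came from the same search space
            raise RuntimeError("clique reconstruction failed")
    return frozenset(clique)


def first_and_second_clique(
    g: OverlapGraph, exact_limit: int = EXACT_NODE_LIMIT
) -> CliqueResult:
    """First and second maximum cliques; leftover species are residual.

    The second clique is the maximum clique of the graph restricted to
    species outside the first; a size-1 second clique is retained (the
    later density filters decide its fate).
    """
    first = maximum_clique(g, exact_limit)
    remaining = [v for v in g.nodes if v not in first]
    restricted = OverlapGraph(
        gene_label=g.gene_label,
        nodes=tuple(remaining),
        edges=frozenset(e for e in g.edges if e <= set(remaining)),
        threshold=g.threshold,
        overlap_counts=g.overlap_counts,
    )
    second = maximum_clique(restricted, exact_limit)
    residual = frozenset(set(g.nodes) - set(first) - set(second))
    if residual:
        logger.info(
            "gene %s: %d species outside both cliques discarded",
            g.gene_label, len(residual),
        )
    return CliqueResult(first=first, second=second, residual=residual)


def split_by_cliques(
    group: GeneGroup, threshold: int = OVERLAP_THRESHOLD
) -> tuple[GeneGroup, GeneGroup, frozenset[str]]:
    """Partition an aligned group into first-clique and second-clique
    sub-groups, returning also the discarded residual species."""
    g = build_overlap_graph(group, threshold)
    res = first_and_second_clique(g)
    return group.subset(set(res.first)), group.subset(set(res.second)), res.residual
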