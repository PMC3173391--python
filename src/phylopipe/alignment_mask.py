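"""Column-level alignment masking and tRNA concatenation.

Gap-saturated columns carry little signal and inflate alignment length;
third codon positions of mitochondrial protein-coding genes are saturated
with synonymous substitutions at deep divergences.  Both are removed at the
column level (optionally replaced by the missing symbol instead of being
deleted).  The many short tRNA alignments are concatenated into a single
block so they can be handled as one partition downstream.

Gap symbols are '-' and '?'; N/X are ambiguous characters, not gaps.
"""

from __future__ import annotations

from dataclasses import replace

from phylopipe.density_filters import GeneGroup

MAX_GAP_FRACTION = 0.70
_GAPS = set("-?")
MISSING = "?"


def gap_fraction(column: str) -> float:
    if not column:
        return 0.0
    return sum(1 for c in column if c in _GAPS) / len(column)


def _drop_columns(group: GeneGroup, drop: set[int], mask_instead: bool) -> GeneGroup:
    entries = []
    for e in group.entries:
        if mask_instead:
            row = "".join(
                MISSING if i in drop else c for i, c in enumerate(e.residues)
            )
        else:
            row = "".join(c for i, c in enumerate(e.residues) if i not in drop)
        entries.append(e.with_residues(row))
    return replace(group, entries=tuple(entries))


def mask_gappy_sites(
    group: GeneGroup,
    max_gap_fraction: float = MAX_GAP_FRACTION,
    mask_instead_of_delete: bool = False,
) -> tuple[GeneGroup, list[int]]:
    """Remove columns whose gap fraction strictly exceeds the threshold.

    Returns the masked group and the 0-based indices of removed columns.
    A column at exactly the threshold is kept.
    """
    if not group.aligned:
        raise ValueError(f"group {group.gene_label} must be aligned")
    if not group.entries:
        return group, []
    width = group.width
    drop = {
        i
        for i in range(width)
        if gap_fraction("".join(e.residues[i] for e in group.entries)) > max_gap_fraction
    }
    return _drop_columns(group, drop, mask_instead_of_delete), sorted(drop)


def mask_third_positions(
    group: GeneGroup, mask_instead_of_delete: bool = False
) -> GeneGroup:
    """Remove every third codon position of a codon-preserving alignment.

    Requires the aligned length to be divisible by three (back-translated
    alignments keep gaps codon-sized, so codon phase equals column index
    mod 3).
    """
    if not group.aligned:
        raise ValueError(f"group {group.gene_label} must be aligned")
    width = group.width
    if width % 3 != 0:
        raise ValueError(
            f"group {group.gene_label}: aligned length {width} not divisible by 3"
        )
    drop = set(range(2, width, 3))
    return _drop_columns(group, drop, mask_instead_of_delete)


def concatenate_trnas(
    groups: list[GeneGroup], label: str = "tRNA_concat"
) -> tuple[GeneGroup, list[tuple[str, int, int]]]:
    """Concatenate aligned tRNA groups into one block.

    Species missing from a block are filled with gap characters over that
    block's width.  Returns the combined group and the recorded block
    boundaries as (gene_label, start, end) in 1-based inclusive columns.
    """
    if not groups:
        raise ValueError("no tRNA groups to concatenate")
    for g in groups:
        if not g.aligned:
            raise ValueError(f"group {g.gene_label} must be aligned")
    species = sorted(set().union(*(g.species for g in groups)))
    rows = {s: [] for s in species}
    proto = {}
    boundaries: list[tuple[str, int, int]] = []
    pos = 0
    for g in groups:
        width = g.width
        boundaries.append((g.gene_label, pos + 1, pos + width))
        pos += width
        for s in species:
            e = g.entry_for(s)
            if e is None:
                rows[s].append("-" * width)
            else:
                rows[s].append(e.residues)
                proto.setdefault(s, e)
    entries = tuple(
        proto[s].with_residues("".join(rows[s]), gene_label=label) for s in species
    )
    combined = GeneGroup(label, entries, alphabet=groups[0].alphabet, aligned=True)
    return combined, boundaries
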