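"""Concatenation into a partitioned supermatrix and tree-inference exports.

The surviving gene alignments are concatenated into one character matrix
over the union of species.  A species absent from a gene contributes a
block of the missing symbol ``?`` (``-`` is reserved for within-alignment
gaps).  Each gene becomes one contiguous partition with a substitution-model
hint; nuclear coding amino-acid groups can be merged under a single protein
partition.  Exports are relaxed PHYLIP (the tree-inference input), FASTA,
and a plain-text partition file in the RAxML ``MODEL, name = start-end``
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from phylopipe.density_filters import GeneGroup

MISSING = "?"
DNA_MODEL = "DNA"
PROTEIN_MODEL = "LGF"  # LG substitution matrix with empirical (+F) frequencies


@dataclass(frozen=True)
class Partition:
    gene_label: str
    alphabet: str
    start: int  # 1-based inclusive
    end: int
    model_hint: str
    n_gene_groups: int = 1  # >1 when several groups were merged


@dataclass(frozen=True)
class Supermatrix:
    species: tuple[str, ...]
    partitions: tuple[Partition, ...]
    matrix: dict  # species -> character row

    def __post_init__(self):
        width = self.width
        for s in self.species:
            if len(self.matrix[s]) != width:
                raise ValueError(f"row {s} has length {len(self.matrix[s])} != {width}")

    @property
    def width(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    @property
    def n_gene_groups(self) -> int:
        return sum(p.n_gene_groups for p in self.partitions)

    def block(self, species: str, partition: Partition) -> str:
        return self.matrix[species][partition.start - 1 : partition.end]

    @property
    def n_sequences(self) -> int:
        """Filled species-x-gene blocks (at least one non-missing character)."""
        count = 0
        for p in self.partitions:
            for s in self.species:
                if any(c != MISSING for c in self.block(s, p)):
                    count += 1
        return count


def concatenate(
    groups: list[GeneGroup],
    species_order: list[str] | None = None,
    merge_amino_acid_partitions: bool = False,
    merged_label: str = "nuclear_protein",
) -> Supermatrix:
    """Concatenate aligned gene groups into one partitioned supermatrix.

    Partitions are recorded in input order.  With
    ``merge_amino_acid_partitions`` all amino-acid groups are moved to the
    end and recorded as a single protein partition (their widths still
    count as separate gene groups for the coverage statistic).
    """
    if not groups:
        raise ValueError("cannot concatenate zero groups")
    for g in groups:
        if not g.aligned:
            raise ValueError(f"group {g.gene_label} must be aligned")
        seen = [e.species for e in g.entries]
        if len(seen) != len(set(seen)):
            dupes = sorted({s for s in seen if seen.count(s) > 1})
            raise ValueError(f"group {g.gene_label}: duplicate species {dupes}")
    if species_order is None:
        species = sorted(set().union(*(g.species for g in groups)))
    else:
        species = list(species_order)
    if merge_amino_acid_partitions:
        nt = [g for g in groups if g.alphabet != "amino_acid"]
        aa = [g for g in groups if g.alphabet == "amino_acid"]
    else:
        nt, aa = list(groups), []
    rows = {s: [] for s in species}
    partitions: list[Partition] = []
    pos = 0
    for g in nt:
        width = g.width
        model = DNA_MODEL if g.alphabet == "nucleotide" else PROTEIN_MODEL
        partitions.append(Partition(g.gene_label, g.alphabet, pos + 1, pos + width, model))
        pos += width
        for s in species:
            e = g.entry_for(s)
            rows[s].append(e.residues if e is not None else MISSING * width)
    if aa:
        start = pos + 1
        for g in aa:
            width = g.width
            pos += width
            for s in species:
                e = g.entry_for(s)
                rows[s].append(e.residues if e is not None else MISSING * width)
        partitions.append(
            Partition(merged_label, "amino_acid", start, pos, PROTEIN_MODEL,
                      n_gene_groups=len(aa))
        )
    matrix = {s: "".join(rows[s]) for s in species}
    return Supermatrix(tuple(species), tuple(partitions), matrix)


def coverage_from_counts(n_sequences: int, n_groups: int, n_species: int) -> float:
    """Data coverage: sequences over (ortholog groups x species), as percent
    rounded to two decimals."""
    if n_groups <= 0 or n_species <= 0:
        raise ValueError("coverage requires at least one group and one species")
    return round(100.0 * n_sequences / (n_groups * n_species), 2)


def coverage(sm: Supermatrix) -> float:
    """Percentage of filled species-x-gene blocks in the supermatrix."""
    return coverage_from_counts(sm.n_sequences, sm.n_gene_groups, len(sm.species))


# ---------------------------------------------------------------------------
# exports

def _safe_name(name: str) -> str:
    return "_".join(name.split())


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: header line ``n_species n_sites``, then one
    ``name<space>row`` line per species."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.species)} {sm.width}\n")
        for s in sm.species:
            fh.write(f"{_safe_name(s)} {sm.matrix[s]}\n")


def read_phylip(path: str | Path) -> tuple[tuple[str, ...], dict]:
    """Read relaxed PHYLIP back into (species order, matrix)."""
    lines = Path(path).read_text().splitlines()
    n_species, n_sites = (int(x) for x in lines[0].split())
    species: list[str] = []
    matrix: dict = {}
    for line in lines[1 : 1 + n_species]:
        name, row = line.split(None, 1)
        if len(row) != n_sites:
            raise ValueError(f"row {name} has {len(row)} sites, header says {n_sites}")
        species.append(name)
        matrix[name] = row
    return tuple(species), matrix


def write_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML plain-format partition file: ``MODEL, name = start-end``."""
    with open(path, "w") as fh:
        for p in sm.partitions:
            fh.write(f"{p.model_hint}, {_safe_name(p.gene_label)} = {p.start}-{p.end}\n")


def write_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sm.species:
            fh.write(f">{_safe_name(s)}\n{sm.matrix[s]}\n")


def write_summary(sm: Supermatrix, path: str | Path) -> None:
    """Per-partition occupancy summary plus the overall coverage line."""
    with open(path, "w") as fh:
        fh.write("partition\talphabet\tstart\tend\twidth\tspecies_present\n")
        for p in sm.partitions:
            present = sum(
                1 for s in sm.species if any(c != MISSING for c in sm.block(s, p))
            )
            fh.write(
                f"{p.gene_label}\t{p.alphabet}\t{p.start}\t{p.end}"
                f"\t{p.end - p.start + 1}\t{present}\n"
            )
        fh.write(f"# species={len(sm.species)} gene_groups={sm.n_gene_groups} "
                 f"sequences={sm.n_sequences} coverage={coverage(sm):.2f}%\n")
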