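"""Data-density filters over the ortholog-group dataset.

Supermatrices built from public databases are extremely sparse.  These
filters enforce the pipeline's density rules: ortholog groups need at least
four species to be informative for rooted quartets, species contributing a
single sequence add noise without connectivity, species-rich genera are
pruned to their best-represented members, and the final species set is
anchored on the most sequence-rich ("leading") gene so every retained
species overlaps somewhere.

A :class:`Dataset` is serialized as a directory of per-gene FASTA files
plus a tab-separated exclusion log, which is also the on-disk interface
between CLI stages.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

from phylopipe.genbank_io import SeqEntry, read_fasta, write_fasta

logger = logging.getLogger(__name__)

MIN_SPECIES = 4
MAX_PER_GENUS = 15
MAX_PER_FAMILY = 2

Exclusion = tuple[str, str, str]  # (record_id, stage, reason)


@dataclass(frozen=True)
class GeneGroup:
    """A named group of putatively orthologous sequences, one per species."""

    gene_label: str
    entries: tuple[SeqEntry, ...]
    alphabet: str = "nucleotide"
    aligned: bool = False

    def __post_init__(self):
        if not isinstance(self.entries, tuple):
            object.__setattr__(self, "entries", tuple(self.entries))
        species = [e.species for e in self.entries]
        dupes = [s for s, k in Counter(species).items() if k > 1]
        if dupes:
            raise ValueError(
                f"group {self.gene_label}: more than one entry for species {dupes}"
            )
        if self.aligned:
            widths = {len(e.residues) for e in self.entries}
            if len(widths) > 1:
                raise ValueError(
                    f"group {self.gene_label}: aligned rows differ in length {widths}"
                )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(e.species for e in self.entries)

    @property
    def width(self) -> int:
        return len(self.entries[0].residues) if self.entries else 0

    def entry_for(self, species: str) -> SeqEntry | None:
        for e in self.entries:
            if e.species == species:
                return e
        return None

    def subset(self, keep: set[str]) -> "GeneGroup":
        return replace(self, entries=tuple(e for e in self.entries if e.species in keep))


@dataclass(frozen=True)
class Dataset:
    """All gene groups under filtering plus the accumulated exclusion log."""

    groups: tuple[GeneGroup, ...]
    exclusion_log: tuple[Exclusion, ...] = ()
    needs_composition_retest: bool = False

    def __post_init__(self):
        if not isinstance(self.groups, tuple):
            object.__setattr__(self, "groups", tuple(self.groups))
        if not isinstance(self.exclusion_log, tuple):
            object.__setattr__(self, "exclusion_log", tuple(self.exclusion_log))

    @property
    def species(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g.species
        return frozenset(out)

    @property
    def n_entries(self) -> int:
        return sum(len(g.entries) for g in self.groups)

    def species_group_counts(self) -> Counter:
        counts: Counter = Counter()
        for g in self.groups:
            counts.update(g.species)
        return counts

    def entries_of(self, species: str) -> list[SeqEntry]:
        return [e for g in self.groups for e in g.entries if e.species == species]


# ---------------------------------------------------------------------------
# filters

def drop_small_groups(
    ds: Dataset, min_species: int = MIN_SPECIES, stage: str = "small_groups"
) -> Dataset:
    """Remove ortholog groups with fewer than ``min_species`` species."""
    kept: list[GeneGroup] = []
    log = list(ds.exclusion_log)
    for g in ds.groups:
        if len(g.species) < min_species:
            for e in g.entries:
                log.append((e.record_id, stage,
                            f"group {g.gene_label} has {len(g.species)} species"))
        else:
            kept.append(g)
    return replace(ds, groups=tuple(kept), exclusion_log=tuple(log))


def drop_singleton_species(
    ds: Dataset,
    min_species: int = MIN_SPECIES,
    fixpoint: bool = False,
) -> Dataset:
    """Remove species contributing a single sequence, then small groups.

    One pass applies the singleton rule followed by the small-group rule,
    in that order.  With ``fixpoint=True`` the pair is repeated until the
    dataset is stable (each removal can create new singletons).
    """
    while True:
        counts = ds.species_group_counts()
        singletons = {s for s, k in counts.items() if k == 1}
        log = list(ds.exclusion_log)
        groups: list[GeneGroup] = []
        for g in ds.groups:
            kept_entries = []
            for e in g.entries:
                if e.species in singletons:
                    log.append((e.record_id, "singleton_species",
                                f"{e.species} has a single sequence in the dataset"))
                else:
                    kept_entries.append(e)
            groups.append(replace(g, entries=tuple(kept_entries)))
        out = drop_small_groups(
            replace(ds, groups=tuple(groups), exclusion_log=tuple(log)),
            min_species=min_species,
        )
        if not fixpoint or out.n_entries == ds.n_entries:
            return out
        ds = out


def genus_of(species: str) -> str:
    """Genus under the ``Genus_epithet`` naming convention."""
    genus, _, epithet = species.partition("_")
    if not epithet:
        logger.warning("species %r has no epithet; treated as its own genus", species)
    return genus


def representation_rank(ds: Dataset, species: str) -> tuple[int, int]:
    """(sequence count, total residue length) of a species in the dataset."""
    entries = ds.entries_of(species)
    return len(entries), sum(len(e.ungapped()) for e in entries)


def prune_genera(ds: Dataset, max_species: int = MAX_PER_GENUS) -> Dataset:
    """Prune species-rich genera to their best-represented members.

    Within each genus of more than ``max_species`` species, keep the
    ``max_species`` ranked highest by (1) number of sequences in the
    dataset, then (2) overall residue length; remaining ties break
    alphabetically by species name.
    """
    by_genus: dict[str, list[str]] = defaultdict(list)
    for s in sorted(ds.species):
        by_genus[genus_of(s)].append(s)
    drop: set[str] = set()
    for genus, members in by_genus.items():
        if len(members) <= max_species:
            continue
        ranked = sorted(
            members,
            key=lambda s: (*(-v for v in representation_rank(ds, s)), s),
        )
        drop.update(ranked[max_species:])
    log = list(ds.exclusion_log)
    groups: list[GeneGroup] = []
    for g in ds.groups:
        kept = []
        for e in g.entries:
            if e.species in drop:
                log.append((e.record_id, "prune_genera",
                            f"genus {genus_of(e.species)} pruned to {max_species} species"))
            else:
                kept.append(e)
        groups.append(replace(g, entries=tuple(kept)))
    return replace(ds, groups=tuple(groups), exclusion_log=tuple(log))


def reduce_to_leading_gene(ds: Dataset) -> Dataset:
    """Restrict the dataset to species present in the leading gene group.

    The leading group is the one with the most species (ties broken
    alphabetically by gene label); keeping only its species guarantees
    every retained species overlaps with every other in at least this one
    gene fragment.
    """
    if not ds.groups:
        raise ValueError("cannot reduce an empty dataset to its leading gene")
    leading = min(ds.groups, key=lambda g: (-len(g.species), g.gene_label))
    keep = leading.species
    log = list(ds.exclusion_log)
    groups: list[GeneGroup] = []
    for g in ds.groups:
        kept = []
        for e in g.entries:
            if e.species in keep:
                kept.append(e)
            else:
                log.append((e.record_id, "leading_gene",
                            f"{e.species} absent from leading group {leading.gene_label}"))
        groups.append(replace(g, entries=tuple(kept)))
    return replace(ds, groups=tuple(groups), exclusion_log=tuple(log))


def reinclude_families(
    core: Dataset,
    pool: Dataset,
    target_families: list[str],
    max_per_family: int = MAX_PER_FAMILY,
) -> Dataset:
    """Add back representatives of families lost during filtering.

    For each target family, up to ``max_per_family`` species are selected
    from the pre-filter pool by the same representation ranking used for
    genus pruning, and their sequences are re-inserted into the matching
    core gene groups.  The result is flagged for a repeated composition
    homogeneity test.
    """
    core_species = core.species
    core_genes = {g.gene_label for g in core.groups}
    pool_by_family: dict[str, set[str]] = defaultdict(set)
    for g in pool.groups:
        for e in g.entries:
            pool_by_family[e.family].add(e.species)
    additions: list[str] = []
    for family in target_families:
        candidates = sorted(pool_by_family.get(family, set()) - core_species)
        if not candidates:
            logger.warning("family %s has no candidate species in the pool; skipped", family)
            continue
        ranked = sorted(
            candidates,
            key=lambda s: (*(-v for v in representation_rank(pool, s)), s),
        )
        additions.extend(ranked[:max_per_family])
    groups: list[GeneGroup] = []
    for g in core.groups:
        extra = []
        pool_group = next((p for p in pool.groups if p.gene_label == g.gene_label), None)
        if pool_group is not None:
            for s in additions:
                e = pool_group.entry_for(s)
                if e is not None and g.entry_for(s) is None:
                    extra.append(e)
        groups.append(replace(g, entries=tuple(list(g.entries) + extra)))
    for g in pool.groups:
        if g.gene_label not in core_genes:
            found = [s for s in additions if g.entry_for(s) is not None]
            if found:
                logger.info(
                    "gene %s not in the core dataset; sequences of %s not re-included",
                    g.gene_label, found,
                )
    return replace(core, groups=tuple(groups), needs_composition_retest=True)


# ---------------------------------------------------------------------------
# directory serialization

EXCLUSION_FILE = "exclusions.tsv"


def save_dataset(ds: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g in ds.groups:
        write_fasta(g.entries, directory / f"{g.gene_label}.fasta")
    with open(directory / EXCLUSION_FILE, "w") as fh:
        fh.write("record_id\tstage\treason\n")
        for record_id, stage, reason in ds.exclusion_log:
            fh.write(f"{record_id}\t{stage}\t{reason}\n")


def load_dataset(directory: str | Path, is_mitochondrial: bool = False) -> Dataset:
    """Load a per-gene FASTA directory written by :func:`save_dataset`.

    A group is taken as aligned when all its rows have equal length and a
    gap character occurs somewhere (unaligned equal-length collections are
    rare enough that callers can override via re-construction).
    """
    directory = Path(directory)
    groups: list[GeneGroup] = []
    for path in sorted(directory.glob("*.fasta")):
        entries = read_fasta(path, gene_label=path.stem, is_mitochondrial=is_mitochondrial)
        if not entries:
            continue
        widths = {len(e.residues) for e in entries}
        has_gaps = any(c in e.residues for e in entries for c in "-?")
        aligned = len(widths) == 1 and (has_gaps or len(entries) > 1)
        alphabet = entries[0].alphabet
        groups.append(GeneGroup(path.stem, tuple(entries), alphabet=alphabet, aligned=aligned))
    log: list[Exclusion] = []
    exc = directory / EXCLUSION_FILE
    if exc.exists():
        for line in exc.read_text().splitlines()[1:]:
            record_id, stage, reason = line.split("\t", 2)
            log.append((record_id, stage, reason))
    return Dataset(tuple(groups), tuple(log))
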