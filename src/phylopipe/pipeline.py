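"""Stage orchestration: the pre-alignment path and the post-alignment path.

The pipeline is split where the external tools sit.  The pre-alignment
path takes GenBank flat files to unaligned per-gene FASTA (split, orient,
pick longest per species, translate coding genes); the user then aligns
those files with their aligner of choice.  The post-alignment path takes a
directory of aligned per-gene FASTA through masking, clique-based overlap
selection, composition filtering, density filters and concatenation into
the final supermatrix.

Every stage records a manifest row (entries in, entries out, exclusions)
and the rows must reconcile: in = out + excluded at every stage.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

from phylopipe import alignment_mask, composition_filter, overlap_clique, supermatrix
from phylopipe.config import PipelineConfig
from phylopipe.density_filters import (
    Dataset,
    GeneGroup,
    drop_singleton_species,
    drop_small_groups,
    prune_genera,
    reduce_to_leading_gene,
    save_dataset,
)
from phylopipe.fixtures import MITO_CODING
from phylopipe.genbank_io import SeqEntry, read_genbank, split_multigene, write_fasta
from phylopipe.sequence_qc import check_orientation, choose_longest, translate_cds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageManifest:
    stage: str
    entries_in: int
    entries_out: int
    entries_excluded: int

    @property
    def reconciles(self) -> bool:
        return self.entries_in == self.entries_out + self.entries_excluded


def _manifest(stage: str, n_in: int, n_out: int) -> StageManifest:
    return StageManifest(stage, n_in, n_out, n_in - n_out)


# ---------------------------------------------------------------------------
# pre-alignment path (GenBank -> unaligned per-gene FASTA)

def run_prealign(
    genbank_paths: list[str | Path],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    templates: dict[str, list[SeqEntry]] | None = None,
) -> tuple[Dataset, list[StageManifest]]:
    """Split records, orient, select longest per species, translate coding.

    ``templates`` maps gene labels to ordered template sequences for the
    orientation check; genes without templates skip that check.  Writes
    the unaligned per-gene files plus, for coding mitochondrial genes, the
    translated amino-acid files to align, then stops: alignment itself is
    an external-tool step.
    """
    config = config or PipelineConfig()
    manifests: list[StageManifest] = []
    log: list[tuple[str, str, str]] = []

    entries: list[SeqEntry] = []
    n_records = 0
    for path in genbank_paths:
        for record in read_genbank(path):
            n_records += 1
            entries.extend(split_multigene(record))
    manifests.append(_manifest("split", len(entries), len(entries)))

    if templates:
        kept: list[SeqEntry] = []
        for e in entries:
            if e.gene_label in templates:
                result = check_orientation(
                    e, templates[e.gene_label],
                    min_match=config.min_match, max_templates=config.max_templates,
                )
                if result.status == "discarded":
                    log.append((e.record_id, "orientation",
                                f"no match > {config.min_match} nt on either strand"))
                    continue
                kept.append(result.entry)
            else:
                kept.append(e)
        manifests.append(_manifest("orientation", len(entries), len(kept)))
        entries = kept

    by_key: dict[tuple[str, str], list[SeqEntry]] = defaultdict(list)
    for e in entries:
        by_key[(e.species, e.gene_label)].append(e)
    longest: list[SeqEntry] = []
    for key in sorted(by_key):
        chosen = choose_longest(by_key[key])
        longest.append(chosen)
        for e in by_key[key]:
            if e is not chosen:
                log.append((e.record_id, "choose_longest",
                            f"shorter duplicate of {e.species}/{e.gene_label}"))
    manifests.append(_manifest("choose_longest", len(entries), len(longest)))

    by_gene: dict[str, list[SeqEntry]] = defaultdict(list)
    for e in longest:
        by_gene[e.gene_label].append(e)
    groups = []
    for gene in sorted(by_gene):
        group_entries = tuple(sorted(by_gene[gene], key=lambda e: e.species))
        groups.append(GeneGroup(gene, group_entries, alphabet="nucleotide"))
    ds = drop_small_groups(
        Dataset(tuple(groups), tuple(log)), min_species=config.min_species
    )
    manifests.append(_manifest("small_groups", len(longest), ds.n_entries))
    n = ds.n_entries
    ds = drop_singleton_species(ds, min_species=config.min_species)
    manifests.append(_manifest("singleton_species", n, ds.n_entries))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_dataset(ds, out_dir)
    translated_dir = out_dir / "translated"
    for g in ds.groups:
        if g.gene_label in MITO_CODING:
            translated_dir.mkdir(exist_ok=True)
            aa = [translate_cds(e) for e in g.entries if e.source_frame]
            if aa:
                write_fasta(aa, translated_dir / f"{g.gene_label}.fasta")
    logger.info(
        "pre-alignment path done (%d records): align the per-gene FASTA files in %s "
        "with an external aligner, then run the post-alignment path on the "
        "aligned directory", n_records, out_dir,
    )
    return ds, manifests


# ---------------------------------------------------------------------------
# post-alignment path (aligned per-gene FASTA -> supermatrix)

def _apply_masking(ds: Dataset, config: PipelineConfig) -> Dataset:
    """Gap-saturated column masking, then third-position removal for
    mitochondrial coding genes.

    Coding groups have gappy columns replaced by the missing symbol rather
    than deleted so the codon phase survives for the third-position step.
    """
    groups = []
    for g in ds.groups:
        coding = g.gene_label in MITO_CODING and g.alphabet == "nucleotide"
        masked, _ = alignment_mask.mask_gappy_sites(
            g, config.max_gap_fraction, mask_instead_of_delete=coding
        )
        if coding and masked.width % 3 == 0:
            masked = alignment_mask.mask_third_positions(masked)
        groups.append(masked)
    return replace(ds, groups=tuple(groups))


def _apply_cliques(ds: Dataset, config: PipelineConfig) -> Dataset:
    """First+second maximum clique selection per gene; residual discarded.

    The two cliques of a gene share one alignment, so their survivors are
    kept as clique-tagged sub-groups for the composition test and merged
    back per gene afterwards.
    """
    groups = []
    log = list(ds.exclusion_log)
    for g in ds.groups:
        first, second, residual = overlap_clique.split_by_cliques(g, config.overlap)
        for sp in sorted(residual):
            e = g.entry_for(sp)
            log.append((e.record_id, "overlap_clique",
                        f"{sp} outside both maximum cliques of {g.gene_label}"))
        kept = tuple(e for e in g.entries if e.species in first.species | second.species)
        groups.append(replace(g, entries=kept))
    return replace(ds, groups=tuple(groups), exclusion_log=tuple(log))


def _apply_composition(ds: Dataset, config: PipelineConfig) -> Dataset:
    groups = []
    log = list(ds.exclusion_log)
    for g in ds.groups:
        if g.alphabet != "nucleotide" or len(g.entries) < 2:
            groups.append(g)
            continue
        g1, g2, discarded, _reports = composition_filter.composition_partition(
            g, config.alpha
        )
        for sp in sorted(discarded):
            e = g.entry_for(sp)
            log.append((e.record_id, "composition",
                        f"{sp} compositionally deviant in {g.gene_label} (both passes)"))
        keep = g1.species | g2.species
        groups.append(replace(g, entries=tuple(e for e in g.entries if e.species in keep)))
    return replace(ds, groups=tuple(groups), exclusion_log=tuple(log))


def run_postalign(
    ds: Dataset,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[supermatrix.Supermatrix, list[StageManifest]]:
    """Aligned dataset -> masked, clique- and composition-filtered,
    density-enforced, concatenated supermatrix."""
    config = config or PipelineConfig()
    manifests: list[StageManifest] = []

    n = ds.n_entries
    ds = _apply_masking(ds, config)
    manifests.append(_manifest("masking", n, ds.n_entries))

    n = ds.n_entries
    ds = _apply_cliques(ds, config)
    manifests.append(_manifest("overlap_clique", n, ds.n_entries))

    n = ds.n_entries
    ds = _apply_composition(ds, config)
    manifests.append(_manifest("composition", n, ds.n_entries))

    n = ds.n_entries
    ds = drop_singleton_species(ds, min_species=config.min_species)
    manifests.append(_manifest("density", n, ds.n_entries))

    n = ds.n_entries
    ds = prune_genera(ds, max_species=config.max_per_genus)
    manifests.append(_manifest("prune_genera", n, ds.n_entries))

    n = ds.n_entries
    ds = reduce_to_leading_gene(ds)
    manifests.append(_manifest("leading_gene", n, ds.n_entries))

    groups = [g for g in ds.groups if g.entries]
    sm = supermatrix.concatenate(groups, merge_amino_acid_partitions=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        supermatrix.write_phylip(sm, out_dir / "supermatrix.phy")
        supermatrix.write_partitions(sm, out_dir / "partitions.txt")
        supermatrix.write_fasta(sm, out_dir / "supermatrix.fasta")
        supermatrix.write_summary(sm, out_dir / "summary.tsv")
        save_dataset(ds, out_dir / "final_dataset")
        write_manifests(manifests, out_dir / "manifests.tsv")
    return sm, manifests


def write_manifests(manifests: list[StageManifest], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tentries_in\tentries_out\tentries_excluded\n")
        for m in manifests:
            fh.write(f"{m.stage}\t{m.entries_in}\t{m.entries_out}\t{m.entries_excluded}\n")
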