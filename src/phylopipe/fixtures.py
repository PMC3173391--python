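"""Deterministic synthetic data with known ground truth for every stage.

Real inputs to the pipeline are GenBank downloads; none are needed here.
The generators emulate the structural properties the pipeline's stages
react to — multi-gene mitochondrial-style records with CDS/tRNA/rRNA
features on both strands and shifted reading frames, aligned gene groups
with engineered overlap (planted maximum cliques), and sequence groups with
planted base-composition outliers — while returning the ground truth
alongside so tests can assert exact recovery.  All generators take a
mandatory seed and are byte-deterministic.
"""

from __future__ import annotations

import random
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from phylopipe.density_filters import Dataset, GeneGroup
from phylopipe.genbank_io import FeatureSpan, GenBankRecord, SeqEntry

MITO_CODING = {
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
}

_CDS_NAMES = ["COX1", "COX2", "COX3", "CYTB", "ND1", "ND2", "ND3", "ATP6"]
_TRNA_NAMES = ["tRNA-Leu", "tRNA-Lys", "tRNA-Asp", "tRNA-Gly"]
_RRNA_NAMES = ["rrnS", "rrnL"]

# stop codons of the invertebrate mitochondrial code (table 5)
_STOPS_T5 = {"TAA", "TAG"}


def _random_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_cds(rng: random.Random, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_bases(rng, 3)
        if c not in _STOPS_T5:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def make_mito_record(
    seed: int,
    n_genes: int = 3,
    strand_flips: tuple[int, ...] = (),
    codon_start_offsets: dict[int, int] | None = None,
    organism: str = "Apis mellifera",
    lineage: tuple[str, ...] = ("Eukaryota", "Arthropoda", "Insecta", "Hymenoptera", "Apidae"),
) -> tuple[GenBankRecord, dict[str, str]]:
    """A mitochondrial-style multi-gene record with known per-gene truth.

    Genes cycle through CDS / tRNA / rRNA kinds.  ``strand_flips`` lists
    0-based gene indices placed on the minus strand (the record carries the
    reverse complement; the returned ground truth is always the sense
    strand).  ``codon_start_offsets`` maps gene indices to a codon_start of
    2 or 3, implemented by prepending offset-1 extra 5' bases to the CDS
    feature span.
    """
    rng = random.Random(seed)
    codon_start_offsets = codon_start_offsets or {}
    pieces: list[str] = []
    features: list[FeatureSpan] = []
    ground_truth: dict[str, str] = {}
    pos = 0
    kinds = ["CDS", "tRNA", "rRNA"]
    names = {"CDS": list(_CDS_NAMES), "tRNA": list(_TRNA_NAMES), "rRNA": list(_RRNA_NAMES)}
    for i in range(n_genes):
        kind = kinds[i % 3]
        label = names[kind].pop(0) if names[kind] else f"{kind}_{i}"
        offset = codon_start_offsets.get(i, 1)
        if kind == "CDS":
            seq = _random_bases(rng, offset - 1) + _random_cds(rng, rng.randint(40, 80))
        elif kind == "tRNA":
            seq = _random_bases(rng, rng.randint(60, 72))
        else:
            seq = _random_bases(rng, rng.randint(300, 500))
        spacer = _random_bases(rng, rng.randint(5, 20))
        start = pos + len(spacer) + 1
        end = start + len(seq) - 1
        flipped = i in strand_flips
        stored = str(Seq(seq).reverse_complement()) if flipped else seq
        pieces.append(spacer + stored)
        pos = end
        features.append(
            FeatureSpan(
                kind=kind,
                gene_label=label,
                start=start,
                end=end,
                strand="-" if flipped else "+",
                codon_start=offset if kind == "CDS" else None,
                transl_table=5 if kind == "CDS" else None,
            )
        )
        ground_truth[label] = seq
    residues = "".join(pieces) + _random_bases(rng, rng.randint(5, 20))
    record = GenBankRecord(
        record_id=f"SYN{seed:06d}",
        organism=organism,
        lineage=lineage,
        residues=residues,
        features=tuple(features),
        is_mitochondrial=True,
    )
    return record, ground_truth


def write_genbank_flatfile(records: list[GenBankRecord], path: str | Path) -> None:
    """Render synthetic records as a GenBank flat file (for reader tests)."""
    out = []
    for r in records:
        rec = SeqRecord(
            Seq(r.residues),
            id=r.record_id,
            name=r.record_id.replace(".", "_")[:16],
            description=f"{r.organism} synthetic record",
            annotations={
                "organism": r.organism,
                "taxonomy": list(r.lineage),
                "molecule_type": "DNA",
            },
        )
        source_quals = {"organism": [r.organism]}
        if r.is_mitochondrial:
            source_quals["organelle"] = ["mitochondrion"]
        rec.features.append(
            SeqFeature(
                FeatureLocation(0, len(r.residues), strand=1),
                type="source",
                qualifiers=source_quals,
            )
        )
        for f in r.features:
            quals = {"gene": [f.gene_label]}
            if f.kind == "CDS":
                quals["codon_start"] = [str(f.codon_start or 1)]
                if f.transl_table:
                    quals["transl_table"] = [str(f.transl_table)]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1),
                    type=f.kind,
                    qualifiers=quals,
                )
            )
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# overlap scenarios

def make_overlap_scenario(
    seed: int,
    n_species: int = 10,
    planted_clique_size: int = 6,
    threshold: int = 100,
    gene_label: str = "COX1",
) -> tuple[GeneGroup, frozenset[str]]:
    """An aligned group whose overlap graph has a known unique maximum clique.

    Planted species share one window of exactly ``threshold`` columns, so
    all their pairwise overlaps meet the threshold.  The remaining species
    occupy windows staggered by half the threshold: they overlap nobody by
    the full threshold, so (for planted sizes >= 2) the planted set is the
    unique maximum clique.
    """
    if planted_clique_size > n_species:
        raise ValueError("planted clique larger than the species set")
    rng = random.Random(seed)
    names = [f"Species_{i:02d}" for i in range(n_species)]
    planted = frozenset(rng.sample(names, planted_clique_size))
    outsiders = [s for s in names if s not in planted]
    step = max(threshold // 2, 1)
    width = threshold + (len(outsiders)) * step + threshold
    entries = []
    for s in names:
        if s in planted:
            start = 0
        else:
            start = threshold + outsiders.index(s) * step
        window = _random_bases(rng, threshold)
        row = "-" * start + window + "-" * (width - start - threshold)
        entries.append(
            SeqEntry(
                species=s,
                family="Syntheticidae",
                record_id=f"ov{seed}_{s}",
                gene_label=gene_label,
                alphabet="nucleotide",
                residues=row,
            )
        )
    group = GeneGroup(gene_label, tuple(entries), alphabet="nucleotide", aligned=True)
    return group, planted


# ---------------------------------------------------------------------------
# composition scenarios

def _multinomial_sequence(rng: random.Random, length: int, p: tuple[float, ...]) -> str:
    bases = "ACGT"
    cum = []
    total = 0.0
    for x in p:
        total += x
        cum.append(total)
    out = []
    for _ in range(length):
        u = rng.random() * total
        for b, c in zip(bases, cum):
            if u <= c:
                out.append(b)
                break
    return "".join(out)


def _exact_frequency_sequence(rng: random.Random, length: int, p: tuple[float, ...]) -> str:
    counts = [int(round(length * x)) for x in p]
    counts[0] += length - sum(counts)
    chars = list("".join(b * c for b, c in zip("ACGT", counts)))
    rng.shuffle(chars)
    return "".join(chars)


def make_composition_scenario(
    seed: int,
    n_homogeneous: int = 20,
    n_outliers: int = 3,
    outlier_gc_shift: float = 0.20,
    length: int = 400,
    gene_label: str = "RRNS",
    exact_frequencies: bool = False,
) -> tuple[GeneGroup, frozenset[str]]:
    """A nucleotide group with planted GC-shifted composition outliers.

    Homogeneous sequences draw bases uniformly; outliers draw from
    frequencies with G and C each raised by ``outlier_gc_shift``/2 at the
    expense of A and T, a deviation far beyond multinomial noise for the
    default shift and length.

    With ``exact_frequencies`` every sequence realizes its target
    frequencies exactly (only the base arrangement is random): homogeneous
    members then have identical composition, so the filter must exclude
    exactly the planted outliers with no sampling-noise false positives.
    With multinomial sampling, homogeneous members are only homogeneous on
    average and the test keeps its nominal per-sequence type-I rate.
    """
    rng = random.Random(seed)
    base = (0.25, 0.25, 0.25, 0.25)
    s = outlier_gc_shift / 2.0
    shifted = (0.25 - s, 0.25 + s, 0.25 + s, 0.25 - s)
    draw = _exact_frequency_sequence if exact_frequencies else _multinomial_sequence
    entries = []
    outliers = []
    for i in range(n_homogeneous):
        name = f"Homog_{i:02d}"
        entries.append(SeqEntry(
            species=name, family="Homogenidae", record_id=f"cs{seed}_h{i}",
            gene_label=gene_label, alphabet="nucleotide",
            residues=draw(rng, length, base),
        ))
    for i in range(n_outliers):
        name = f"Outlier_{i:02d}"
        outliers.append(name)
        entries.append(SeqEntry(
            species=name, family="Deviantidae", record_id=f"cs{seed}_o{i}",
            gene_label=gene_label, alphabet="nucleotide",
            residues=draw(rng, length, shifted),
        ))
    group = GeneGroup(gene_label, tuple(entries), alphabet="nucleotide", aligned=False)
    return group, frozenset(outliers)


# ---------------------------------------------------------------------------
# end-to-end pipeline fixture

def make_aligned_dataset(seed: int) -> Dataset:
    """A small pre-aligned multi-gene dataset exercising every filter.

    Contents: a codon-preserving mitochondrial COX1 alignment shared by
    most species (the eventual leading gene), two rRNA groups with partial
    species overlap and one strong GC outlier, a nuclear 18S group, and an
    ND2 group with only three species that the small-group rule removes.
    """
    rng = random.Random(seed)
    genera = ["Apis", "Bombus", "Vespula", "Formica", "Nasonia", "Cotesia"]
    species = []
    for g in genera:
        for j in (1, 2):
            species.append(f"{g}_sp{j}")
    families = {
        "Apis": "Apidae", "Bombus": "Apidae", "Vespula": "Vespidae",
        "Formica": "Formicidae", "Nasonia": "Pteromalidae", "Cotesia": "Braconidae",
    }

    def entry(sp, gene, residues, mito=False):
        return SeqEntry(
            species=sp, family=families[sp.split("_")[0]], record_id=f"fx{seed}_{sp}_{gene}",
            gene_label=gene, alphabet="nucleotide", residues=residues,
            is_mitochondrial=mito,
        )

    # COX1: 300 columns, codon-preserving, gapless for 10 of 12 species;
    # the last two cover only 60 columns and fail the 100-position overlap.
    cox1_entries = []
    for i, sp in enumerate(species):
        if i < 10:
            row = _random_bases(rng, 300)
        else:
            row = _random_bases(rng, 60) + "-" * 240
        cox1_entries.append(entry(sp, "COX1", row, mito=True))
    cox1 = GeneGroup("COX1", tuple(cox1_entries), alphabet="nucleotide", aligned=True)

    # RRNS: 200 columns over 8 species, one extreme GC outlier (Cotesia_sp1)
    rrns_entries = []
    for sp in species[:7]:
        rrns_entries.append(entry(sp, "RRNS", _multinomial_sequence(rng, 200, (0.25,) * 4), mito=True))
    rrns_entries.append(entry("Cotesia_sp1", "RRNS",
                              _multinomial_sequence(rng, 200, (0.05, 0.45, 0.45, 0.05)),
                              mito=True))
    rrns = GeneGroup("RRNS", tuple(rrns_entries), alphabet="nucleotide", aligned=True)

    # RRNL: 150 columns over 6 species
    rrnl_entries = [
        entry(sp, "RRNL", _multinomial_sequence(rng, 150, (0.25,) * 4), mito=True)
        for sp in species[2:8]
    ]
    rrnl = GeneGroup("RRNL", tuple(rrnl_entries), alphabet="nucleotide", aligned=True)

    # 18S: 180 columns over 6 species (keeps the nuclear path represented)
    s18_entries = [
        entry(sp, "18S", _multinomial_sequence(rng, 180, (0.25,) * 4))
        for sp in species[4:10]
    ]
    s18 = GeneGroup("18S", tuple(s18_entries), alphabet="nucleotide", aligned=True)

    # ND2: only three species; the small-group rule must delete it
    nd2_entries = [
        entry(sp, "ND2", _random_bases(rng, 120), mito=True) for sp in species[:3]
    ]
    nd2 = GeneGroup("ND2", tuple(nd2_entries), alphabet="nucleotide", aligned=True)

    return Dataset((cox1, rrns, rrnl, s18, nd2))


def write_ground_truth(truth: dict[str, str], path: str | Path) -> None:
    """Sidecar tab-separated ground-truth table (label, sequence)."""
    with open(path, "w") as fh:
        fh.write("label\tsequence\n")
        for label in sorted(truth):
            fh.write(f"{label}\t{truth[label]}\n")
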