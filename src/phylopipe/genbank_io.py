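"""GenBank flat-file and FASTA input/output with standardized headers.

GenBank records arrive as multi-gene regions (whole mitochondrial genomes,
rRNA cassettes) whose feature tables locate individual genes.  This module
parses those records, splits them into single-gene sequence entries reading
5'->3' on the gene's sense strand, and renders every entry under the
pipeline-wide header convention ``species,family,record_id``.

Coordinates follow each format's native convention: GenBank feature spans are
1-based inclusive at the boundary and converted to 0-based half-open slices
internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDE_CHARS = set("ACGTUNRYSWKMBDHV")
GAP_CHARS = set("-?")

_FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "misc")


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be interpreted."""


@dataclass(frozen=True)
class FeatureSpan:
    """One gene-bearing feature of a GenBank record.

    ``start``/``end`` are 1-based inclusive; ``parts`` carries the exon
    spans of a ``join(...)`` location in annotation order (a single-span
    feature has one part equal to (start, end)).  ``codon_start`` is the
    1-based reading-frame offset and only meaningful for CDS features.
    """

    kind: str
    gene_label: str
    start: int
    end: int
    strand: str = "+"
    codon_start: int | None = None
    transl_table: int | None = None
    parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.kind not in _FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.codon_start is not None and self.kind != "CDS":
            raise ValueError("codon_start is defined only for CDS features")
        if not self.parts:
            object.__setattr__(self, "parts", ((self.start, self.end),))


@dataclass(frozen=True)
class GenBankRecord:
    """A parsed GenBank entry: identity, taxonomy, residues and features."""

    record_id: str
    organism: str
    lineage: tuple[str, ...]
    residues: str
    features: tuple[FeatureSpan, ...] = ()
    is_mitochondrial: bool = False

    def __post_init__(self):
        if not self.organism:
            raise GenBankParseError(f"record {self.record_id}: empty organism")
        n = len(self.residues)
        for f in self.features:
            for s, e in f.parts:
                if not (1 <= s <= e <= n):
                    raise GenBankParseError(
                        f"record {self.record_id}: feature {f.gene_label!r} "
                        f"span {s}..{e} outside 1..{n}"
                    )


@dataclass(frozen=True)
class SeqEntry:
    """A single-gene sequence with standardized identity.

    The FASTA header renders as ``species,family,record_id``; commas and
    whitespace inside any component are replaced by underscores at
    construction so the rendering is always unambiguous.
    """

    species: str
    family: str
    record_id: str
    gene_label: str
    alphabet: str  # "nucleotide" | "amino_acid"
    residues: str
    source_frame: int | None = None
    source_table: int | None = None
    is_mitochondrial: bool = False

    def __post_init__(self):
        if not self.residues:
            raise ValueError("SeqEntry residues must be non-empty")
        if self.alphabet not in ("nucleotide", "amino_acid"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        for name in ("species", "family", "record_id"):
            value = getattr(self, name)
            clean = "_".join(str(value).replace(",", "_").split())
            object.__setattr__(self, name, clean)

    @property
    def header(self) -> str:
        return f"{self.species},{self.family},{self.record_id}"

    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)

    def with_residues(self, residues: str, **kw) -> "SeqEntry":
        return replace(self, residues=residues, **kw)


# ---------------------------------------------------------------------------
# gene-label normalization

def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("phylopipe").joinpath("data/gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        synonym, canonical = line.split("\t")
        table[synonym.casefold()] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None


def normalize_gene_label(label: str) -> str:
    """Map a raw gene/product annotation onto a canonical gene label.

    Case-folds, strips whitespace, and resolves common synonyms (COI, CO1,
    cox1 -> COX1 ...) through an editable table shipped with the package;
    unknown labels are uppercased with internal whitespace collapsed to
    underscores.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = " ".join(label.split()).casefold()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    return "_".join(label.split()).upper() or "UNKNOWN_GENE"


# ---------------------------------------------------------------------------
# family resolution

def default_family_resolver(lineage: Sequence[str]) -> str | None:
    """Return the lineage entry carrying the animal family suffix ``-idae``."""
    for name in lineage:
        if name.endswith("idae"):
            return name
    return None


def standardize_header(
    record: GenBankRecord,
    family_resolver: Callable[[Sequence[str]], str | None] = default_family_resolver,
) -> tuple[str, str, str]:
    """Produce the standardized ``(species, family, record_id)`` triple.

    Species is the organism with whitespace replaced by underscores; the
    family is looked up in the taxonomy lineage (fallback
    ``unknown_family`` when no lineage entry matches).
    """
    species = "_".join(record.organism.replace(",", "_").split())
    family = family_resolver(record.lineage) or "unknown_family"
    return species, family, record.record_id


# ---------------------------------------------------------------------------
# GenBank reading

def read_genbank(path: str | Path) -> list[GenBankRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    Raises :class:`GenBankParseError` naming the offending LOCUS on a
    malformed record; an empty file yields an empty list.
    """
    records: list[GenBankRecord] = []
    current = "<unknown LOCUS>"
    try:
        for rec in SeqIO.parse(str(path), "genbank"):
            current = rec.name or rec.id or current
            records.append(_convert_record(rec))
    except GenBankParseError:
        raise
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise GenBankParseError(f"malformed GenBank record near {current}: {exc}") from exc
    return records


def _convert_record(rec) -> GenBankRecord:
    organism = rec.annotations.get("organism", "")
    if not organism or organism == ".":
        raise GenBankParseError(f"record {rec.name or rec.id}: missing ORGANISM")
    lineage = tuple(rec.annotations.get("taxonomy", ()))
    is_mito = False
    features: list[FeatureSpan] = []
    for f in rec.features:
        if f.type == "source":
            organelle = (f.qualifiers.get("organelle") or [""])[0]
            if "mitochondri" in organelle.lower():
                is_mito = True
            continue
        if f.type in ("CDS", "rRNA", "tRNA"):
            kind = f.type
        elif f.type in ("gene",):
            continue  # redundant with the CDS/rRNA/tRNA feature itself
        else:
            kind = "misc"
        quals = f.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("locus_tag") or [""])[0]
        parts = tuple(
            (int(p.start) + 1, int(p.end)) for p in sorted(
                f.location.parts, key=lambda p: int(p.start)
            )
        )
        codon_start = None
        table = None
        if kind == "CDS":
            codon_start = int((quals.get("codon_start") or ["1"])[0])
            if "transl_table" in quals:
                table = int(quals["transl_table"][0])
        features.append(
            FeatureSpan(
                kind=kind,
                gene_label=label,
                start=min(s for s, _ in parts),
                end=max(e for _, e in parts),
                strand="-" if f.location.strand == -1 else "+",
                codon_start=codon_start,
                transl_table=table,
                parts=parts,
            )
        )
    return GenBankRecord(
        record_id=rec.id or rec.name,
        organism=organism,
        lineage=lineage,
        residues=str(rec.seq).upper(),
        features=tuple(features),
        is_mitochondrial=is_mito,
    )


# ---------------------------------------------------------------------------
# record splitting

def extract_feature(record: GenBankRecord, feat: FeatureSpan) -> str:
    """Residues of one feature, 5'->3' on the gene's sense strand.

    Exons of a joined location are concatenated in annotation order before
    the whole concatenation is reverse-complemented for minus-strand
    features (the GenBank ``complement(join(...))`` reading).
    """
    pieces = [record.residues[s - 1 : e] for s, e in feat.parts]
    seq = "".join(pieces)
    if feat.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def split_multigene(
    record: GenBankRecord,
    family_resolver: Callable[[Sequence[str]], str | None] = default_family_resolver,
) -> list[SeqEntry]:
    """Split a multi-gene record into one :class:`SeqEntry` per gene feature.

    Qualifying features are CDS, rRNA and tRNA; minus-strand features are
    reverse-complemented so every entry reads 5'->3' on its sense strand.
    CDS entries carry the annotated reading frame and genetic-code table
    (defaulting to the invertebrate-mitochondrial table 5 for mitochondrial
    records, table 1 otherwise).
    """
    species, family, record_id = standardize_header(record, family_resolver)
    entries: list[SeqEntry] = []
    for feat in record.features:
        if feat.kind not in ("CDS", "rRNA", "tRNA"):
            continue
        residues = extract_feature(record, feat)
        frame = table = None
        if feat.kind == "CDS":
            frame = feat.codon_start or 1
            table = feat.transl_table or (5 if record.is_mitochondrial else 1)
        entries.append(
            SeqEntry(
                species=species,
                family=family,
                record_id=record_id,
                gene_label=normalize_gene_label(feat.gene_label),
                alphabet="nucleotide",
                residues=residues,
                source_frame=frame,
                source_table=table,
                is_mitochondrial=record.is_mitochondrial,
            )
        )
    if not entries:
        logger.info("record %s: no CDS/rRNA/tRNA features, skipped", record.record_id)
    return entries


# ---------------------------------------------------------------------------
# FASTA

def infer_alphabet(residues: str) -> str:
    chars = set(residues.upper()) - GAP_CHARS
    return "nucleotide" if chars <= NUCLEOTIDE_CHARS else "amino_acid"


def write_fasta(entries: Iterable[SeqEntry], path: str | Path) -> None:
    """Write entries under the ``>species,family,record_id`` header."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header}\n{e.residues}\n")


def read_fasta(
    path: str | Path,
    gene_label: str = "",
    is_mitochondrial: bool = False,
) -> list[SeqEntry]:
    """Read a pipeline FASTA file; residues are uppercased on read.

    Headers are the comma-separated ``species,family,record_id`` triple
    (missing components become empty strings).  Duplicate headers raise a
    warning but both entries are kept.
    """
    entries: list[SeqEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        parts = header.split(",")
        species = parts[0] if parts else header
        family = parts[1] if len(parts) > 1 else ""
        record_id = parts[2] if len(parts) > 2 else ""
        if header in seen:
            warnings.warn(f"duplicate FASTA header {header!r} in {path}", stacklevel=2)
        seen.add(header)
        residues = str(rec.seq).upper()
        entries.append(
            SeqEntry(
                species=species,
                family=family or "unknown_family",
                record_id=record_id,
                gene_label=gene_label,
                alphabet=infer_alphabet(residues),
                residues=residues,
                is_mitochondrial=is_mitochondrial,
            )
        )
    return entries


def write_manifest(entries: Iterable[SeqEntry], path: str | Path) -> None:
    """Tab-separated identifier manifest (record_id, species, family, gene)."""
    with open(path, "w") as fh:
        fh.write("record_id\tspecies\tfamily\tgene_label\n")
        for e in entries:
            fh.write(f"{e.record_id}\t{e.species}\t{e.family}\t{e.gene_label}\n")
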