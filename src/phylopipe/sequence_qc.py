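"""Per-sequence quality control: strand orientation, length selection, translation.

Public-database single-gene files mix strand polarities and occasionally
carry mis-annotated sequences.  Orientation checking compares each sequence
against up to four trusted template sequences of the same gene and either
accepts it as-is, accepts its reverse complement, or discards it.  Coding
mitochondrial sequences are translated to amino acids for alignment and
later back-translated codon-by-codon onto the aligned protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

from phylopipe.genbank_io import GAP_CHARS, SeqEntry

logger = logging.getLogger(__name__)

MAX_TEMPLATES = 4
MIN_MATCH = 15
MIN_SEGMENT_IDENTITY = 0.90


@dataclass(frozen=True)
class OrientationResult:
    """Outcome of the strand-polarity/similarity check for one sequence.

    ``entry`` carries the residues actually accepted: for
    ``accepted_reverted`` they are the reverse complement of the input.
    """

    entry: SeqEntry
    status: str  # accepted_forward | accepted_reverted | discarded
    templates_tried: int
    match_length: int


def reverse_complement(entry: SeqEntry) -> SeqEntry:
    if entry.alphabet != "nucleotide":
        raise TypeError("reverse complement requires a nucleotide entry")
    return entry.with_residues(str(Seq(entry.residues).reverse_complement()))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3
    return aligner


def _longest_identity_segment(template: str, query: str, aligner: PairwiseAligner) -> int:
    """Longest contiguous segment of the best local alignment whose identity
    is at least :data:`MIN_SEGMENT_IDENTITY`.

    Each gapless aligned block is scanned for its longest sub-window with
    the required match fraction; the maximum over blocks is returned.
    """
    if not template or not query:
        return 0
    alignments = aligner.align(template, query)
    try:
        best = alignments[0]
    except IndexError:
        return 0
    longest = 0
    t_blocks, q_blocks = best.aligned
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        matches = [template[ts + k] == query[qs + k] for k in range(te - ts)]
        n = len(matches)
        prefix = [0] * (n + 1)
        for k, m in enumerate(matches):
            prefix[k + 1] = prefix[k] + m
        for length in range(n, longest, -1):
            ok = any(
                prefix[i + length] - prefix[i] >= MIN_SEGMENT_IDENTITY * length
                for i in range(n - length + 1)
            )
            if ok:
                longest = max(longest, length)
                break
    return longest


def check_orientation(
    entry: SeqEntry,
    templates: list[SeqEntry],
    min_match: int = MIN_MATCH,
    max_templates: int = MAX_TEMPLATES,
) -> OrientationResult:
    """Check strand polarity and overall similarity against ordered templates.

    For each template in order (at most ``max_templates``): if the longest
    high-identity locally aligned segment between template and entry is
    strictly longer than ``min_match`` nucleotides the entry is accepted
    forward; otherwise its reverse complement is tested and, on success,
    the reverted entry is accepted.  After all templates fail on both
    strands the entry is discarded.
    """
    if entry.alphabet != "nucleotide":
        raise TypeError("orientation check requires nucleotide entries")
    if not templates:
        raise ValueError("at least one template is required")
    aligner = _make_aligner()
    revcomp = reverse_complement(entry)
    best_seen = 0
    for i, template in enumerate(templates[:max_templates], start=1):
        if template.alphabet != "nucleotide":
            raise TypeError("orientation templates must be nucleotide sequences")
        t = template.ungapped()
        fwd = _longest_identity_segment(t, entry.ungapped(), aligner)
        if fwd > min_match:
            return OrientationResult(entry, "accepted_forward", i, fwd)
        rev = _longest_identity_segment(t, revcomp.ungapped(), aligner)
        if rev > min_match:
            return OrientationResult(revcomp, "accepted_reverted", i, rev)
        best_seen = max(best_seen, fwd, rev)
    tried = min(len(templates), max_templates)
    return OrientationResult(entry, "discarded", tried, best_seen)


def choose_longest(entries: list[SeqEntry]) -> SeqEntry:
    """Pick the longest sequence among entries of one species and gene.

    Length is the ungapped residue count; ties go to the lexicographically
    smallest record_id.
    """
    if not entries:
        raise ValueError("choose_longest requires a non-empty entry list")
    species = {e.species for e in entries}
    genes = {e.gene_label for e in entries}
    if len(species) > 1 or len(genes) > 1:
        raise ValueError(
            f"choose_longest requires one species and gene, got {species} / {genes}"
        )
    return min(entries, key=lambda e: (-len(e.ungapped()), e.record_id))


def _coding_region(entry: SeqEntry) -> str:
    frame = entry.source_frame
    seq = entry.ungapped()[frame - 1 :]
    return seq[: len(seq) - len(seq) % 3]


def translate_cds(entry: SeqEntry) -> SeqEntry:
    """Translate a coding nucleotide entry using its annotated frame and table.

    Translation starts at the annotated codon offset; a trailing partial
    codon and a terminal stop are dropped; internal stops are kept as ``*``
    and logged.
    """
    if entry.alphabet != "nucleotide":
        raise TypeError("translate_cds requires a nucleotide entry")
    if entry.source_frame is None or entry.source_table is None:
        raise ValueError(
            f"{entry.header}: reading frame / genetic code missing; "
            "take codon_start and transl_table from the GenBank annotation"
        )
    coding = _coding_region(entry)
    aa = str(Seq(coding).translate(table=entry.source_table))
    if aa.endswith("*"):
        aa = aa[:-1]
    internal_stops = aa.count("*")
    if internal_stops:
        logger.warning(
            "%s (%s): %d internal stop codon(s) in translation",
            entry.header, entry.gene_label, internal_stops,
        )
    return entry.with_residues(aa, alphabet="amino_acid")


def backtranslate(aligned_aa: SeqEntry, source_nt: SeqEntry) -> SeqEntry:
    """Map an aligned amino-acid sequence back onto its source codons.

    Each residue becomes its source codon; each gap becomes ``---`` so
    alignment gaps stay codon-sized.  The ungapped protein must match the
    translation of the source nucleotides residue-for-residue.
    """
    if aligned_aa.alphabet != "amino_acid":
        raise TypeError("backtranslate expects an amino-acid alignment row")
    expected = translate_cds(source_nt)
    coding = _coding_region(source_nt)
    codons = [coding[i : i + 3] for i in range(0, 3 * len(expected.residues), 3)]
    out: list[str] = []
    pos = 0
    for i, aa in enumerate(aligned_aa.residues, start=1):
        if aa in GAP_CHARS:
            out.append("---")
            continue
        if pos >= len(codons) or aa != expected.residues[pos]:
            have = expected.residues[pos] if pos < len(expected.residues) else "<end>"
            raise ValueError(
                f"{aligned_aa.header}: residue mismatch at alignment position {i}: "
                f"aligned {aa!r} vs translated {have!r}"
            )
        out.append(codons[pos])
        pos += 1
    if pos != len(codons):
        raise ValueError(
            f"{aligned_aa.header}: aligned protein shorter than source coding region"
        )
    return source_nt.with_residues("".join(out))


def genetic_code_table(table_id: int) -> CodonTable.CodonTable:
    """The NCBI genetic-code table behind a transl_table identifier."""
    return CodonTable.unambiguous_dna_by_id[table_id]
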