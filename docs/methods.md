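# Methods

This note documents the models, statistics and procedural choices behind
`phylopipe`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and where genuinely open design decisions were
resolved by the package.

## Problem setting

Sequences harvested from public databases for a taxon of interest arrive as
a mixture of multi-gene records (whole mitochondrial genomes, rRNA
cassettes), single-gene fragments of varying length and strand, and genes
sampled in wildly different numbers of species. Concatenating them naively
yields a supermatrix that is huge, extremely sparse, and contaminated with
mis-annotated or compositionally deviant sequences — all of which degrade
partitioned maximum-likelihood inference. The pipeline enforces three
guarantees before concatenation: *orthologous identity and orientation* per
gene, *minimum pairwise overlap* among retained species, and *base
compositional homogeneity* within each nucleotide partition, plus standard
density floors so that no species or gene enters the matrix with negligible
signal.

## Record splitting and header standardization

GenBank feature tables locate genes in 1-based inclusive coordinates;
internally all slicing is 0-based half-open. A `join(...)` location is
extracted by concatenating its spans in ascending coordinate order and
reverse-complementing the concatenation for minus-strand features, the
standard reading of `complement(join(...))`. Every extracted gene reads
5′→3′ on its sense strand.

Headers are standardized to `species,family,record_id`. The family is taken
from the taxonomy lineage as the entry ending in the animal family suffix
*-idae*, with fallback `unknown_family`: lineages rarely label ranks
explicitly, and the suffix rule is deterministic and testable. Gene labels
are case-folded and mapped through an editable synonym table
(`phylopipe/data/gene_synonyms.tsv`; COI/CO1/cox1 → COX1 and so on) —
cross-record grouping is impossible without it, and the table is data, not
code, so users can extend it for their taxon.

## Orientation and similarity check

The check accepts a sequence if it shares a sufficiently long
high-identity segment with a trusted template of the same gene, on either
strand. "Sufficiently long" is operationalized as: the longest contiguous
(gapless) segment of the best local alignment (match +1, mismatch −2, gap
−3) whose identity is ≥ 90 % must be **strictly longer than 15
nucleotides** (`min_match`). Up to four templates (`max_templates`) are
tried in the caller-supplied order before the sequence is discarded;
passing an explicitly ordered template list rather than sampling previously
accepted sequences keeps runs reproducible. The 90 % segment-identity
reading is one defensible operationalization of a pairwise-BLAST "identity
longer than 15 nt" criterion; it is deterministic and brute-force checkable
(the tests cross-check discards against an exact longest-common-substring
dynamic program on both strands).

## Translation and back-translation

Coding mitochondrial genes are aligned at the protein level. Translation
uses the annotated `codon_start` and `transl_table` (defaults: table 5,
invertebrate mitochondrial, for mitochondrial entries; table 1 otherwise);
trailing partial codons and the terminal stop are dropped and internal
stops are kept as `*` with a warning. Back-translation replaces each
aligned residue by its source codon and each gap by `---`, so alignment
gaps always occupy whole codons and the aligned nucleotide length is
exactly three times the protein alignment length. A mismatch between the
aligned protein and the translation of the source nucleotides is an error
with the offending position — it indicates the wrong source sequence, not a
recoverable condition.

## Column masking

Columns whose gap fraction **strictly exceeds** 0.70 are removed
(`'-'` and `'?'` count as gaps; `N`/`X` are ambiguous characters, not
gaps). Third codon positions of mitochondrial coding alignments are removed
as saturated at deep divergences; this requires the aligned width to be
divisible by three, which back-translated alignments guarantee. Both
operators delete columns by default; a flag substitutes the missing symbol
instead. In the assembled pipeline the gap-saturation step runs **in
substitution mode for coding groups**: deleting arbitrary columns would
destroy the codon phase that the third-position step depends on, whereas
substituting `?` preserves width and phase. Non-coding groups use deletion.
tRNA alignments, individually short, are concatenated into a single block
with per-block boundaries recorded.

## Overlap cliques

For each aligned gene, species are vertices and an edge connects two
species whose rows share ≥ 100 (`overlap`) columns in which both carry a
comparable character (gap and missing symbols do not count). The largest
species set in which *every* pair satisfies the criterion is exactly a
maximum clique of this graph. The solver is an exact branch-and-bound
search with a greedy-coloring upper bound; among equal-size maxima it
returns the lexicographically smallest sorted species tuple, obtained by
fixing the smallest feasible vertex at each level, so results are
independent of input order. Graphs beyond 2,000 vertices fall back to a
degree-greedy heuristic whose output is still verified to be a clique (28S
rRNA-sized groups can exceed comfortable exact search). Species outside the
first clique get a second chance via the maximum clique of the remaining
vertices; everything else is discarded. A second clique of size one is
retained — the subsequent density filters remove its consequences if it
stays isolated.

## Compositional homogeneity

Each nucleotide group is tested with a TREE-PUZZLE-style χ² goodness of
fit: with π̄ the mean of per-sequence relative base frequencies over the
currently included sequences, a sequence with *n* countable bases has
expected counts *n*·π̄_b and statistic χ² = Σ_b (o_b − n·π̄_b)² / (n·π̄_b),
df = 3, upper-tail p-value. If any included sequence has p < α (= 0.05),
the single most deviant one (smallest p; ties to larger χ², then
alphabetical species) is removed and the means are recomputed — removing
one at a time matters because each exclusion moves the mean, and batch
removal over-excludes. The procedure terminates in at most *n* iterations.
The excluded set is re-tested identically: consistently deviant clades
(e.g. a GC-rich family) form a legitimate second homogeneous group;
sequences failing both passes are discarded. Sets with fewer than two
testable sequences, and sequences with zero countable bases, pass by
convention with an explicit flag. A base with zero expected frequency
contributes nothing when its observed count is also zero and renders the
sequence deviant otherwise.

Because every sequence is tested at level α, a homogeneous group of *k*
sequences still yields false exclusions at roughly the per-sequence rate
(empirically ≈ 0.043 for k = 20, slightly conservative since each sequence
contributes to the mean). Exact "only the planted outliers" recovery is
therefore a property of scenarios whose null members share identical
composition — the synthetic generator offers exactly that
(`exact_frequencies=True`) alongside the realistic multinomial mode.

## Density filters and subset construction

Groups with fewer than 4 species (`min_species`) are deleted; species with
a single sequence in the dataset are deleted, followed by a re-application
of the group-size rule (one pass by default, an opt-in flag iterates the
pair to a fixed point). Genera with more than 15 species
(`max_per_genus`) are pruned to the 15 best-represented, ranked by
(1) sequence count in the dataset, then (2) total residue length, ties
alphabetical; genus is the species-name prefix before the first underscore.
Finally the dataset is reduced to species present in the leading (most
species-rich) gene group, which guarantees every retained species overlaps
every other in at least that gene. An extended subset can re-include up to
2 best-represented species (`max_per_family`) per family lost during
filtering; the result is flagged as requiring a composition re-test, which
the pipeline enforces before such a dataset is concatenated.

## Supermatrix and exports

Concatenation fills absent species×gene blocks with `?` (missing), keeping
`-` strictly for within-alignment gaps. Each gene is one contiguous
partition with a model hint (`DNA` for nucleotide partitions; merged
amino-acid groups become one protein partition hinted `LGF`, i.e. the LG
matrix with empirical frequencies). Data coverage is
100 · sequences / (gene groups × species), reported to two decimals, where
a sequence is a species×gene block containing at least one non-missing
character; merged protein partitions still count their constituent gene
groups in the denominator. Exports are relaxed PHYLIP (`name row` lines
under an `n_species n_sites` header), FASTA, a RAxML plain-format partition
file (`MODEL, name = start-end`), and a per-partition occupancy summary.

## Synthetic data: what it does and does not emulate

The generators produce, deterministically from a mandatory seed:
multi-gene mitochondrial-style records (CDS/tRNA/rRNA features, both
strands, shifted reading frames, ground truth returned alongside); aligned
groups whose overlap graph has a planted, provably unique maximum clique
(planted species share one threshold-wide window, outsiders are staggered
by half a threshold); and composition scenarios with GC-shifted outliers in
multinomial or exact-frequency mode. They emulate the *structural*
properties the pipeline's filters react to — coordinates, strandedness,
overlap geometry, composition — not sequence evolution: there is no
substitution model, no rate heterogeneity, no indel process, and alignments
are constructed, not inferred. Passing tests therefore demonstrate that the
filters implement their stated rules exactly, not that the rules are
optimal for real data, where alignment error and phylogenetic structure
add failure modes the fixtures do not model.

Default fixture sizes (a 12-species, 5-gene aligned dataset; 200-graph /
100-group oracle sweeps) keep the full test suite and the acceptance script
in the low seconds while exercising every stage and boundary.

## Numerical and degenerate-input conventions

* χ² p-values via the scipy χ² survival function; statistic cross-checked
  against an independent goodness-of-fit computation to 1e-9 relative error.
* All tie-breaks are deterministic and documented: lexicographic record_id
  (longest-sequence selection), lexicographic species tuple (cliques),
  smallest p → larger χ² → alphabetical species (composition), alphabetical
  gene label (leading gene).
* Empty inputs: empty GenBank file → empty list; empty dataset passes
  through the density filters; concatenating zero groups, reducing an empty
  dataset to a leading gene, or computing coverage without species/groups
  are errors.
* Masking an alignment down to zero columns would produce empty rows and is
  rejected by the sequence container; in practice the 70 % rule leaves
  informative columns standing.

## Known limitations

* Family assignment relies on the *-idae* suffix heuristic; taxa whose
  lineages lack such an entry land in `unknown_family`.
* The orientation statistic is one reading of a pairwise-BLAST length
  criterion; other readings (HSP length, raw identity count) would shift
  acceptance near the threshold.
* The greedy clique fallback above 2,000 vertices guarantees clique-ness
  but not maximality.
* Amino-acid composition heterogeneity is not tested (the χ² filter applies
  to nucleotide groups only), and no symmetry-type tests are included.
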