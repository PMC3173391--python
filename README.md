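# phylopipe

Public sequence databases hold enormous numbers of sequences that were never
collected with a joint phylogenetic analysis in mind: multi-gene mitochondrial
records, single-gene fragments on either strand, rRNA cassettes, and wildly
uneven taxon sampling. `phylopipe` turns such heterogeneous collections into a
filtered, compositionally homogeneous, overlap-guaranteed, partitioned
**supermatrix** ready for partitioned maximum-likelihood inference. It is
aimed at systematists assembling large taxon-rich matrices from GenBank-style
flat files; multiple sequence alignment and tree inference stay with the
external tools you already use (MAFFT, RAxML, ...) and are exchanged through
standard formats (FASTA, relaxed PHYLIP, RAxML partition files).

## What it does

Pre-alignment (per GenBank record / per gene):

* parse GenBank flat files and split multi-gene records into single-gene
  entries using the feature table (CDS/rRNA/tRNA, both strands, `join(...)`
  locations, `codon_start` offsets), under the standardized header
  `species,family,record_id`;
* check strand polarity and similarity of every sequence against up to four
  template sequences — a sequence is accepted if its best local-alignment
  segment (≥ 90 % identity) is longer than 15 nt on either strand, otherwise
  discarded;
* keep the longest sequence per species and gene, and translate coding
  mitochondrial genes for protein-level alignment.

Post-alignment (per aligned gene group, then globally):

* back-translate aligned proteins codon-by-codon (gaps stay codon-sized);
* delete alignment columns with > 70 % gaps and third codon positions of
  mitochondrial coding genes; concatenate tRNA blocks;
* select, per gene, the **first and second maximum cliques** of species whose
  sequences all mutually overlap in ≥ 100 aligned positions (exact
  branch-and-bound maximum-clique search);
* iteratively exclude sequences whose base composition deviates from the
  group mean — a TREE-PUZZLE-style χ² goodness-of-fit test
  (χ² = Σ_b (o_b − n·π̄_b)²⁄(n·π̄_b), df = 3) at α = 0.05 — and re-test the
  excluded set for a second homogeneous group;
* enforce data density: drop ortholog groups with < 4 species and species
  with a single sequence, prune genera to their 15 best-represented species,
  and keep only species present in the leading (most species-rich) gene;
* concatenate everything into a partitioned supermatrix, compute the data
  coverage statistic `100 · sequences / (groups × species)`, and write
  PHYLIP + partition files.

A deterministic synthetic-data module (`phylopipe.fixtures`) generates
GenBank-style records and aligned groups with planted cliques and planted
composition outliers, so the whole pipeline is testable offline.

## Worked example

```bash
# generate a synthetic fixture set (multi-gene records + aligned dataset)
phylopipe fixture --seed 7 -o demo

# pre-alignment path on the GenBank file (stops at the alignment gap)
phylopipe pipeline --genbank demo/records.gb -o demo/genes
# -> "pre-alignment path complete; align the FASTA files in demo/genes ..."

# post-alignment path on the pre-aligned fixture dataset
phylopipe pipeline --aligned demo/aligned -o demo/run
```

The last command prints, for seed 7:

```
masking: in=35 out=35 excluded=0
overlap_clique: in=35 out=33 excluded=2
composition: in=33 out=33 excluded=0
density: in=33 out=31 excluded=2
prune_genera: in=31 out=31 excluded=0
leading_gene: in=31 out=31 excluded=0
supermatrix: 11 species x 730 sites, 4 partitions, coverage 70.45%
```

Reading: two sequences fail the 100-position mutual-overlap criterion and
are discarded by the clique stage; one compositionally deviant rRNA sequence
survives as its own second homogeneous group; the final matrix spans 4 gene
partitions over 730 sites, with 70.45 % of species×gene blocks filled.
`demo/run/` then contains `supermatrix.phy`, `partitions.txt` (e.g.
`DNA, COX1 = 1-200`), `summary.tsv` and the per-stage `manifests.tsv`.

Every stage is also available as its own subcommand (`split`, `check`,
`longest`, `translate`, `backtranslate`, `filter-small`, `filter-singletons`,
`clique`, `chi2`, `mask-gaps`, `mask-third`, `prune-genera`, `leading-gene`,
`reinclude`, `concat`, `coverage`) reading and writing the same per-gene
FASTA directory layout, so you can interleave manual curation or external
tools anywhere.

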