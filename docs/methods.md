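# Methods

This note records the conventions, numerical choices and open design
decisions behind mitochar, in the spirit of a methods section: what is
computed, under which assumptions, and what the synthetic-data tests do
and do not demonstrate.

## Coordinates and circular arithmetic

External coordinates are 1-based inclusive, matching GenBank flat files
and published mitogenome annotation tables; internal slicing is 0-based
half-open with explicit converters. A feature may wrap the circular
origin at most once, and after canonical rotation (trnM at position 1 —
the conventional start of the lepidopteran gene order) only the control
region→trnM junction can wrap. Adjacency for the gap column is defined on
plus-strand coordinate order regardless of feature strand, because the
published tables this reproduces list all features in one ordered column.
With gaps defined as `start(next) − end(current) − 1` the closure identity
Σ(length + gap) = genome length is exact (telescoping sum) whenever every
overlap involves only consecutive rows; a separate validator warns about
non-consecutive coordinate overlaps, which would break the printed-table
interpretation without invalidating the features themselves.

## Codon calls

Start codons are reported verbatim and classified: ATN = canonical, CGA =
alternative (the recurring lepidopteran cox1 start), anything else =
unexpected. No re-annotation is attempted — this is a characterization
tool, not an annotator. Stop calls are length-driven: CDS length mod 3 of
0 yields the terminal trinucleotide (complete only if TAA/TAG), 1 yields
the abbreviated stop `T`, 2 yields `TA`, each confirmed against the actual
trailing bases; mismatched tails and internal in-frame stops raise
annotation-inconsistency flags rather than errors. The length-driven rule
is used because published abbreviated stops coincide exactly with genes
whose annotated length is ≡ 1 (mod 3).

## Composition and codon usage

Skews follow Perna & Kocher (1995): AT-skew = (A−T)/(A+T), GC-skew =
(G−C)/(G+C). The functions accept counts or percentages — the formula is
scale-invariant — which is what makes a published composition table a
usable test vector. N and other ambiguity codes are excluded from
denominators. Gene-level statistics use the oriented 5'→3' sequence;
whole-genome statistics use the plus strand. Reports round percentages to
1 decimal and skews to 2, the precision of the field's tables; raw values
stay in machine output.

Codon usage hard-codes NCBI translation table 5 (cross-checked against
Biopython's copy in the test suite). Conventions that external
codon-usage servers leave unstated are fixed here explicitly: terminal
complete stops and truncated T/TA tails are excluded; start codons count
as their table-5 sense translation (a CGA start counts toward Arg, not
Met); N-containing codons are dropped, not imputed; leucine is one
six-codon family by default, with a `split_leucine` switch for UUR/CUN
sub-families. RSCU is count × family size / family total; unobserved
families report missing rather than zero.

## Motifs and repeats

Motif search is exact-match only (no PWM or fuzzy matching); the
conserved-element report checks the four diagnostic lepidopteran
elements — ATAGA + downstream poly-T upstream of rrnS in the control
region, the control region's terminal poly-A toward trnM, ATACTAA in the
trnS2–nad1 spacer, and ATGATAA spanning the atp8/atp6 overlap — each
reported found/absent with coordinates and observed run lengths, and
degrading to a partial report when prerequisites are missing. Repeat
detection finds maximal perfect runs only: homopolymers at ≥ 2 copies;
microsatellites with primitive units of 2–6 bp, ≥ 3 copies and ≥ 8 bp
total. These microsatellite thresholds are this package's operational
definition — published mitogenome reports rarely define their detector —
and are configurable. Overlapping candidate runs resolve to the longest,
ties to the smallest unit.

## Assembly comparison

The comparison targets conspecific assembly pairs (expected identity
≥ 99%); pairs aligning below 95% identity are refused. Both genomes are
rotated to a shared origin — trnM when annotated, otherwise the first
k-mer (k = 21 by default) unique in both — and globally aligned with
edlib's Needleman–Wunsch path. The edit-distance cap is 5% of the genome
length plus a configurable headroom (`band`, default 50). Indels are
normalized to the VCF convention (left-aligned, anchor base first); an
indel whose inserted/deleted sequence is a whole number of copies of a
primitive 2–6 bp unit adjacent to a reference tract of ≥ 3 copies and
≥ 8 bp is reclassified as a microsatellite copy-number variant, making
those calls deterministic and position-stable. Variants in light-strand
genes are reported in plus-strand genome coordinates with codon effects
computed on the oriented CDS; rRNA length polymorphisms are plain indels
with no codon fields. Region assignment resolves overlap ties by class
priority PCG > tRNA/rRNA > control region > intergenic.

## Supermatrix preparation

Tree inference, model selection and bootstrap are out of scope; the
package prepares inputs for them. The bundled aligner is a deliberately
simple codon-aware star alignment (translate under table 5, pairwise-align
amino acids to the first taxon, merge on reference positions, back-thread
codons, gaps in whole triplets); it exists to make supermatrix tests
self-contained on synthetic data and is not a substitute for a production
codon aligner. Terminal stops and truncated tails are stripped before
alignment by default (configurable), so a 13-gene single-taxon matrix from
the default synthetic genome is 11,169 bp wide. Gene order in the matrix
is genome order, with an alphabetical option matching common concatenation
tools; gap and missing data share the `-` character, as is usual
supermatrix practice. Partition schemes: I = one site set per gene; II =
codon positions {1,2} vs {3} across all genes; III = positions {1,2} only
(third positions dropped from the exported matrix; single set by default,
per-gene via option); IV = all sites in one partition flagged for codon
models. Partition files are written in RAxML text (comma-separated ranges,
`\3` strides) and NEXUS sets blocks (whitespace-separated, per the NEXUS
standard); round-trips are covered by tests. The conventional
branch-support reading thresholds (SH-aLRT ≥ 80, UFBoot ≥ 95) are emitted
as documentation for downstream interpretation, not used in computation.

## The synthetic-data generator

The generator emulates the structure the analyses assume: a ~15.4 kb
circle with the canonical lepidopteran gene complement and order, the
published per-gene lengths, and either the published overlap/spacer
profile (default, 15,395 bp) or a resampled one (spacers up to 62 bp,
overlaps 1–8 bp, with the two codon-sharing PCG junctions atp8→atp6 and
atp6→cox3 held fixed). PCGs are synthesized codon-by-codon from an
AT-biased distribution over sense codons, so valid starts, absence of
internal stops, and complete-or-truncated termini hold by construction;
the atp8 terminus is fixed to …ATA-TGA-TAA so the conserved ATGATAA
heptamer genuinely spans the atp8/atp6 overlap, and atp6's TAA stop
supplies the A that cox3's ATG start shares. Background, control-region
and PCG A+T levels default to 0.78 / 0.93 / 0.765, mirroring the
composition gradient of real lepidopteran mitogenomes; because stop
codons (AT-rich) are excluded from the sampler, the realized whole-genome
A+T runs ≈ 1–1.5 points below the nominal background value. tRNA/rRNA
filler is random AT-biased sequence — no secondary-structure realism is
attempted, and nothing downstream requires it.

The mutated sister assembly plants a configurable spectrum (default: 5
transitions, 1 transversion, 2 indels, 3 microsatellite copy-number
changes, mirroring a typical published two-assembly comparison) with the
default placement: the transversion and three transitions in four
distinct PCGs (exactly one a synonymous third-position change — under
table 5 every third-position transition is synonymous, which the planner
exploits), one transition each in the control region and a tRNA free of
PCG overlap, indels in an rRNA (a 2 bp length polymorphism) and the
control region, and copy-number ±1 at the planted intergenic repeats.
Truth records (position, left-aligned alleles, class, subclass, region,
codon effect) come from the generator's own coordinate bookkeeping,
independent of the comparison pipeline tested against them. Planting
enforces separation (≥ 25 bp), avoidance of planted motifs/repeats and
the anchor region, and locally unambiguous indel sites (flanking bases
disjoint from the fragment's letters), so the minimum-edit alignment of
the pair is unique over the planted set and exact recovery is a
well-posed expectation. All randomness flows through one seeded numpy
generator; identical seeds give byte-identical output.

What passing tests show — and what they do not: exact planted-variant
recovery on these pairs demonstrates the correctness of the rotation,
alignment, normalization and classification logic under realistic
composition and spacing, but real assembly pairs can present ambiguities
the planner deliberately avoids (indels inside long homopolymers,
clustered edits), where equally optimal alignments make the variant
representation non-unique; the left-alignment convention then picks one
canonical representative. Likewise the generator's composition targets
make composition statistics well-exercised, but ranked amino-acid
frequencies of real genomes depend on real sequence and are reported as
outputs, not asserted.

## Bundled reference data

The package ships the published annotation coordinates (and printed
lengths, signed gaps and codons) of the two *Paracossulus thrips*
assemblies, GenBank PQ668644 (CAT07, 15,395 bp) and PQ668645 (CAT08,
15,385 bp), as plain TSV. No sequence data is bundled; sequence-dependent
statistics of those accessions (e.g. control-region A+T%) are not
reproduced offline, and the published gap column is always recomputed from
coordinates rather than trusted (the tRNA-Cys 35 vs 37 difference between
the assemblies, for instance, follows from the trnY coordinate shift).

## Known limitations

- Exact-match motif scanning only; degenerate motifs need an external tool.
- Imperfect (mismatch-containing) repeats are not detected.
- The comparison assumes colinear conspecific assemblies; rearrangements
  are out of scope (and rejected by the identity floor).
- The star aligner is adequate for near-identical sequences; deep
  divergence should go through MACSE/MAFFT upstream.
- GFF3/BED export cannot represent an origin-wrapping feature; rotate to
  the canonical origin first.
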