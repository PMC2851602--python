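# Methods

`chondriome` mechanizes the comparative analysis of plant mitochondrial
"master circle" genomes: reconstructing a single circular sequence from
depth-annotated assembler contigs, comparing circular genomes to count
rearrangements, annotating genes, chimeric ORFs and variant panels, and
grouping accessions by marker presence/absence. This note records the
models, conventions and numerical choices behind each stage, and what the
synthetic test substrate does and does not demonstrate.

## The master-circle model

Plant mitochondrial DNA is physically multipartite; the master circle is
the conventional single-circle abstraction carrying the full gene
complement. Two reconstructions describe the same molecule when one is a
rotation and/or reverse complement of the other, so all comparisons of
alternative assemblies go through a canonical form: the lexicographically
minimal string over all rotations of the sequence and of its reverse
complement (computed with Booth's least-rotation algorithm). Internally
all coordinates are 0-based half-open; GFF3 and report output is 1-based
inclusive.

## Contig filtering and circle enumeration

Filtering applies four criteria in order of precedence: explicit
exclusion list (e.g. plasmid-like molecules); full-length 100% identity
to a nuclear reference on either strand (contaminants); dead ends —
contigs with an end lacking any link to a surviving contig, iterated to a
fixpoint because removing one dead end can expose another; and bridging
contigs with read depth below 15. Depth is a per-contig scalar (total
base redundancy / contig length), matching the filtering rules that
consume it; a contig at exactly 15 survives, the reading consistent with
both published phrasings of the cutoff.

The linkage graph joins contig 5'/3' ends with validated link edges. A
contig's copy number bound is its depth divided by the median depth,
rounded and clipped to [1, 3] (a collapsed two-copy repeat shows ~2x
depth); bounds are user-overridable. Parsimonious reconstruction searches
multiplicity assignments in order of increasing total length and returns
every closed walk that traverses each contig exactly its multiplicity,
entering at one end and exiting at the other, consecutive contigs joined
by a link edge. Walks are deduplicated up to rotation and reversal via a
canonical signed-id sequence (a flag disables reversal deduplication).
Enumeration is exact; a cap (default 10,000) guards against pathological
graphs and sets a truncation flag. Joins are butt joints — assembler
contigs are treated as non-overlapping genome segments, matching the
PCR-bridge validation model.

## Synteny and rearrangement detection

Pairwise comparison replaces local alignment plots with maximal exact
matches (MEMs): a k-mer index with k = min_len (default 50, far above
random-match length at half-megabase scale) yields every maximal match as
a maximal run of diagonal k-mer hits, exactly. Circular genomes are
searched doubled; truncated images of matches crossing the origin are
removed by a circular-containment filter, and no match longer than either
genome is reported.

Greedy colinear chaining joins same-strand anchors whose gaps on both
genomes are at most max_gap (default 5 kb, computed on the circle) and
mutually consistent within max_gap. Chains are merged across the origin
and their coordinates unrolled to be monotonic, which makes every
downstream count rotation-invariant; a single chain covering the whole
circle still has a seam between its last and first anchor, whose gap is
folded into the block statistics. Gap regions between chained anchors are
globally aligned with affine gap costs (match 1, mismatch −2, open −4,
extend −0.5) to fill per-block SNP and indel-event counts; each
contiguous gap run counts as one indel event regardless of length. Gap
regions above 50 kb are not aligned base-wise and count as one unaligned
event — a desk-scale runtime choice.

Before any counting, the query is tiled: blocks shorter than 1 kb or
mostly covered by a longer block are dropped. Dispersed repeats below the
duplication threshold map every copy onto every other copy; without
tiling these multi-mapping blocks fabricate variants and junctions.

* **Duplications.** Self-comparison reports each repeat *pair* (not copy)
  of length ≥ dup_min (default 10,000 bp). Masking deletes the later copy
  in the current rotation, iterating to a fixpoint; the subject of a
  comparison is always masked first, the query never. Detection is exact
  repeats only; near-identical large repeats appear as chained anchor
  runs and are masked through the same machinery in practice.
* **Recombination junctions.** Blocks are ordered around the circular
  query (wrapping last-to-first); a junction is a boundary whose subject
  images are not adjacent and colinear within max_gap, order- and
  orientation-aware. One crossover on a circle yields two junctions, so
  published event counts read off dot plots are treated as lower bounds.
  A query-side duplication also contributes one junction pair under this
  operationalization.
* **Large indels.** Gaps present in exactly one genome, larger than
  indel_min (default 1,000 bp), scanned both inside blocks and at
  colinear block boundaries including the circular seam. A gap whose
  skipped sequence is covered by another block (modulo the circle) is the
  return jump of a duplication, not an indel, and is suppressed. The
  "large" threshold labels events; it never removes them from the variant
  tally.

## Annotation

Catalog genes are located by exact-seed clustering (seed 20 bp) plus
local re-alignment of the candidate window; status is `present` at
coverage ≥ 0.98 and identity ≥ 0.95 with, for protein genes, an intact
reading frame (ATG start, terminal stop, no internal stop), `partial`
otherwise (annotated with the missing terminus), `absent` with no seed
cluster. The thresholds are declared defaults, not inferred from any
published search parameters, and are configurable.

Coding variants come from a global CDS alignment: mismatches are grouped
per codon and each affected codon translated on both sides under the
standard genetic code (translation table 1 — guarded by fixtures in which
two point mutations in one arginine codon yield a single non-synonymous
call labelled `R144G`). In-frame gap runs are `indel` variants; a
frame-breaking run raises a flag and suppresses per-codon calls.

ORF prediction follows a declared convention: six frames, ORF = first ATG
after the previous in-frame stop through the next stop, one ORF per
stop-to-stop span, minimum 70 codons, circular wrap allowed once, nested
and antisense ORFs all kept. Published ORF totals depend on an unstated
merge rule across several predictors, so this package's counts are
validated against an independent brute-force scanner rather than any
printed total.

Chimeric ORFs — the classic anatomy of CMS candidate genes — are ORFs
absent from a reference genome (no infix match within 1% edit distance,
screened with edlib) that decompose into catalog-gene fragments of
≥ 100 bp at ≥ 85% identity plus unknown remainder, with at least one gene
fragment and one unknown segment, or fragments of two distinct genes. The
85% figure is the one identity the source material prints for such
fragments.

SNP-panel genotyping locates each site by its flanks (both strands,
wrap-aware), reads the allele between them, and codes it by which named
reference genomes carry it: `j` both japonica genomes, `9`/`n`/`p` single
genomes (shared carriers joined by `/`), `cms` an allele none carries,
`-` flanks absent or ambiguous. Detectability is the count of non-`-`
sites.

## Marker assays and haplogrouping

In-silico PCR reports convergent exact primer-site pairs within the
product-size bound, wrap-aware; mismatch-tolerant matching is a reserved
option, off by default, since no mismatch policy is published for the
assays being emulated. Haplogroups are exact-pattern groups of
presence/absence vectors, lettered A, B, ... by first appearance;
designated reference profiles (the CMS lines) keep their names and never
receive letters. The package ships the published fourteen-row,
nine-marker pattern table as data; grouping it yields the twelve lettered
groups plus the two CMS patterns.

## The synthetic substrate

The generator emulates, at the rice chondriome's scale (default
490,669 bp, GC 0.44, mean contig depth 42, noise SD 4), the post-assembly
state of a pyrosequencing project: a circular reference with planted
ATG-to-stop genes and exact dispersed repeat pairs; derivatives carrying
repeat-mediated inversions, large duplications (> 10 kb), insertions
(> 1 kb, e.g. the 6,881-bp scale used in fixtures), deletions, SNPs and
small indels; contig sets cut at repeat boundaries (repeat pairs
collapsed to one contig at doubled depth) with true end-to-end links; and
decoys — dead-end contigs (depth < 15, one free end), nuclear
contaminants (verbatim substrings of a decoy sequence, depth < 15) and
low-depth bridges (depth < 15, linked both ends). One PRNG stream seeded
once drives everything; truth records replay byte-exactly.

What it does not emulate: read-level error profiles (substitution noise
defaults to 0, matching the measured 99.99% platform accuracy, and is
configurable), homopolymer artifacts, chloroplast/nuclear insertions
beyond the decoy contaminants, diverged (non-identical) repeat families,
and substoichiometric subgenome mixtures. Passing tests therefore show
the algorithms are correct under clean assembly conditions, not that they
are robust to raw-read artifacts.

Test problem sizes are package choices: recombination-recovery runs use
200-kb genomes (five disjoint exchange slots plus genes do not fit
comfortably in less), duplication/indel/SNP recovery 100 kb, round-trip
reassembly 60 kb, chimera simulations 25 kb. The enumeration oracle
compares against an exhaustive independent walk enumerator on graphs of
up to six contigs with multiplicities up to two.

## Known limitations

* Exact-match anchoring makes variant tallies parameter-sensitive for
  genomes sequenced on different platforms; blocks under 1 kb are dropped
  by tiling, so variants in very short syntenic fragments go uncounted.
* Duplication detection reports exact repeats; a repeat pair interrupted
  by a variant is reported as chained sub-pairs.
* Junction counting attributes one junction pair per crossover only when
  exchanges do not share flanking sequence; overlapping or nested
  rearrangements can merge junctions.
* `derived_position` (truth bookkeeping) assumes the disjoint-slot event
  layout produced by `random_events`.
* In-silico PCR is exact-match only; primer-site mutations in a real
  accession would read as marker absence.
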