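# Methods

This note records the models, definitions and numerical choices behind
`contexttree`, including the places where the design was genuinely open and
what was decided.

## Data model and coordinates

Genes are stored exactly as GFF represents them: 1-based, inclusive on both
ends, with a mandatory strand (`+`/`-`). A gene spanning 100..400 is 301 nt
long. The intergenic gap between consecutive genes is the number of
nucleotides strictly between them, gap(gᵢ, gᵢ₊₁) = startᵢ₊₁ − endᵢ − 1, so
gap 0 means abutting genes and overlapping genes have negative gap. All
derived quantities (chaining thresholds, spacing comparisons, spans) use
this convention; nothing is converted to half-open coordinates internally,
which avoids a whole class of off-by-one errors against the source format.

GFF parsing accepts both attribute dialects (`key=value;` and
`key value;`), autodetected per line, because real annotation files mix
them. The gene identifier is the first present of `locus_tag`, `ID`,
`gene_id`, `gene`; the annotation the first of `product`, `Note`,
`annotation`, `description`. Feature types retained default to
`{gene, CDS}`; when both records share an ID the `gene` record wins
(deterministic dedup). Strandless records (`.`/`?`) are rejected rather
than guessed: every downstream metric and rendering rule consumes strand.
Homology tables are accepted in two TSV layouts (one gene per row;
one cluster per row with `species|gene` members); the reader is the
extension point for further layouts.

## Context sets

The operon scheme chains consecutive same-strand genes on one contig with
gap ≤ T, transitively; T defaults to 20 nt, the conventional
intergenic-distance threshold for operon prediction in microbes. The
strand-distance scheme is the identical kernel with its own threshold D
(D = 75 gives the "D75" grouping used throughout the examples); the two
are implemented as one function and tested as equivalent. Chains break
only at contig boundaries and strand switches; circular-contig wrap-around
is not modelled because GFF carries no reliable topology flag.

Window schemes take ±k genes or ±w nt around each query match; an
nt-window includes any gene overlapping the window (genes are atomic — the
renderer draws whole genes, so membership is all-or-nothing).

Leaves are named `species-serial`, serial counting matches per species in
(contig, start) order from 1, whitespace in species names mapped to `_`
for Newick safety. When several matches land in one grouping the grouping
appears once, keeping the serial of its first match; serials may therefore
skip numbers, which preserves the correspondence between a leaf's serial
and the match that produced it.

## Dissimilarity metrics

**Dice and Jaccard** operate on the *set* of identity keys of a grouping's
genes — homology cluster IDs, or annotation strings normalized by
lowercasing and whitespace collapsing. Duplicate homologs within one
grouping count once (set, not multiset, semantics). Genes with no homology
assignment have no cross-species identity and are excluded from the set.
Both metrics return 0 for two empty sets. For any pair,
jaccard ≥ dice with equality exactly at 0 and 1; this follows from the
identity j = 2d/(1+d) and is enforced by property tests.

**Moving Distances** is this package's own definition (the idea — compare
gene order and intergenic spacing — fixes only the intent, not a formula):
restrict each grouping's ordered gene list to the identity keys present in
both, matching repeated keys in positional order; for each adjacent pair
of that shared subsequence measure the gap between the paired genes'
facing boundaries in each grouping; the dissimilarity is the mean absolute
gap difference, plus a penalty P (default 0) per unshared gene. Fewer than
two shared genes leaves no spacing to compare and returns a configured
sentinel (default 10 000 nt, far above any plausible intra-context gap
difference). Two groupings with identical gene lists score 0 regardless.
By default a grouping whose genes sit mostly (strict majority) on the
reverse strand is read right-to-left first, mirroring the viewer's strand
normalization, so analogous contexts encoded on opposite strands compare
in a common orientation.

**Total Length** is the absolute difference of grouping spans
(span = end − start + 1 of the genomic envelope). A `gene_sum` switch
instead sums gene lengths, for the reading of "total length" that ignores
intergenic DNA; the envelope is the default because a region's length is
what the viewer shows.

## Variable-group clustering

Pair-group agglomeration resolves tied minimum distances arbitrarily, so
its output can depend on input order. The variable-group algorithm
removes that dependence: each round finds the global minimum
inter-cluster distance d\*, builds the graph over clusters whose pairwise
distance is within tolerance of d\*, and merges every connected component
of that graph into one node. The node records the agglomeration band —
band_low = d\*, band_high = the largest pairwise distance fused inside the
component; the band is degenerate when there are no ties. Node heights
are reported from band_low by default (it is the threshold at which the
agglomeration happened, hence the natural ultrametric height); the band
midpoint is available as an option.

Tie detection uses a relative tolerance, `tie_epsilon · max(|d*|, 1)` with
tie_epsilon = 1e−9. Exact ties in rational inputs are always caught; the
epsilon exists solely so that floating-point summation order cannot turn a
mathematical tie into a spurious binary merge. On tie-free inputs the
algorithm reduces exactly to classical binary agglomeration, which is
verified against an independent implementation (scipy) for single,
complete and average linkage, and against minimum-spanning-tree edge
weights for single linkage.

Distance updates after a multi-way merge generalize the pairwise rules:
single = min, complete = max over member distances; unweighted average
(UPGMA) weights member distances by leaf counts; weighted average (WPGMA)
averages members equally. **Joint Between-Within** linkage is defined
here as d(U, K) = √(mean of squared leaf-to-leaf dissimilarities over all
pairs drawn from U ∪ K) — between-cluster and within-cluster pairs alike,
computed from the original matrix. The name constrains the definition
(both between- and within-group dispersion enter the score); the exact
formula is a design choice of this package and is isolated behind the
linkage interface so it can be swapped. It is not monotone in general;
the band/height monotonicity invariant is asserted only for the monotone
linkages. Children of every node are ordered by their smallest leaf name,
making Newick output reproducible byte-for-byte.

## Rendering

SVG replaces raster/EPS export: it is resolution-independent and
diffable in tests. Panels are 900×90 px with 30 px side margins and 18 px
gene bars — documented constants, not tuned to any original. Gene
rectangles sit above (+) or below (−) a centerline; the panel midpoint
maps to the center of the grouping's span and x-extent is affine in
nucleotide position. Strand normalization mirrors a panel when a strict
majority of its context genes are on the reverse strand (ties do not
mirror). Colors come from an HSV wheel over the sorted identity keys —
deterministic across runs and machines — with gray (#808080) reserved for
flanking genes; the legend is alphabetized.

## Synthetic data

The generator fabricates annotated genomes plus a homology map with known
context structure, at microbial scale: gene lengths uniform in
300–1500 nt, background genes separated by 200–800 nt (never chaining at
the thresholds under study), fully determined by the seed.

- `single_gene_vs_operon`: each species carries the query family (cluster
  1) either as a lone gene or as the first gene of a four-gene same-strand
  operon with gaps ≤ 20 nt — the lone-gene vs operon contrast that
  motivates context trees. Species alternate types, so any n ≥ 2 yields
  both groups.
- `conserved_operon`: the identical operon in every species; all pairwise
  dissimilarities 0 and the tree is a single n-way merge at height 0.
- `gap_variation`: identical gene content and order, species-specific
  intergenic gaps — the Moving Distances regime.
- `tie_block`: contexts sharing exactly one of two gene families, so every
  pair sits at Dice 0.5 — a perfect mutual tie exercising the
  simultaneous-merge semantics. `generate_tie_block` produces the
  corresponding k×k constant matrix directly.

What the generator does **not** emulate: pseudogenes, nested or
overlapping gene structures beyond simple overlap, annotation noise,
paralog expansions, multi-contig contexts, or realistic evolutionary
divergence. Passing tests therefore demonstrate algorithmic correctness
on clean planted structure, not robustness to messy real annotations.

## Problem sizes and determinism

The test-suite and the acceptance script use deliberately small problems —
matrices up to n = 12 against the clustering oracle (200 draws), 100
random genomes of 10–40 genes for partition laws, 1000 random set pairs
for metric algebra, 6 species end-to-end — chosen so the whole suite runs
in seconds while still exercising every code path and tie configuration.
All randomness flows from explicit seeds; every pipeline rerun on the same
inputs is byte-identical in its Newick, matrix and SVG outputs.

## Known limitations

- Cluster-query semantics require homology information (a table or
  feature-embedded cluster IDs); there is no on-the-fly sequence
  clustering — homology is an upstream input by design.
- Moving Distances and Joint Between-Within are explicit definitions of
  this package (see above), not reconstructions of any other tool's
  internals.
- Contexts never span contigs; circular replicons are treated as linear.
- The multiset variants of Dice/Jaccard are out of scope.
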