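# contexttree

Cross-species comparison of **genomic contexts** — the neighborhoods of
genes on a chromosome, including their order, strand and spacing — for
microbial comparative genomics. Two genes with nearly identical sequences
can play different roles that only their neighborhoods reveal: a
gamma-glutamyl-transpeptidase-like gene standing alone is a different
functional story from the same family sitting inside a four-gene operon.
`contexttree` turns that intuition into trees: it groups annotated genes
into contexts, scores context-to-context dissimilarity, and agglomerates
the contexts into a **context tree** whose leaves are genomic groupings
from many species.

It is a library first (import `contexttree`), with a thin `contexttree`
command line on top and narrative scripts under `examples/`.

## The method

1. **Context sets.** Each genome (tab-delimited GFF, GFF2 or GFF3
   attributes autodetected) is partitioned or windowed into groupings:
   single genes; predicted operons (consecutive same-strand genes with
   intergenic gap ≤ *T*, default *T* = 20 nt, where
   gap(gᵢ, gᵢ₊₁) = startᵢ₊₁ − endᵢ − 1); same-strand chains within *D* nt
   (e.g. the "D75" set, *D* = 75); ±k gene or ±w nt windows around a query
   match; or custom groupings from file.
2. **Query.** Contexts are retrieved by annotation substring or by
   cross-species homology-cluster ID (clusters computed upstream, e.g.
   BLAST + MCL, supplied as a TSV). Each retrieved grouping becomes one
   leaf, named `species-serial`.
3. **Dissimilarity.** With A, B the sets of gene identity keys of two
   groupings:
   - Common Genes – Dice: d = 1 − 2|A∩B| / (|A|+|B|)
   - Common Genes – Jaccard: d = 1 − |A∩B| / |A∪B|
   - Moving Distances: mean |gap_A − gap_B| over adjacent pairs of the
     shared gene subsequence, plus an optional penalty per unshared gene
   - Total Length: |span(A) − span(B)| in nucleotides
4. **Clustering.** Variable-group agglomerative hierarchical clustering:
   at each step *all* clusters tied at the minimal distance d\* merge
   simultaneously into one node carrying an agglomeration band
   [band_low, band_high], so the multidendrogram is independent of input
   order. Linkages: single, complete, unweighted/weighted average, and
   Joint Between-Within (root-mean-square leaf dissimilarity over all
   pairs in the union of the merging clusters).
5. **Export.** Multifurcating Newick (heights from band_low or the band
   midpoint), TSV/PHYLIP matrices, JSON tree dumps, and SVG context
   diagrams (strand above/below a centerline, homology coloring, gray
   flanking genes, alphabetized legend).

## Worked example

`python examples/01_build_context_tree.py` generates six synthetic
species — three carrying the query gene family as a lone gene, three
inside a four-gene operon — and builds a D75 / Dice / Joint Between-Within
context tree:

```
leaves: Species_01-1, Species_02-1, Species_03-1, Species_04-1, Species_05-1, Species_06-1

context tree (Newick):
((Species_01-1:0,Species_03-1:0,Species_05-1:0):0.4647580015,(Species_02-1:0,Species_04-1:0,Species_06-1:0):0.4647580015);
```

Within each context type the Dice dissimilarity is 0 (identical gene
content), so each type collapses into a zero-height multifurcation; the
root then splits the tree into two out-branches, lone-gene contexts on one
side and operon contexts on the other. The root height 0.465 is the
Joint Between-Within score: with nine between-type pairs at Dice 0.6 and
six within-type pairs at 0, √(9·0.6²⁄15) ≈ 0.4648.

The same run from the shell:

```sh
contexttree gen-fixtures --scenario single_gene_vs_operon --n-species 6 \
    --seed 11 --out-dir fx
contexttree build-tree --genome-dir fx --homology-table fx/homology.tsv \
    --query-mode homology_cluster_id --query-value 1 \
    --scheme strand_distance --distance-nt 75 \
    --metric dice --linkage joint_between_within --newick-out tree.nwk
contexttree render --genome-dir fx --homology-table fx/homology.tsv \
    --query-mode homology_cluster_id --query-value 1 \
    --scheme strand_distance --svg-out contexts.svg --legend
```

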