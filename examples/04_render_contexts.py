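"""Render genomic context panels to SVG with homology coloring.

Builds the single-gene-vs-operon scenario, then draws every context: genes
as rectangles above (+) or below (-) a centerline, colored by homology
cluster, with flanking genes in gray and an alphabetized color legend.
"""

import os

from contexttree import (
    ContextSet, LinkageSpec, Query, RenderOptions, ScenarioSpec, build_tree,
    color_assignment, generate_scenario, layout_context, render_svg,
)

genomes, homology, _ = generate_scenario(
    ScenarioSpec("single_gene_vs_operon", n_species=4, seed=5)
)
result = build_tree(
    genomes, homology, Query("homology_cluster_id", 1),
    ContextSet("D75", "strand_distance", distance_nt=75),
    metric="dice", linkage=LinkageSpec("complete"),
)

colors = color_assignment(result.leaves, "homology_cluster")
opts = RenderOptions(
    show_surrounding=True, flank_nt=2000, colors=colors, show_coordinates=True,
)
by_species = {g.species_name: g for g in genomes}
layouts = [layout_context(lf, by_species[lf.species_name], opts)
           for lf in result.leaves]

out = os.path.join("scratch" if os.path.isdir("scratch") else ".", "contexts.svg")
render_svg(layouts, out, legend=True, colors=colors, show_coordinates=True)

print(f"wrote {len(layouts)} context panels to {out}")
print(f"distinct gene-family colors: {len(colors)}")
for lf, layout in zip(result.leaves, layouts):
    n_flank = sum(gl.surrounding for gl in layout.glyphs)
    print(f"  {lf.leaf_name}: {len(lf.genes)} context genes, "
          f"{n_flank} gray flanking genes, window "
          f"{layout.window_start}-{layout.window_end}")
print(
    "\nPanels are stacked in leaf order and centered on each grouping; the "
    "same homology cluster gets the same color in every species."
)
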