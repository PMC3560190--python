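"""End-to-end wiring: load genomes, resolve a query to context leaves,
compute the dissimilarity matrix, cluster, and export artifacts.

This is the library face of the command line: everything here is callable
from Python with plain objects, and the CLI only translates flags into a
:class:`RunConfig`.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import io as gio
from .cluster import LinkageSpec, Multidendrogram, cluster, select_leaves, to_newick
from .contexts import build_context_leaves
from .errors import InputError, UsageError
from .metrics import DEFAULT_MOVING_CAP, DissimilarityMatrix, build_matrix
from .model import ContextGrouping, ContextSet, Genome, HomologyMap, Query
from .render import RenderOptions, color_assignment, layout_context, render_svg

log = logging.getLogger("contexttree")


@dataclass
class RunConfig:
    """Everything one tree-building run needs; validated before computation."""

    # inputs
    genome_dir: Optional[str] = None
    mapping_file: Optional[str] = None
    homology_table: Optional[str] = None
    homology_format: str = "long"
    custom_groupings_file: Optional[str] = None
    # query
    query_mode: str = "homology_cluster_id"
    query_value: str | int = 0
    case_sensitive: bool = False
    # context set
    scheme: str = "single_gene"
    threshold_nt: int = 20
    distance_nt: int = 75
    k_genes: int = 0
    window_nt: int = 0
    # metric
    metric: str = "dice"
    comparison_key: str = "homology_cluster"
    moving_penalty: float = 0.0
    moving_cap: float = DEFAULT_MOVING_CAP
    mirror_minus: bool = True
    length_mode: str = "span"
    # linkage
    linkage: str = "joint_between_within"
    tie_epsilon: float = 1e-9
    height_mode: str = "band_low"
    # outputs
    newick_out: Optional[str] = None
    matrix_out: Optional[str] = None
    svg_out: Optional[str] = None
    # render options
    show_coordinates: bool = False
    normalize_strand: bool = True
    show_surrounding: bool = False
    color_surrounding: bool = False
    flank_nt: int = 0
    legend: bool = False
    # misc
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if (self.genome_dir is None) == (self.mapping_file is None):
            raise UsageError("provide exactly one of genome_dir or mapping_file")
        if self.query_mode == "homology_cluster_id" and self.homology_table is None:
            raise UsageError("a homology-cluster query requires a homology table")
        if self.scheme == "custom" and self.custom_groupings_file is None:
            raise UsageError("the custom scheme requires a custom-groupings file")

    def context_set(self) -> ContextSet:
        return ContextSet(
            name=self.scheme, scheme=self.scheme,
            threshold_nt=self.threshold_nt, distance_nt=self.distance_nt,
            k_genes=self.k_genes, window_nt=self.window_nt,
        )

    def query(self) -> Query:
        return Query(self.query_mode, self.query_value, self.case_sensitive)

    def linkage_spec(self) -> LinkageSpec:
        return LinkageSpec(self.linkage, self.tie_epsilon)

    def render_options(self, colors: dict) -> RenderOptions:
        return RenderOptions(
            show_coordinates=self.show_coordinates,
            normalize_strand=self.normalize_strand,
            show_surrounding=self.show_surrounding,
            color_surrounding=self.color_surrounding,
            flank_nt=self.flank_nt,
            colors=colors,
            comparison_key=self.comparison_key,
        )


def load_genomes(cfg: RunConfig) -> list[Genome]:
    """Read the working set from a directory of GFFs or a mapping file."""
    if cfg.genome_dir is not None:
        paths = sorted(glob.glob(os.path.join(cfg.genome_dir, "*.gff")))
        if not paths:
            raise InputError(f"no .gff files found in {cfg.genome_dir!r}")
        pairs = [(os.path.splitext(os.path.basename(p))[0], p) for p in paths]
    else:
        entries = gio.parse_species_mapping(cfg.mapping_file)
        base = os.path.dirname(os.path.abspath(cfg.mapping_file))
        pairs = [
            (sp, p if os.path.isabs(p) else os.path.join(base, p))
            for sp, p in entries
        ]
    genomes = [gio.parse_gff(path, species) for species, path in pairs]
    log.info("loaded %d genomes, %d genes total",
             len(genomes), sum(len(g) for g in genomes))
    return genomes


@dataclass
class TreeResult:
    """All products of one tree build."""

    genomes: list[Genome]
    homology: Optional[HomologyMap]
    leaves: list[ContextGrouping]
    matrix: DissimilarityMatrix
    tree: Multidendrogram
    newick: str = ""


def build_tree(
    genomes: Sequence[Genome],
    homology: Optional[HomologyMap],
    query: Query,
    context_set: ContextSet,
    metric: str = "dice",
    comparison_key: str = "homology_cluster",
    linkage: LinkageSpec = LinkageSpec(),
    custom_groupings: Optional[Sequence[ContextGrouping]] = None,
    height_mode: str = "band_low",
    **metric_params,
) -> TreeResult:
    """Functional core: query -> leaves -> matrix -> multidendrogram."""
    if homology is not None:
        genomes = homology.annotate(genomes)
    leaves = build_context_leaves(
        genomes, homology, query, context_set, custom_groupings=custom_groupings
    )
    matrix = build_matrix(leaves, metric=metric, key=comparison_key, **metric_params)
    tree = cluster(matrix, linkage)
    result = TreeResult(list(genomes), homology, leaves, matrix, tree)
    result.newick = to_newick(tree, height_mode=height_mode)
    return result


def run_build_tree(cfg: RunConfig) -> TreeResult:
    """Execute a full configured run and write the requested artifacts.

    No output file is written until the whole computation has succeeded, so
    a failed or empty run leaves no partial artifacts behind.
    """
    cfg.validate()
    genomes = load_genomes(cfg)
    homology = None
    if cfg.homology_table is not None:
        homology = gio.parse_homology_table(cfg.homology_table, cfg.homology_format)
    custom = None
    if cfg.custom_groupings_file is not None:
        custom = gio.parse_custom_groupings(cfg.custom_groupings_file, genomes)

    metric_params: dict = {}
    if cfg.metric == "moving_distances":
        metric_params = dict(
            penalty_P=cfg.moving_penalty, default_cap=cfg.moving_cap,
            mirror_minus=cfg.mirror_minus,
        )
    elif cfg.metric == "total_length":
        metric_params = dict(length_mode=cfg.length_mode)

    result = build_tree(
        genomes, homology, cfg.query(), cfg.context_set(),
        metric=cfg.metric, comparison_key=cfg.comparison_key,
        linkage=cfg.linkage_spec(), custom_groupings=custom,
        height_mode=cfg.height_mode, **metric_params,
    )

    log.info("built tree: %d leaves, metric=%s, linkage=%s",
             len(result.leaves), cfg.metric, cfg.linkage)
    if cfg.newick_out:
        with open(cfg.newick_out, "w", encoding="utf-8") as fh:
            fh.write(result.newick + "\n")
    if cfg.matrix_out:
        if cfg.matrix_out.endswith(".phylip"):
            result.matrix.to_phylip(cfg.matrix_out)
        else:
            result.matrix.to_tsv(cfg.matrix_out)
    if cfg.svg_out:
        run_render(cfg, result=result)
    return result


def run_render(
    cfg: RunConfig,
    leaf_filter: str = "",
    result: Optional[TreeResult] = None,
) -> Optional[str]:
    """Render the context panels of leaves passing a name filter to SVG.

    Returns the output path, or None (with a warning) when the filter
    matches no leaf.
    """
    if result is None:
        svg_out, cfg.svg_out = cfg.svg_out, None
        try:
            result = run_build_tree(cfg)
        finally:
            cfg.svg_out = svg_out
    if not cfg.svg_out:
        raise UsageError("no SVG output path configured")

    selected = set(select_leaves(result.tree, leaf_filter))
    leaves = [lf for lf in result.leaves if lf.leaf_name in selected]
    if not leaves:
        log.warning("leaf filter %r matched nothing; no SVG written", leaf_filter)
        return None
    colors = color_assignment(leaves, cfg.comparison_key)
    by_species = {g.species_name: g for g in result.genomes}
    opts = cfg.render_options(colors)
    layouts = [
        layout_context(lf, by_species[lf.species_name], opts) for lf in leaves
    ]
    render_svg(
        layouts, cfg.svg_out, legend=cfg.legend, colors=colors,
        show_coordinates=cfg.show_coordinates,
    )
    log.info("rendered %d context panels to %s", len(layouts), cfg.svg_out)
    return cfg.svg_out
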