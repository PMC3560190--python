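"""SVG rendering of genomic contexts: a static multi-genome browser.

Each context grouping becomes one panel: genes are rectangles above
(forward strand) or below (reverse strand) a centerline, placed linearly in
nucleotide coordinates and centered on the midpoint of the grouping's span.
Genes are colored by identity key (homology cluster or annotation) so the
same gene family shows the same color in every species; genes flanking the
context can be shown in gray.  Output is deterministic SVG 1.1.
"""

from __future__ import annotations

import colorsys
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Hashable, Optional, Sequence

from .errors import UsageError
from .metrics import identity_key
from .model import ContextGrouping, Genome

SURROUNDING_GRAY = "#808080"

# layout constants (pixels)
PANEL_WIDTH = 900.0
PANEL_HEIGHT = 90.0
MARGIN_X = 30.0
GENE_HEIGHT = 18.0
LEGEND_ROW = 18.0


@dataclass(frozen=True)
class RenderOptions:
    """Display toggles mirroring the genome-display checkbox panel."""

    show_coordinates: bool = False
    normalize_strand: bool = True
    show_surrounding: bool = False
    color_surrounding: bool = False
    flank_nt: int = 0
    colors: dict = field(default_factory=dict)
    comparison_key: str = "homology_cluster"

    def __post_init__(self) -> None:
        if self.flank_nt < 0:
            raise UsageError("flank_nt must be >= 0")


@dataclass(frozen=True)
class Glyph:
    """One placed gene rectangle, in panel pixel coordinates."""

    gene_id: str
    x0: float
    x1: float
    above: bool
    fill: str
    surrounding: bool = False
    label: str = ""


@dataclass
class PanelLayout:
    """All glyphs of one context panel plus its coordinate window."""

    leaf_name: str
    glyphs: list[Glyph]
    window_start: int
    window_end: int
    mirrored: bool = False


def color_assignment(
    leaves: Sequence[ContextGrouping], key: str = "homology_cluster"
) -> dict[Hashable, str]:
    """Deterministic color per identity key, hues maximally spaced.

    Keys are sorted (by string form) and placed evenly around the HSV hue
    wheel, so reruns and machines agree; gray is reserved for surrounding
    genes and never assigned.
    """
    keys = sorted(
        {k for g in leaves for gene in g.genes
         if (k := identity_key(gene, key)) is not None},
        key=str,
    )
    n = max(len(keys), 1)
    out = {}
    for i, k in enumerate(keys):
        r, g, b = colorsys.hsv_to_rgb(i / n, 0.65, 0.85)
        out[k] = f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}"
    return out


def mirror_layout(layout: PanelLayout) -> PanelLayout:
    """Mirror a panel about its vertical center, flipping strands.

    An involution: mirroring twice restores the original layout.
    """
    cx = PANEL_WIDTH / 2.0
    glyphs = [
        replace(gl, x0=2 * cx - gl.x1, x1=2 * cx - gl.x0, above=not gl.above)
        for gl in layout.glyphs
    ]
    glyphs.sort(key=lambda gl: (gl.x0, gl.gene_id))
    return replace(layout, glyphs=glyphs, mirrored=not layout.mirrored)


def layout_context(
    g: ContextGrouping, genome: Genome, opts: RenderOptions = RenderOptions()
) -> PanelLayout:
    """Place one grouping's genes (and optional flanking genes) in a panel.

    The panel midpoint maps to the center of the grouping's span; x extent
    is an affine function of nucleotide position.  With ``normalize_strand``
    a panel whose genes sit mostly on the reverse strand is mirrored.
    """
    for gene in g.genes:
        if genome.get(gene.gene_id) != gene:
            raise UsageError(
                f"grouping gene {gene.gene_id!r} is not part of genome "
                f"{genome.species_name!r}"
            )
    window_start = g.span_start - opts.flank_nt
    window_end = g.span_end + opts.flank_nt
    center_nt = (g.span_start + g.span_end) / 2.0
    span_nt = max(window_end - window_start + 1, 1)
    scale = (PANEL_WIDTH - 2 * MARGIN_X) / span_nt
    cx = PANEL_WIDTH / 2.0

    def to_px(pos: float) -> float:
        return cx + (pos - center_nt) * scale

    shown: list[tuple] = [(gene, False) for gene in g.genes]
    if opts.show_surrounding:
        in_group = set(g.gene_ids())
        for gene in genome.contig_features(g.contig):
            if gene.gene_id in in_group:
                continue
            if gene.end >= window_start and gene.start <= window_end:
                shown.append((gene, True))

    glyphs = []
    for gene, surrounding in shown:
        if surrounding and not opts.color_surrounding:
            fill = SURROUNDING_GRAY
        else:
            k = identity_key(gene, opts.comparison_key)
            fill = opts.colors.get(k, SURROUNDING_GRAY)
        glyphs.append(
            Glyph(
                gene_id=gene.gene_id,
                x0=to_px(gene.start),
                x1=to_px(gene.end + 1),
                above=gene.strand == "+",
                fill=fill,
                surrounding=surrounding,
                label=gene.gene_id,
            )
        )
    glyphs.sort(key=lambda gl: (gl.x0, gl.gene_id))
    layout = PanelLayout(g.leaf_name or "", glyphs, window_start, window_end)

    if opts.normalize_strand:
        minus = sum(1 for gene in g.genes if gene.strand == "-")
        if minus * 2 > len(g.genes):  # strict majority; ties keep orientation
            layout = mirror_layout(layout)
    return layout


def render_svg(
    layouts: Sequence[PanelLayout],
    out_path: str,
    legend: bool = False,
    colors: Optional[dict] = None,
    show_coordinates: bool = False,
) -> None:
    """Write stacked context panels (leaf order preserved) as SVG 1.1."""
    if not layouts:
        raise UsageError("nothing to render: no layouts given")
    colors = colors or {}
    legend_keys = sorted(colors, key=str) if legend else []
    height = PANEL_HEIGHT * len(layouts) + LEGEND_ROW * len(legend_keys) + (
        30.0 if legend_keys else 0.0
    )

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": f"{PANEL_WIDTH:g}",
            "height": f"{height:g}",
            "viewBox": f"0 0 {PANEL_WIDTH:g} {height:g}",
        },
    )
    for i, layout in enumerate(layouts):
        top = i * PANEL_HEIGHT
        mid = top + PANEL_HEIGHT / 2.0
        panel = ET.SubElement(svg, "g", {"id": f"panel-{i}"})
        ET.SubElement(
            panel, "line",
            {"x1": f"{MARGIN_X:g}", "y1": f"{mid:g}",
             "x2": f"{PANEL_WIDTH - MARGIN_X:g}", "y2": f"{mid:g}",
             "stroke": "#404040", "stroke-width": "1"},
        )
        label = ET.SubElement(
            panel, "text",
            {"x": f"{MARGIN_X:g}", "y": f"{top + 14:g}", "font-size": "12",
             "font-family": "sans-serif"},
        )
        label.text = layout.leaf_name
        for gl in layout.glyphs:
            y = mid - GENE_HEIGHT - 2 if gl.above else mid + 2
            ET.SubElement(
                panel, "rect",
                {"x": f"{gl.x0:.2f}", "y": f"{y:.2f}",
                 "width": f"{max(gl.x1 - gl.x0, 0.5):.2f}",
                 "height": f"{GENE_HEIGHT:g}", "fill": gl.fill,
                 "stroke": "#202020", "stroke-width": "0.5"},
            )
        if show_coordinates:
            for x, pos in (
                (MARGIN_X, layout.window_start),
                (PANEL_WIDTH - MARGIN_X, layout.window_end),
            ):
                t = ET.SubElement(
                    panel, "text",
                    {"x": f"{x:g}", "y": f"{top + PANEL_HEIGHT - 4:g}",
                     "font-size": "10", "font-family": "sans-serif",
                     "text-anchor": "middle"},
                )
                t.text = str(pos)

    if legend_keys:
        base = PANEL_HEIGHT * len(layouts) + 20.0
        lg = ET.SubElement(svg, "g", {"id": "legend"})
        for j, k in enumerate(legend_keys):
            y = base + j * LEGEND_ROW
            ET.SubElement(
                lg, "rect",
                {"x": f"{MARGIN_X:g}", "y": f"{y:.2f}", "width": "14",
                 "height": "14", "fill": colors[k]},
            )
            t = ET.SubElement(
                lg, "text",
                {"x": f"{MARGIN_X + 20:g}", "y": f"{y + 12:.2f}",
                 "font-size": "12", "font-family": "sans-serif"},
            )
            t.text = str(k)

    ET.indent(svg)
    data = ET.tostring(svg, encoding="unicode", xml_declaration=False)
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(data)
        fh.write("\n")
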