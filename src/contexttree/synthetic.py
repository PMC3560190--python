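"""Synthetic genomes and homology maps with known-answer context structure.

Real cross-species context analyses need annotated genomes plus an upstream
homology clustering; for testing, this module fabricates both, together with
the ground truth the pipeline should recover.  The flagship scenario,
``single_gene_vs_operon``, plants in each species either a lone copy of the
query gene family or the query gene inside a four-gene same-strand operon
(gaps <= 20 nt) — the contrast between a solitary ggt-like gene and an
hpxWXYZ-like operon that context trees are designed to separate.

Gene lengths are drawn uniformly from 300–1500 nt (plausible microbial
genes); background genes are spaced >= 200 nt apart so they never chain with
the planted construct at the thresholds under study.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UsageError
from .io import write_gff
from .metrics import DissimilarityMatrix
from .model import GeneFeature, Genome, HomologyMap

SCENARIOS = ("conserved_operon", "single_gene_vs_operon", "gap_variation", "tie_block")

QUERY_CLUSTER = 1          # the planted query gene family
OPERON_CLUSTERS = (1, 2, 3, 4)   # query gene plus three companions
GENE_LEN_RANGE = (300, 1500)
BACKGROUND_GAP_RANGE = (200, 800)
OPERON_GAP_RANGE = (3, 18)       # always <= the 20 nt operon threshold


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study; generation is seed-deterministic."""

    scenario: str = "single_gene_vs_operon"
    n_species: int = 6
    genes_per_genome: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise UsageError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_species < 1 or self.genes_per_genome < 1:
            raise UsageError("n_species and genes_per_genome must be >= 1")


def _gene_length(rng: np.random.Generator) -> int:
    return int(rng.integers(GENE_LEN_RANGE[0], GENE_LEN_RANGE[1] + 1))


def _background_gap(rng: np.random.Generator) -> int:
    return int(rng.integers(BACKGROUND_GAP_RANGE[0], BACKGROUND_GAP_RANGE[1] + 1))


def _species_name(i: int) -> str:
    return f"Species_{i + 1:02d}"


def generate_scenario(
    spec: ScenarioSpec, out_dir: Optional[str] = None
) -> tuple[list[Genome], HomologyMap, dict]:
    """Build the genomes, homology map and ground truth of one scenario.

    With ``out_dir``, also writes one GFF per species, a long-format
    homology table (``homology.tsv``) and a species mapping file
    (``genomes.tsv``), byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[Genome] = []
    assignments: dict[tuple[str, str], int] = {}
    expected: dict = {"scenario": spec.scenario, "query_cluster": QUERY_CLUSTER,
                      "types": {}, "planted_gaps": {}}

    for i in range(spec.n_species):
        species = _species_name(i)
        construct = _construct_for(spec, i, rng, expected, species)
        n_construct = len(construct)
        n_background = max(spec.genes_per_genome - n_construct, 0)
        insert_at = n_background // 2

        feats: list[GeneFeature] = []
        cursor = int(rng.integers(500, 2001))
        idx = 0

        def emit(cluster: int, strand: str, length: int, gap_before: int) -> None:
            nonlocal cursor, idx
            cursor += gap_before
            gid = f"{species}_g{idx:03d}"
            start, end = cursor, cursor + length - 1
            annotation = _annotation_for(cluster)
            feats.append(GeneFeature(gid, "chr1", start, end, strand, annotation))
            assignments[(species, gid)] = cluster
            cursor = end + 1
            idx += 1

        placed_construct = False
        for b in range(n_background):
            if b == insert_at:
                _emit_construct(construct, emit, rng)
                placed_construct = True
            strand = "+" if (b % 2 == 0) else "-"
            emit(1000 + b, strand, _gene_length(rng), _background_gap(rng))
        if not placed_construct:
            _emit_construct(construct, emit, rng)

        genomes.append(Genome(species, feats))

    homology = HomologyMap(assignments)
    genomes = homology.annotate(genomes)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "genomes.tsv"), "w", encoding="utf-8") as fh:
            for g in genomes:
                path = os.path.join(out_dir, f"{g.species_name}.gff")
                write_gff(g, path)
                fh.write(f"{g.species_name}\t{g.species_name}.gff\n")
        with open(os.path.join(out_dir, "homology.tsv"), "w", encoding="utf-8") as fh:
            for (sp, gid), cl in sorted(assignments.items()):
                fh.write(f"{sp}\t{gid}\t{cl}\n")

    return genomes, homology, expected


def _annotation_for(cluster: int) -> str:
    if cluster == QUERY_CLUSTER:
        return "gamma-glutamyl transpeptidase family protein"
    if cluster in OPERON_CLUSTERS:
        return f"operon companion protein {cluster}"
    return f"hypothetical protein fam{cluster}"


def _construct_for(
    spec: ScenarioSpec, i: int, rng: np.random.Generator, expected: dict, species: str
) -> list[tuple[int, int]]:
    """The planted construct: list of (cluster, gap_before_within_construct)."""
    if spec.scenario == "single_gene_vs_operon":
        # alternate types so any species count >= 2 yields both groups
        is_operon = i % 2 == 1
        expected["types"][species] = "operon" if is_operon else "single"
        if not is_operon:
            return [(QUERY_CLUSTER, 0)]
        gaps = [int(rng.integers(*OPERON_GAP_RANGE)) for _ in range(3)]
        expected["planted_gaps"][species] = gaps
        return [(OPERON_CLUSTERS[0], 0)] + [
            (c, g) for c, g in zip(OPERON_CLUSTERS[1:], gaps)
        ]
    if spec.scenario == "conserved_operon":
        expected["types"][species] = "operon"
        gaps = [10, 12, 8]  # identical across species: all pairwise distances 0
        expected["planted_gaps"][species] = gaps
        return [(OPERON_CLUSTERS[0], 0)] + [
            (c, g) for c, g in zip(OPERON_CLUSTERS[1:], gaps)
        ]
    if spec.scenario == "gap_variation":
        expected["types"][species] = "operon"
        gaps = [int(rng.integers(5, 71)) for _ in range(2)]
        expected["planted_gaps"][species] = gaps
        return [(QUERY_CLUSTER, 0), (2, gaps[0]), (3, gaps[1])]
    # tie_block: two-gene context {0, i}: every pair shares exactly cluster 0,
    # so all pairwise Dice dissimilarities equal 0.5 — a mutual tie
    expected["types"][species] = "tie"
    return [(QUERY_CLUSTER, 0), (50 + i, 10)]


def _emit_construct(construct, emit, rng: np.random.Generator) -> None:
    first = True
    for cluster, gap in construct:
        gap_before = _background_gap(rng) if first else gap
        emit(cluster, "+", _gene_length(rng), gap_before)
        first = False


def generate_tie_block(k: int, d: float) -> DissimilarityMatrix:
    """A k x k matrix with every off-diagonal equal to d: a perfect tie."""
    if k < 2:
        raise UsageError("a tie block needs k >= 2")
    if d <= 0:
        raise UsageError("tie dissimilarity must be positive")
    values = np.full((k, k), float(d))
    np.fill_diagonal(values, 0.0)
    leaves = [f"L{i + 1}" for i in range(k)]
    return DissimilarityMatrix(leaves, values, metric="dice")
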