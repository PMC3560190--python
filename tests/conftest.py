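import numpy as np
import pytest

from contexttree import ContextGrouping, GeneFeature, Genome


def mkgene(gene_id, start, end, strand="+", contig="c1", annotation="", cluster=None):
    return GeneFeature(gene_id, contig, start, end, strand, annotation, cluster)


def mkgrouping(genes, species="spA", leaf_name="spA-1"):
    return ContextGrouping(species, genes[0].contig, list(genes), leaf_name=leaf_name)


def random_genome(rng: np.random.Generator, species="spX", n_genes=30, n_contigs=2):
    """A random genome with mixed strands and gaps spanning the thresholds."""
    feats = []
    for c in range(n_contigs):
        cursor = int(rng.integers(1, 500))
        for i in range(n_genes // n_contigs):
            length = int(rng.integers(150, 1200))
            feats.append(
                GeneFeature(
                    f"{species}_c{c}_g{i}", f"contig{c}", cursor,
                    cursor + length - 1,
                    "+" if rng.random() < 0.5 else "-",
                    f"protein {i}", int(rng.integers(1, 12)),
                )
            )
            cursor += length + int(rng.integers(0, 120))
    return Genome(species, feats)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def operon_pair():
    """Two same-strand genes 15 nt apart: within the 20 nt operon threshold."""
    return Genome("spA", [mkgene("g1", 100, 400), mkgene("g2", 416, 900)])
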