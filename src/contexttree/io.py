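"""Readers and writers for annotated genomes and the tables around them.

Genomes arrive as 9-column tab-delimited GFF.  Real annotation files mix the
GFF2 attribute style (``key value; key value``) with the GFF3 style
(``key=value;key=value``), so the attribute column is dialect-autodetected
per line.  Homology clusters and custom groupings are plain TSV.  All
readers tolerate ``#`` comment lines and blank lines.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Optional, Sequence

from .errors import InputError, ParseError
from .model import ContextGrouping, GeneFeature, Genome, HomologyMap

# Attribute keys tried in order for the gene identifier and its annotation.
GENE_ID_KEYS = ("locus_tag", "ID", "gene_id", "gene")
ANNOTATION_KEYS = ("product", "Note", "annotation", "description")

DEFAULT_RETAIN_TYPES = frozenset({"gene", "CDS"})

_GFF3_ATTR = re.compile(r"\s*([^=;\s][^=;]*?)\s*=\s*([^;]*)\s*")


def _parse_attributes(raw: str) -> dict[str, str]:
    """Parse one GFF attribute column, autodetecting GFF2 vs GFF3 style."""
    attrs: dict[str, str] = {}
    raw = raw.strip()
    if not raw or raw == ".":
        return attrs
    gff3 = "=" in raw.split(";", 1)[0]
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if gff3:
            m = _GFF3_ATTR.fullmatch(chunk)
            if not m:
                continue
            key, value = m.group(1), m.group(2)
        else:
            parts = chunk.split(None, 1)
            key = parts[0]
            value = parts[1] if len(parts) > 1 else ""
        value = value.strip().strip('"')
        attrs.setdefault(key, value)
    return attrs


def _first_of(attrs: dict[str, str], keys: Sequence[str]) -> Optional[str]:
    for k in keys:
        if k in attrs and attrs[k] != "":
            return attrs[k]
    return None


def parse_gff(
    path: str | os.PathLike,
    species_name: str,
    retain_types: frozenset[str] | set[str] = DEFAULT_RETAIN_TYPES,
) -> Genome:
    """Read one tab-delimited GFF file into a :class:`Genome`.

    Records whose feature type (column 3) is not in ``retain_types`` are
    skipped.  When a ``gene`` record and a ``CDS`` record share an identifier
    the ``gene`` record wins.  Strand must be ``+`` or ``-``: contexts are
    stranded objects, so strandless records are a parse error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"GFF file not found: {path}")

    chosen: dict[str, GeneFeature] = {}
    chosen_type: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, found {len(cols)}",
                    path, lineno,
                )
            _, _, ftype, start_s, end_s, _, strand, _, attr_col = cols[:9]
            if ftype not in retain_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}..{end_s!r}", path, lineno
                ) from None
            if end < start:
                raise ParseError(f"end {end} < start {start}", path, lineno)
            if strand not in ("+", "-"):
                raise ParseError(
                    f"strand must be '+' or '-', found {strand!r}", path, lineno
                )
            attrs = _parse_attributes(attr_col)
            gene_id = _first_of(attrs, GENE_ID_KEYS)
            if gene_id is None:
                gene_id = f"{cols[0]}:{start}-{end}({strand})"
            annotation = _first_of(attrs, ANNOTATION_KEYS) or ""
            feat = GeneFeature(gene_id, cols[0], start, end, strand, annotation)
            if gene_id in chosen:
                # deterministic dedup: 'gene' beats 'CDS'; first record otherwise
                if chosen_type[gene_id] != "gene" and ftype == "gene":
                    chosen[gene_id] = feat
                    chosen_type[gene_id] = ftype
                continue
            chosen[gene_id] = feat
            chosen_type[gene_id] = ftype
    return Genome(species_name, list(chosen.values()))


def write_gff(genome: Genome, path: str | os.PathLike) -> None:
    """Write a genome back to GFF3; inverse of :func:`parse_gff`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            attrs = [f"locus_tag={f.gene_id}"]
            if f.annotation:
                attrs.append(f"product={f.annotation}")
            fh.write(
                "\t".join([
                    f.contig, "contexttree", "gene", str(f.start), str(f.end),
                    ".", f.strand, ".", ";".join(attrs),
                ]) + "\n"
            )


def _data_rows(path: str) -> Iterable[tuple[int, str]]:
    if not os.path.exists(path):
        raise InputError(f"file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_species_mapping(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a 2-column TSV of species name -> GFF path, preserving order."""
    path = os.fspath(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, line in _data_rows(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, found {len(cols)}", path, lineno
            )
        species, gff_path = cols[0].strip(), cols[1].strip()
        if species in seen:
            raise InputError(f"duplicate species name {species!r} in {path}")
        seen.add(species)
        out.append((species, gff_path))
    return out


HOMOLOGY_FORMATS = ("long", "cluster_per_line")


def parse_homology_table(path: str | os.PathLike, format_id: str = "long") -> HomologyMap:
    """Read a cross-species homology-cluster table.

    Two layouts are supported:

    ``long``
        one row per gene: ``species<TAB>gene_id<TAB>cluster_id``
    ``cluster_per_line``
        one row per cluster: ``cluster_id<TAB>species|gene<TAB>species|gene...``

    A gene assigned to two different clusters is an input error.
    """
    path = os.fspath(path)
    if format_id not in HOMOLOGY_FORMATS:
        raise InputError(
            f"unknown homology table format {format_id!r}; "
            f"supported: {', '.join(HOMOLOGY_FORMATS)}"
        )
    assignments: dict[tuple[str, str], int] = {}

    def assign(species: str, gene_id: str, cluster: int, lineno: int) -> None:
        key = (species, gene_id)
        if key in assignments and assignments[key] != cluster:
            raise InputError(
                f"{path}:{lineno}: gene {species}/{gene_id} assigned to clusters "
                f"{assignments[key]} and {cluster}"
            )
        assignments[key] = cluster

    for lineno, line in _data_rows(path):
        cols = line.split("\t")
        if format_id == "long":
            if len(cols) != 3:
                raise ParseError(
                    f"expected 3 tab-separated columns, found {len(cols)}", path, lineno
                )
            species, gene_id, cluster_s = (c.strip() for c in cols)
            try:
                cluster = int(cluster_s)
            except ValueError:
                raise ParseError(
                    f"non-integer cluster ID {cluster_s!r}", path, lineno
                ) from None
            assign(species, gene_id, cluster, lineno)
        else:
            if len(cols) < 2:
                raise ParseError("expected cluster ID plus at least one member", path, lineno)
            try:
                cluster = int(cols[0].strip())
            except ValueError:
                raise ParseError(
                    f"non-integer cluster ID {cols[0]!r}", path, lineno
                ) from None
            for member in cols[1:]:
                member = member.strip()
                if not member:
                    continue
                if "|" not in member:
                    raise ParseError(
                        f"member {member!r} is not of form species|gene_id", path, lineno
                    )
                species, gene_id = member.split("|", 1)
                assign(species, gene_id, cluster, lineno)
    return HomologyMap(assignments)


def parse_custom_groupings(
    path: str | os.PathLike, genomes: Sequence[Genome]
) -> list[ContextGrouping]:
    """Read a 3-column TSV (species, grouping label, gene_id) of custom contexts.

    One grouping is produced per (species, label) pair, genes sorted by
    genomic position regardless of row order.  Unknown species or gene IDs
    are input errors.
    """
    path = os.fspath(path)
    by_species = {g.species_name: g for g in genomes}
    collected: dict[tuple[str, str], list[GeneFeature]] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in _data_rows(path):
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(
                f"expected 3 tab-separated columns, found {len(cols)}", path, lineno
            )
        species, label, gene_id = (c.strip() for c in cols)
        genome = by_species.get(species)
        if genome is None:
            raise InputError(f"{path}:{lineno}: unknown species {species!r}")
        feat = genome.get(gene_id)
        if feat is None:
            raise InputError(
                f"{path}:{lineno}: gene {gene_id!r} not present in genome {species!r}"
            )
        key = (species, label)
        if key not in collected:
            collected[key] = []
            order.append(key)
        collected[key].append(feat)
    out = []
    for species, label in order:
        genes = collected[(species, label)]
        contig = genes[0].contig
        if any(g.contig != contig for g in genes):
            raise InputError(
                f"{path}: grouping {label!r} of {species!r} spans multiple contigs"
            )
        out.append(ContextGrouping(species, contig, genes, leaf_name=label))
    return out
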