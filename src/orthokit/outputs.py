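"""Serialisation of orthogroup partitions.

Two formats: plain text (one orthogroup per line, ``OG0000000: geneA geneB``)
and OrthoXML 0.3, the Quest for Orthologs community standard.  Reading
supports both the native plain-text dialect and OrthoMCL-style
``GROUP: members`` lines (auto-detected — the dialects are identical up to
the group label).
"""

from __future__ import annotations

from typing import IO

from lxml import etree

from .data_io import DataError, SequenceCatalog
from .mcl import Partition

__all__ = [
    "write_plain_text",
    "write_unassigned",
    "write_orthoxml",
    "read_partition",
    "ORTHOXML_NS",
]

ORTHOXML_NS = "http://orthoXML.org/2011/"


def _sorted_genes(genes: set[int], catalog: SequenceCatalog) -> list[int]:
    return sorted(
        genes, key=lambda g: (catalog.gene_species[g], catalog.gene_names[g])
    )


def write_plain_text(
    partition: Partition, catalog: SequenceCatalog, stream: IO[str]
) -> None:
    """One line per orthogroup: ``OG<7-digit index>: name1 name2 ...``,
    members sorted by species then name."""
    for i, group in enumerate(partition.orthogroups):
        names = " ".join(
            catalog.gene_names[g] for g in _sorted_genes(group, catalog)
        )
        stream.write(f"OG{i:07d}: {names}\n")


def write_unassigned(
    partition: Partition, catalog: SequenceCatalog, stream: IO[str]
) -> None:
    """Unassigned singletons, one external gene name per line."""
    for g in _sorted_genes(partition.unassigned, catalog):
        stream.write(catalog.gene_names[g] + "\n")


def write_orthoxml(
    partition: Partition,
    catalog: SequenceCatalog,
    stream: IO[bytes],
    origin: str = "orthokit",
    origin_version: str = "0.1.0",
) -> None:
    """Write the partition as OrthoXML 0.3.

    One ``species`` element per proteome carrying its genes (internal numeric
    ids plus external protein identifiers), then one flat ``orthologGroup``
    per orthogroup referencing genes by internal id.  XML-reserved characters
    in gene names are escaped by the serialiser.
    """
    nsmap = {None: ORTHOXML_NS}
    root = etree.Element("orthoXML", nsmap=nsmap)
    root.set("version", "0.3")
    root.set("origin", origin)
    root.set("originVersion", origin_version)

    for sp_id, sp_name in enumerate(catalog.species_names):
        sp_el = etree.SubElement(root, "species")
        sp_el.set("name", sp_name)
        sp_el.set("NCBITaxId", "0")  # unknown taxon; placeholder required by schema
        db = etree.SubElement(sp_el, "database")
        db.set("name", origin)
        db.set("version", origin_version)
        genes_el = etree.SubElement(db, "genes")
        for g in catalog.genes_of_species(sp_id):
            gene_el = etree.SubElement(genes_el, "gene")
            gene_el.set("id", str(int(g)))
            gene_el.set("protId", catalog.gene_names[g])

    groups_el = etree.SubElement(root, "groups")
    for i, group in enumerate(partition.orthogroups):
        og_el = etree.SubElement(groups_el, "orthologGroup")
        og_el.set("id", f"OG{i:07d}")
        for g in _sorted_genes(group, catalog):
            ref = etree.SubElement(og_el, "geneRef")
            ref.set("id", str(int(g)))

    tree = etree.ElementTree(root)
    tree.write(stream, xml_declaration=True, encoding="utf-8",
               pretty_print=True)


def read_partition(stream: IO[str], catalog: SequenceCatalog) -> Partition:
    """Parse plain-text orthogroups back into a :class:`Partition`.

    Lines are ``LABEL: name name ...``; catalogue genes not listed become
    unassigned, as do genes on single-member lines.  Unknown gene names and
    genes appearing in more than one group are errors.
    """
    clusters: list[set[int]] = []
    seen: dict[int, str] = {}
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        if ":" not in line:
            raise DataError(f"line {line_no}: expected 'LABEL: members'")
        label, _, members = line.partition(":")
        genes: set[int] = set()
        for name in members.split():
            g = catalog.gene_id(name)
            if g in seen:
                raise DataError(
                    f"gene {name!r} appears in both {seen[g]!r} and "
                    f"{label.strip()!r}"
                )
            seen[g] = label.strip()
            genes.add(g)
        if genes:
            clusters.append(genes)
    return Partition.from_clusters(clusters, set(range(catalog.n_genes)))
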