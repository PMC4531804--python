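"""Reading proteomes and all-vs-all similarity search results.

Input conventions follow the common comparative-genomics layout: one protein
FASTA file per species, and one 12-column tabular similarity file
(``blastp -outfmt 6``) per *ordered* species pair, including the same-species
searches.  Genes are given dense integer ids across the whole dataset; species
are numbered by the order of their FASTA files.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceCatalog",
    "HitTable",
    "read_fasta_lengths",
    "parse_blast_tabular",
    "dedupe_hits",
    "write_hit_table",
    "write_id_maps",
]

#: column names of BLAST tabular output (-outfmt 6)
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_EVALUE_MAX = 1e-3


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class SequenceCatalog:
    """Dense id maps for all genes across all input species.

    Attributes
    ----------
    species_names :
        One name per species, in input order; ``species_id`` indexes this list.
    gene_species :
        Array of length ``n_genes`` mapping each gene id to its species id.
    gene_names :
        External name of each gene (FASTA header token up to first whitespace).
    gene_headers :
        Full FASTA header line per gene (without the leading ``>``).
    lengths :
        Protein length in amino acids per gene (terminal ``*`` stripped).
    """

    species_names: list[str]
    gene_species: np.ndarray
    gene_names: list[str]
    gene_headers: list[str]
    lengths: np.ndarray
    _name_to_id: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._name_to_id:
            self._name_to_id = {n: i for i, n in enumerate(self.gene_names)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def gene_id(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise DataError(f"unknown sequence name: {name!r}") from None

    def genes_of_species(self, species_id: int) -> np.ndarray:
        return np.flatnonzero(self.gene_species == species_id)

    def all_genes(self) -> np.ndarray:
        return np.arange(self.n_genes)

    def subset(self, keep: Iterable[int]) -> "SequenceCatalog":
        """Catalogue restricted to ``keep`` gene ids, with re-densified ids.

        Returns the new catalogue; use :meth:`old_to_new` style mapping via the
        returned object's ``gene_names`` to translate external data.
        """
        keep = np.asarray(sorted(set(int(g) for g in keep)))
        return SequenceCatalog(
            species_names=list(self.species_names),
            gene_species=self.gene_species[keep].copy(),
            gene_names=[self.gene_names[g] for g in keep],
            gene_headers=[self.gene_headers[g] for g in keep],
            lengths=self.lengths[keep].copy(),
        )


@dataclass
class HitTable:
    """Directed similarity records for one ordered species pair.

    ``hits`` is a DataFrame with integer columns ``query``/``subject``
    (dense gene ids) and float columns ``bitscore``/``evalue``.
    """

    species_pair: tuple[int, int]
    hits: pd.DataFrame

    def __len__(self) -> int:
        return len(self.hits)

    def copy(self) -> "HitTable":
        return HitTable(self.species_pair, self.hits.copy())


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": pd.Series(dtype=np.int64),
            "subject": pd.Series(dtype=np.int64),
            "bitscore": pd.Series(dtype=float),
            "evalue": pd.Series(dtype=float),
        }
    )


def read_fasta_lengths(
    fasta_sources: Sequence[tuple[str, IO[str] | str | Path]],
) -> SequenceCatalog:
    """Build a :class:`SequenceCatalog` from per-species FASTA files.

    Parameters
    ----------
    fasta_sources :
        ``(species_name, source)`` pairs where ``source`` is a path or an open
        text handle.  Species ids follow the given order.

    Raises
    ------
    DataError
        On fewer than two species, an empty file, a duplicate header within
        one file, or a zero-length sequence after stripping terminal stops.
    """
    if len(fasta_sources) < 2:
        raise DataError("at least 2 species FASTA files are required")

    species_names: list[str] = []
    gene_species: list[int] = []
    gene_names: list[str] = []
    gene_headers: list[str] = []
    lengths: list[int] = []

    for sp_id, (sp_name, source) in enumerate(fasta_sources):
        species_names.append(sp_name)
        if isinstance(source, (str, Path)):
            handle: IO[str] = open(source)
            close = True
        else:
            handle, close = source, False
        try:
            seen: set[str] = set()
            n_records = 0
            for record in SeqIO.parse(handle, "fasta"):
                n_records += 1
                name = record.id
                if name in seen:
                    raise DataError(
                        f"duplicate header {name!r} in species {sp_name!r}"
                    )
                seen.add(name)
                seq = str(record.seq).rstrip("*")
                if len(seq) == 0:
                    raise DataError(
                        f"zero-length sequence {name!r} in species {sp_name!r}"
                    )
                gene_species.append(sp_id)
                gene_names.append(name)
                gene_headers.append(record.description)
                lengths.append(len(seq))
            if n_records == 0:
                raise DataError(f"no FASTA records found for species {sp_name!r}")
        finally:
            if close:
                handle.close()

    if len(set(gene_names)) != len(gene_names):
        dupes = pd.Series(gene_names)
        dupes = dupes[dupes.duplicated()].unique()
        raise DataError(f"gene names duplicated across species: {list(dupes)[:5]}")

    return SequenceCatalog(
        species_names=species_names,
        gene_species=np.asarray(gene_species, dtype=np.int64),
        gene_names=gene_names,
        gene_headers=gene_headers,
        lengths=np.asarray(lengths, dtype=np.int64),
    )


def parse_blast_tabular(
    source: IO[str] | str | Path,
    catalog: SequenceCatalog,
    species_pair: tuple[int, int],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> HitTable:
    """Parse a 12-column tabular similarity file into a :class:`HitTable`.

    Rows with e-value above ``evalue_max`` and self-hits (query == subject
    gene) are discarded.  Extra trailing columns are ignored with a warning;
    fewer than 12 columns, unknown names, or non-numeric scores are errors.
    """
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source)
        close = True
    else:
        handle, close = source, False

    queries: list[int] = []
    subjects: list[int] = []
    bitscores: list[float] = []
    evalues: list[float] = []
    warned_extra = False
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise DataError(
                    f"malformed line {line_no}: expected 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                warnings.warn(
                    f"line {line_no}: {len(fields)} columns found; ignoring "
                    "columns beyond the standard 12",
                    stacklevel=2,
                )
                warned_extra = True
            qname, sname = fields[0], fields[1]
            q = catalog.gene_id(qname)
            s = catalog.gene_id(sname)
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise DataError(
                    f"malformed line {line_no}: non-numeric evalue/bitscore "
                    f"({fields[10]!r}, {fields[11]!r})"
                ) from None
            if evalue > evalue_max:
                continue
            if q == s:
                continue
            if catalog.gene_species[q] != species_pair[0]:
                raise DataError(
                    f"line {line_no}: query {qname!r} does not belong to "
                    f"species {species_pair[0]}"
                )
            if catalog.gene_species[s] != species_pair[1]:
                raise DataError(
                    f"line {line_no}: subject {sname!r} does not belong to "
                    f"species {species_pair[1]}"
                )
            queries.append(q)
            subjects.append(s)
            bitscores.append(bitscore)
            evalues.append(evalue)
    finally:
        if close:
            handle.close()

    if not queries:
        return HitTable(species_pair, _empty_hits())
    hits = pd.DataFrame(
        {
            "query": np.asarray(queries, dtype=np.int64),
            "subject": np.asarray(subjects, dtype=np.int64),
            "bitscore": np.asarray(bitscores, dtype=float),
            "evalue": np.asarray(evalues, dtype=float),
        }
    )
    return HitTable(species_pair, hits)


def dedupe_hits(table: HitTable) -> HitTable:
    """Collapse multiple HSPs per ordered gene pair to a single record.

    Keeps, per ``(query, subject)``: the maximal bitscore; among equal
    bitscores the minimal e-value; remaining ties broken by first occurrence.
    """
    hits = table.hits
    if hits.empty:
        return table.copy()
    # stable sort: descending bitscore, ascending evalue; first row per pair wins
    order = np.lexsort(
        (np.arange(len(hits)), hits["evalue"].to_numpy(), -hits["bitscore"].to_numpy())
    )
    best = (
        hits.iloc[order]
        .drop_duplicates(subset=["query", "subject"], keep="first")
        .sort_values(["query", "subject"], kind="stable")
        .reset_index(drop=True)
    )
    return HitTable(table.species_pair, best)


def write_hit_table(table: HitTable, catalog: SequenceCatalog, stream: IO[str]) -> None:
    """Write hits back to 12-column tabular form (round-trip companion to
    :func:`parse_blast_tabular`; alignment-coordinate columns are zero-filled)."""
    for row in table.hits.itertuples(index=False):
        stream.write(
            "\t".join(
                [
                    catalog.gene_names[row.query],
                    catalog.gene_names[row.subject],
                    "0", "0", "0", "0", "0", "0", "0", "0",
                    f"{row.evalue:.3g}",
                    f"{row.bitscore:.6g}",
                ]
            )
            + "\n"
        )


def write_id_maps(catalog: SequenceCatalog, out_dir: str | Path) -> None:
    """Write ``SpeciesIDs.txt`` and ``SequenceIDs.txt`` ("index: name") maps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "SpeciesIDs.txt", "w") as fh:
        for i, name in enumerate(catalog.species_names):
            fh.write(f"{i}: {name}\n")
    with open(out_dir / "SequenceIDs.txt", "w") as fh:
        for g in range(catalog.n_genes):
            sp = catalog.gene_species[g]
            fh.write(f"{sp}_{g}: {catalog.gene_names[g]}\n")
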