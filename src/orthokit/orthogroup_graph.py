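"""Putative cognate gene-pair selection and orthogroup graph assembly.

After normalisation, orthologue candidates are found through reciprocal best
normalised hits (RBNHs): gene pairs across two species where each is the
other's highest-scoring normalised hit.  Because recent gene duplications
routinely break plain reciprocal-best relationships, RBNHs are not used as
the edges directly.  Instead each gene's *lowest*-scoring RBNH (across all
species) sets a per-gene inclusion threshold, and any hit — to any species,
including the gene's own — scoring at or above either endpoint's threshold
becomes an edge.  Edge weights are the normalised scores; the resulting
undirected weighted graph is what gets clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .data_io import SequenceCatalog
from .normalization import NormalizedHitTable

__all__ = [
    "RBNHSet",
    "OrthogroupGraph",
    "find_rbnhs",
    "compute_thresholds",
    "build_graph",
    "write_graph",
    "read_graph",
]


@dataclass
class RBNHSet:
    """Reciprocal best normalised hits, stored symmetrically.

    ``partners[q]`` is the set of genes h (in other species) such that h is
    among q's best normalised hits in h's species and vice versa.  Exact
    score ties at the maximum all count as "best", so a gene may have several
    RBNHs in one species.
    """

    partners: dict[int, set[int]] = field(default_factory=dict)

    def add(self, q: int, h: int) -> None:
        self.partners.setdefault(q, set()).add(h)
        self.partners.setdefault(h, set()).add(q)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        q, h = pair
        return h in self.partners.get(q, ())

    def pairs(self) -> set[tuple[int, int]]:
        """All RBNH pairs as unordered (min, max) tuples."""
        return {
            (min(q, h), max(q, h))
            for q, hs in self.partners.items()
            for h in hs
        }


@dataclass
class OrthogroupGraph:
    """Undirected weighted gene graph; nodes are all catalogue genes."""

    n_genes: int
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def add_edge(self, g1: int, g2: int, weight: float) -> None:
        if g1 == g2:
            raise ValueError("self-loops are not allowed")
        key = (min(g1, g2), max(g1, g2))
        self.edges[key] = max(weight, self.edges.get(key, 0.0))

    def neighbors(self, g: int) -> set[int]:
        out = set()
        for (a, b) in self.edges:
            if a == g:
                out.add(b)
            elif b == g:
                out.add(a)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _best_hits_per_query(table: NormalizedHitTable) -> dict[int, set[int]]:
    """For each query gene: subjects achieving its exact maximum norm_score."""
    hits = table.hits
    if hits.empty:
        return {}
    best = hits.groupby("query")["norm_score"].transform("max")
    at_max = hits[hits["norm_score"] == best]
    return {
        int(q): set(int(s) for s in grp["subject"])
        for q, grp in at_max.groupby("query")
    }


def find_rbnhs(
    normalized: dict[tuple[int, int], NormalizedHitTable],
) -> RBNHSet:
    """Identify reciprocal best normalised hits between distinct species.

    ``(q, h)`` is an RBNH iff h is among q's best normalised hits in h's
    species and q is among h's best normalised hits in q's species.  Both
    directions of the species pair must have been normalised.  Within-species
    comparisons never produce RBNHs (reciprocal best is a between-species
    relation here).
    """
    best: dict[tuple[int, int], dict[int, set[int]]] = {}
    for (sa, sb), table in normalized.items():
        if sa == sb:
            continue
        best[(sa, sb)] = _best_hits_per_query(table)

    rbnhs = RBNHSet()
    for (sa, sb), fwd in best.items():
        if sa > sb:
            continue  # handle each unordered species pair once
        rev = best.get((sb, sa), {})
        for q, subjects in fwd.items():
            for h in subjects:
                if q in rev.get(h, ()):
                    rbnhs.add(q, h)
    return rbnhs


def compute_thresholds(
    rbnhs: RBNHSet,
    normalized: dict[tuple[int, int], NormalizedHitTable],
) -> dict[int, float]:
    """Per-gene inclusion threshold: the normalised score of the gene's
    lowest-scoring RBNH, irrespective of species.

    Genes with no RBNH get no threshold; they can still be pulled into the
    graph by other genes' thresholds.
    """
    score = _directional_scores(normalized)
    thresholds: dict[int, float] = {}
    for q, partners in rbnhs.partners.items():
        vals = [score[(q, h)] for h in partners if (q, h) in score]
        if vals:
            thresholds[q] = min(vals)
    return thresholds


def _directional_scores(
    normalized: dict[tuple[int, int], NormalizedHitTable],
) -> dict[tuple[int, int], float]:
    score: dict[tuple[int, int], float] = {}
    for table in normalized.values():
        hits = table.hits
        qs = hits["query"].to_numpy()
        ss = hits["subject"].to_numpy()
        ns = hits["norm_score"].to_numpy()
        for q, s, v in zip(qs, ss, ns):
            score[(int(q), int(s))] = float(v)
    return score


def build_graph(
    normalized: dict[tuple[int, int], NormalizedHitTable],
    thresholds: dict[int, float],
    rbnhs: RBNHSet,
    n_genes: int,
    gene_species: np.ndarray | None = None,
    include_within_species: bool = True,
    rbnh_only: bool = False,
) -> OrthogroupGraph:
    """Assemble the orthogroup graph from the three-clause inclusion rule.

    An edge (q, h) exists iff (q, h) is an RBNH, or ``B'_qh >= threshold(q)``,
    or ``B'_hq >= threshold(h)``.  The edge weight is the larger of the two
    directional normalised scores (only one may exist).

    Parameters
    ----------
    gene_species :
        Gene id -> species id map; required only when
        ``include_within_species`` is False.
    include_within_species :
        Whether same-species hits may form edges through the threshold
        clauses (they can never be RBNHs).  Default True.
    rbnh_only :
        Diagnostic mode: keep only RBNH edges, ignoring the threshold
        clauses.  Useful for demonstrating what plain reciprocal-best
        selection would miss.
    """
    if not include_within_species and gene_species is None:
        raise ValueError("gene_species is required when excluding "
                         "within-species hits")
    score = _directional_scores(normalized)
    graph = OrthogroupGraph(n_genes=n_genes)

    for (q, h), v in score.items():
        if q == h:
            continue
        key = (min(q, h), max(q, h))
        if key in graph.edges:
            continue
        if (not include_within_species
                and gene_species[q] == gene_species[h]):
            continue
        rev = score.get((h, q))
        weight = v if rev is None else max(v, rev)
        is_rbnh = (q, h) in rbnhs
        if rbnh_only:
            if is_rbnh:
                graph.add_edge(q, h, weight)
            continue
        passes = is_rbnh
        if not passes and q in thresholds and v >= thresholds[q]:
            passes = True
        if not passes and rev is not None and h in thresholds and rev >= thresholds[h]:
            passes = True
        if passes:
            graph.add_edge(q, h, weight)
    return graph


def write_graph(graph: OrthogroupGraph, stream: IO[str]) -> None:
    """Emit the graph in MCL label ("abc") format: ``g1\\tg2\\tweight`` per
    line, sorted by (g1, g2), weights with 6 significant digits."""
    for (g1, g2) in sorted(graph.edges):
        stream.write(f"{g1}\t{g2}\t{graph.edges[(g1, g2)]:.6g}\n")


def read_graph(stream: IO[str], n_genes: int) -> OrthogroupGraph:
    """Inverse of :func:`write_graph`."""
    graph = OrthogroupGraph(n_genes=n_genes)
    for line in stream:
        line = line.strip()
        if not line:
            continue
        a, b, w = line.split("\t")
        graph.add_edge(int(a), int(b), float(w))
    return graph
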