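"""Scoring predicted orthogroups against a curated reference.

The counting unit is gene-pair co-membership: a true positive is an
unordered gene pair placed together by both the prediction and the
reference; a false positive is together only in the prediction; a false
negative only in the reference.  Counting is restricted to genes present in
the reference (the universe), because for a partially curated reference the
true negatives are unknowable — which also rules out correlation-style
summary statistics.  From the counts:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

and the F-score is their harmonic mean.  A gene-level counting variant is
available behind ``unit="gene"`` for comparison with benchmarks that count
genes rather than pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .data_io import HitTable, SequenceCatalog
from .mcl import Partition

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "pairwise_confusion",
    "metrics_from_counts",
    "score_partition",
    "length_binned_metrics",
    "per_orthogroup_errors",
    "deletion_robustness",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    fscore: float


def _restricted_groups(
    partition: Partition, universe: set[int]
) -> list[set[int]]:
    return [g & universe for g in partition.orthogroups if len(g & universe) >= 1]


def _n_pairs(sizes: Iterable[int]) -> int:
    return sum(s * (s - 1) // 2 for s in sizes)


def pairwise_confusion(
    predicted: Partition,
    reference: Partition,
    universe: set[int] | None = None,
) -> ConfusionCounts:
    """Co-membership confusion counts over unordered gene pairs.

    ``universe`` defaults to the genes assigned in the reference.  Genes
    unassigned in the prediction are co-membered with nothing.
    """
    if not reference.orthogroups:
        raise ValueError("reference partition is empty")
    if universe is None:
        universe = set().union(*reference.orthogroups)
    pred = _restricted_groups(predicted, universe)
    ref = _restricted_groups(reference, universe)
    ref_member: dict[int, int] = {
        g: i for i, grp in enumerate(ref) for g in grp
    }
    tp = 0
    for pgrp in pred:
        by_ref: dict[int, int] = {}
        for g in pgrp:
            r = ref_member.get(g)
            if r is not None:
                by_ref[r] = by_ref.get(r, 0) + 1
        tp += _n_pairs(by_ref.values())
    pred_pairs = _n_pairs(len(g) for g in pred)
    ref_pairs = _n_pairs(len(g) for g in ref)
    return ConfusionCounts(TP=tp, FP=pred_pairs - tp, FN=ref_pairs - tp)


def gene_confusion(
    predicted: Partition,
    reference: Partition,
    universe: set[int] | None = None,
) -> ConfusionCounts:
    """Gene-level counting variant: each reference group is matched to its
    maximum-overlap predicted group; TP = genes in the overlap, FN = missing
    genes, FP = extra universe genes in the matched predicted group."""
    if not reference.orthogroups:
        raise ValueError("reference partition is empty")
    if universe is None:
        universe = set().union(*reference.orthogroups)
    report = per_orthogroup_errors(predicted, reference, universe)
    tp = sum(row["overlap"] for row in report["groups"])
    fn = sum(len(row["missing"]) for row in report["groups"])
    fp = sum(len(row["erroneous"]) for row in report["groups"])
    return ConfusionCounts(TP=tp, FP=fp, FN=fn)


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Precision/recall/F with 0/0 conventions mapping to zero."""
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    fscore = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return Metrics(precision=precision, recall=recall, fscore=fscore)


def score_partition(
    predicted: Partition,
    reference: Partition,
    universe: set[int] | None = None,
    unit: str = "pair",
) -> Metrics:
    """Convenience wrapper: confusion counts then metrics."""
    counter = {"pair": pairwise_confusion, "gene": gene_confusion}[unit]
    return metrics_from_counts(counter(predicted, reference, universe))


def _comember_pairs(groups: list[set[int]]) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for grp in groups:
        members = sorted(grp)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.add((a, b))
    return pairs


def length_binned_metrics(
    predicted: Partition,
    reference: Partition,
    catalog: SequenceCatalog,
    n_bins: int = 4,
) -> list[dict]:
    """Per-length-bin precision/recall/F over the reference universe.

    Reference genes are sorted by protein length and split into ``n_bins``
    equal-count bins (remainder spread over the earliest bins).  A gene pair
    contributes its TP/FP/FN status to the bin of *each* member, so the
    recall of a short-gene bin reflects the short genes' missing partners.
    Each report row carries the bin's min, max and geometric-mean length.
    """
    universe = set().union(*reference.orthogroups) if reference.orthogroups else set()
    if len(universe) < n_bins:
        raise ValueError(
            f"need at least {n_bins} reference genes, got {len(universe)}"
        )
    genes = sorted(universe, key=lambda g: (catalog.lengths[g], g))
    base, extra = divmod(len(genes), n_bins)
    bins: list[list[int]] = []
    pos = 0
    for i in range(n_bins):
        size = base + (1 if i < extra else 0)
        bins.append(genes[pos:pos + size])
        pos += size
    gene_bin = {g: i for i, b in enumerate(bins) for g in b}

    pred_pairs = _comember_pairs(_restricted_groups(predicted, universe))
    ref_pairs = _comember_pairs(_restricted_groups(reference, universe))
    counts = [{"TP": 0, "FP": 0, "FN": 0} for _ in range(n_bins)]
    for pair in pred_pairs | ref_pairs:
        if pair in pred_pairs and pair in ref_pairs:
            kind = "TP"
        elif pair in pred_pairs:
            kind = "FP"
        else:
            kind = "FN"
        for b in {gene_bin[pair[0]], gene_bin[pair[1]]}:
            counts[b][kind] += 1

    report = []
    for i, b in enumerate(bins):
        lengths = catalog.lengths[np.asarray(b)]
        m = metrics_from_counts(ConfusionCounts(**counts[i]))
        report.append(
            {
                "bin": i,
                "n_genes": len(b),
                "min_length": int(lengths.min()),
                "max_length": int(lengths.max()),
                "geometric_mean_length": float(
                    math.exp(np.log(lengths).mean())
                ),
                "metrics": m,
                "counts": ConfusionCounts(**counts[i]),
            }
        )
    return report


def per_orthogroup_errors(
    predicted: Partition,
    reference: Partition,
    universe: set[int] | None = None,
) -> dict:
    """Per-reference-orthogroup error report.

    Each reference group is matched to the predicted group with maximal
    overlap (ties towards the larger predicted group, then the lowest
    index).  Missing genes are reference members absent from the matched
    group; erroneous genes are universe genes in the matched group that the
    reference places elsewhere.  A group is *fragmented* when its members
    are spread over several predicted groups and *fused* when its matched
    group also holds members of another reference group.
    """
    if universe is None:
        universe = (
            set().union(*reference.orthogroups) if reference.orthogroups else set()
        )
    pred = [g for g in predicted.orthogroups]
    rows = []
    for ref_grp in reference.orthogroups:
        ref_u = ref_grp & universe
        overlaps = [
            (len(ref_u & p), len(p), -i, i) for i, p in enumerate(pred)
        ]
        best = max(overlaps, default=(0, 0, 0, -1))
        overlap, _, _, idx = best
        if overlap == 0 or idx < 0:
            matched: set[int] = set()
            idx = -1
        else:
            matched = pred[idx]
        missing = ref_u - matched
        erroneous = (matched & universe) - ref_grp
        n_pred_groups = len({
            i for i, p in enumerate(pred) if ref_u & p
        })
        rows.append(
            {
                "reference_size": len(ref_u),
                "matched_group": idx,
                "overlap": overlap,
                "missing": missing,
                "erroneous": erroneous,
                "fragmented": n_pred_groups > 1,
                "fused": bool(erroneous),
            }
        )
    n_exact = sum(
        1 for r in rows if not r["missing"] and not r["erroneous"]
    )
    return {
        "groups": rows,
        "pct_error_free": 100.0 * n_exact / len(rows) if rows else 0.0,
    }


def deletion_robustness(
    catalog: SequenceCatalog,
    hit_tables: dict[tuple[int, int], HitTable],
    reference: Partition,
    pipeline: Callable[
        [SequenceCatalog, dict[tuple[int, int], HitTable], set[int]], Partition
    ],
    deletion_fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    seed: int = 0,
) -> dict[float, Metrics]:
    """Robustness of the pipeline to random gene deletion.

    For each fraction, deletes that share of catalogue genes uniformly at
    random (with all their hits), reruns ``pipeline`` on the survivors, and
    scores against the reference restricted to surviving genes.  Gene ids
    are kept stable across deletions.
    """
    rng = np.random.default_rng(seed)
    results: dict[float, Metrics] = {}
    all_genes = np.arange(catalog.n_genes)
    for fraction in deletion_fractions:
        if not 0 <= fraction < 1:
            raise ValueError(f"deletion fraction must be in [0, 1): {fraction}")
        n_delete = int(round(fraction * catalog.n_genes))
        deleted = set(
            rng.choice(all_genes, size=n_delete, replace=False).tolist()
        )
        surviving = set(all_genes.tolist()) - deleted
        tables = {}
        for pair, table in hit_tables.items():
            hits = table.hits
            mask = hits["query"].isin(surviving) & hits["subject"].isin(surviving)
            tables[pair] = HitTable(pair, hits[mask].reset_index(drop=True))
        predicted = pipeline(catalog, tables, surviving)
        ref_universe = (
            set().union(*reference.orthogroups) & surviving
            if reference.orthogroups else set()
        )
        results[fraction] = metrics_from_counts(
            pairwise_confusion(predicted, reference, ref_universe)
        )
    return results
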