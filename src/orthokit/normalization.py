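"""Gene-length and phylogenetic-distance normalisation of bit scores.

Raw alignment bit scores grow with sequence length: long proteins produce
large scores even for mediocre hits, while short proteins can never score
highly.  Scores also shrink with evolutionary distance between the two
species being compared.  Both biases distort any clustering run directly on
the raw scores.

The transform applied here, independently for every ordered species pair,
models the score of the *best* hits as a power law in the length product
``L_qh = L_q * L_h`` (query times hit length, amino acids squared):

    log10 B_qh = a * log10 L_qh + b

fitted by ordinary least squares to the top 5 % of hits (by bit score) in
each equal-count ``L_qh`` bin.  Every hit of the pair is then rescaled as

    B'_qh = B_qh / (10**b * L_qh**a)

so a normalised score of 1 means "as good as a typical best hit between
sequences of this length for this species pair".  Because the fit is per
species pair, the intercept ``b`` absorbs the overall score depression of
distant species pairs, normalising for phylogenetic distance at the same
time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import HitTable, SequenceCatalog

__all__ = [
    "FitModel",
    "NormalizedHitTable",
    "length_products",
    "bin_hits",
    "select_top_fraction",
    "fit_loglog",
    "normalize_scores",
    "normalize_all_pairs",
]

#: bin sizes from the binning rule: 1000 hits per bin, or 200 when the pair
#: has fewer than 5000 hits in total
BIN_SIZE_LARGE = 1000
BIN_SIZE_SMALL = 200
SMALL_TABLE_CUTOFF = 5000
TOP_FRACTION = 0.05
MIN_FIT_POINTS = 10


class NormalizationError(ValueError):
    """Raised when a species pair cannot be normalised."""


@dataclass(frozen=True)
class FitModel:
    """Per-species-pair log-log linear fit ``log10 B = a log10 L + b``."""

    species_pair: tuple[int, int]
    a: float
    b: float
    n_hits_fit: int

    def expected_score(self, l_qh: np.ndarray | float) -> np.ndarray | float:
        """Bit score expected for a best hit at length product ``l_qh``."""
        return 10.0 ** self.b * np.asarray(l_qh, dtype=float) ** self.a


@dataclass
class NormalizedHitTable:
    """Hit table annotated with ``norm_score`` (and ``l_qh``) columns."""

    species_pair: tuple[int, int]
    hits: pd.DataFrame
    model: FitModel

    def __len__(self) -> int:
        return len(self.hits)


def length_products(hits: pd.DataFrame, catalog: SequenceCatalog) -> np.ndarray:
    """``L_qh = L_q * L_h`` for each hit row, as float."""
    lq = catalog.lengths[hits["query"].to_numpy()]
    lh = catalog.lengths[hits["subject"].to_numpy()]
    return (lq * lh).astype(float)


def _bin_boundaries(n: int, bin_size: int) -> list[tuple[int, int]]:
    """Consecutive [start, stop) bins of ``bin_size``; a trailing partial bin
    is merged into the preceding full bin; if n < bin_size there is one bin."""
    if n <= bin_size:
        return [(0, n)]
    n_full = n // bin_size
    bounds = [(i * bin_size, (i + 1) * bin_size) for i in range(n_full)]
    remainder = n - n_full * bin_size
    if remainder:
        start, _ = bounds[-1]
        bounds[-1] = (start, n)
    return bounds


def bin_hits(table: HitTable, catalog: SequenceCatalog) -> list[pd.DataFrame]:
    """Sort hits ascending by ``L_qh`` and split into equal-count bins.

    Bin size is 1000, or 200 when the table holds fewer than 5000 hits.  The
    final partial bin is merged into the preceding one; a table smaller than
    one bin yields a single bin.  Each returned frame carries an ``l_qh``
    column and an ``_order`` column recording the original row position (used
    downstream for deterministic tie-breaking).
    """
    if len(table) == 0:
        raise NormalizationError(
            f"no hits for species pair {table.species_pair}"
        )
    hits = table.hits.copy()
    hits["l_qh"] = length_products(hits, catalog)
    hits["_order"] = np.arange(len(hits))
    order = np.lexsort((hits["_order"].to_numpy(), hits["l_qh"].to_numpy()))
    hits = hits.iloc[order].reset_index(drop=True)
    bin_size = BIN_SIZE_LARGE if len(hits) >= SMALL_TABLE_CUTOFF else BIN_SIZE_SMALL
    return [hits.iloc[lo:hi] for lo, hi in _bin_boundaries(len(hits), bin_size)]


def select_top_fraction(
    bin_hits_df: pd.DataFrame, fraction: float = TOP_FRACTION
) -> pd.DataFrame:
    """The top ``ceil(fraction * n)`` hits of one bin by bit score.

    The ceiling guarantees at least one hit per bin.  Ties at the cut-off are
    broken towards smaller ``L_qh``, then original input order.
    """
    n = len(bin_hits_df)
    if n == 0:
        raise NormalizationError("empty bin")
    k = math.ceil(fraction * n)
    order = np.lexsort(
        (
            bin_hits_df["_order"].to_numpy(),
            bin_hits_df["l_qh"].to_numpy(),
            -bin_hits_df["bitscore"].to_numpy(),
        )
    )
    return bin_hits_df.iloc[order[:k]]


def fit_loglog(selected: pd.DataFrame, species_pair: tuple[int, int]) -> FitModel:
    """Ordinary least squares of ``log10 bitscore`` on ``log10 l_qh``."""
    l = selected["l_qh"].to_numpy(dtype=float)
    B = selected["bitscore"].to_numpy(dtype=float)
    if len(l) < 2 or np.unique(l).size < 2:
        raise NormalizationError(
            f"degenerate fit for species pair {species_pair}: "
            "fewer than 2 distinct length products; widen bins"
        )
    x = np.log10(l)
    y = np.log10(B)
    a, b = np.polyfit(x, y, 1)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise NormalizationError(
            f"non-finite fit coefficients for species pair {species_pair}"
        )
    return FitModel(species_pair=species_pair, a=float(a), b=float(b),
                    n_hits_fit=len(l))


def normalize_scores(
    table: HitTable, model: FitModel, catalog: SequenceCatalog
) -> NormalizedHitTable:
    """Annotate every hit (not just the fitted top 5 %) with its normalised
    score ``B' = B / (10**b * L_qh**a)``.  No hits are dropped."""
    hits = table.hits.copy()
    l_qh = length_products(hits, catalog)
    norm = hits["bitscore"].to_numpy(dtype=float) / (10.0 ** model.b * l_qh ** model.a)
    if not np.all(np.isfinite(norm)) or np.any(norm <= 0):
        bad = int(np.flatnonzero(~np.isfinite(norm) | (norm <= 0))[0])
        raise NormalizationError(
            f"non-finite or non-positive normalised score for hit "
            f"({catalog.gene_names[hits['query'].iloc[bad]]}, "
            f"{catalog.gene_names[hits['subject'].iloc[bad]]})"
        )
    hits["l_qh"] = l_qh
    hits["norm_score"] = norm
    return NormalizedHitTable(table.species_pair, hits, model)


def fit_pair(table: HitTable, catalog: SequenceCatalog,
             fraction: float = TOP_FRACTION) -> FitModel:
    """Bin, select the top fraction, and fit one species pair.

    If binning yields fewer than ``MIN_FIT_POINTS`` selected hits, falls back
    to a single global bin and takes enough of its top hits to reach the
    minimum (or all hits if the pair is tiny).
    """
    bins = bin_hits(table, catalog)
    selected = pd.concat([select_top_fraction(b, fraction) for b in bins])
    if len(selected) < MIN_FIT_POINTS:
        allhits = pd.concat(bins)
        k = min(len(allhits), max(MIN_FIT_POINTS, math.ceil(fraction * len(allhits))))
        order = np.lexsort(
            (
                allhits["_order"].to_numpy(),
                allhits["l_qh"].to_numpy(),
                -allhits["bitscore"].to_numpy(),
            )
        )
        selected = allhits.iloc[order[:k]]
    return fit_loglog(selected, table.species_pair)


def normalize_all_pairs(
    tables: dict[tuple[int, int], HitTable],
    catalog: SequenceCatalog,
    fraction: float = TOP_FRACTION,
) -> dict[tuple[int, int], NormalizedHitTable]:
    """Fit and normalise every ordered species pair independently.

    Same-species pairs go through the identical procedure.  Pairs with zero
    hits are skipped with a warning (they can contribute no graph edges).
    Models are never shared between pairs: the two directions of a species
    pair are fitted separately because similarity scores are not symmetric.
    """
    out: dict[tuple[int, int], NormalizedHitTable] = {}
    for pair in sorted(tables):
        table = tables[pair]
        if len(table) == 0:
            warnings.warn(
                f"species pair {pair} has no hits; skipping", stacklevel=2
            )
            continue
        model = fit_pair(table, catalog, fraction)
        out[pair] = normalize_scores(table, model, catalog)
    return out
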