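import io

import numpy as np
import pandas as pd
import pytest

from orthokit.data_io import HitTable, SequenceCatalog, read_fasta_lengths
from orthokit.normalization import FitModel, NormalizedHitTable
from orthokit.synthetic import SimulationConfig, simulate_dataset


def make_catalog(lengths_per_species: list[list[int]]) -> SequenceCatalog:
    """Catalogue with given per-species protein lengths; gene names are
    ``s<sp>g<idx>``."""
    species, names, lengths = [], [], []
    for sp, ls in enumerate(lengths_per_species):
        for i, l in enumerate(ls):
            species.append(sp)
            names.append(f"s{sp}g{i}")
            lengths.append(l)
    return SequenceCatalog(
        species_names=[f"species_{i}" for i in range(len(lengths_per_species))],
        gene_species=np.array(species, dtype=np.int64),
        gene_names=names,
        gene_headers=list(names),
        lengths=np.array(lengths, dtype=np.int64),
    )


def make_hit_table(pair, triples) -> HitTable:
    """HitTable from (query, subject, bitscore[, evalue]) tuples."""
    rows = []
    for t in triples:
        q, s, b = t[:3]
        e = t[3] if len(t) > 3 else 1e-30
        rows.append((q, s, float(b), float(e)))
    df = pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])
    df["query"] = df["query"].astype(np.int64)
    df["subject"] = df["subject"].astype(np.int64)
    return HitTable(pair, df)


def make_normalized(pair, triples, model=None) -> NormalizedHitTable:
    """NormalizedHitTable directly from (query, subject, norm_score)."""
    df = pd.DataFrame(triples, columns=["query", "subject", "norm_score"])
    df["query"] = df["query"].astype(np.int64)
    df["subject"] = df["subject"].astype(np.int64)
    df["bitscore"] = df["norm_score"]
    df["evalue"] = 1e-30
    model = model or FitModel(pair, 0.0, 0.0, len(df))
    return NormalizedHitTable(pair, df, model)


@pytest.fixture(scope="session")
def default_dataset():
    """One shared run of the default synthetic configuration."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture
def two_species_fasta():
    fa0 = io.StringIO(">g1 first protein\nMKVL\nAAA\n>g2\nMKV*\n")
    fa1 = io.StringIO(">h1\nMKVLAA\n>h2\nMK\n>h3\nMKVLMKVL\n")
    return [("spA", fa0), ("spB", fa1)]
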