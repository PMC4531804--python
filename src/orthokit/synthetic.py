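"""Ground-truthed synthetic inputs for the orthogroup pipeline.

The generator emulates the statistical structure the algorithm exploits,
without simulating actual sequences:

* gene families arise from single ancestral genes and evolve along a random
  ultrametric species tree under a Poisson duplication/loss birth-death
  process, so the true orthogroups (and their paralogue structure) are known;
* protein lengths are log-normal, correlated within a family (members share
  a base length up to ~10 % jitter), as in real orthogroups;
* similarity bit scores follow a power law in the length product
  ``L_qh = L_q * L_h`` with multiplicative decay per unit of gene-tree
  distance and log-normal noise:

      B_qh = 10**b_true * L_qh**a_true * decay**d(q,h) * 10**eps,
      eps ~ Normal(0, noise_sigma)

  mirroring the log-log-linear score/length relationship and the score
  depression between distant species that the normalisation step removes;
* a small fraction of between-family ("background") hits with strongly
  suppressed scores gives the threshold logic false candidates to reject;
* hits under a score floor are dropped, emulating the weak hits a search
  tool's e-value cutoff silently discards.

This is a modelling choice for testability, not a claim about how any
particular search tool's scores arise.  Everything is reproducible
byte-for-byte from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import HitTable, SequenceCatalog
from .mcl import Partition

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_families",
    "simulate_hits",
    "simulate_dataset",
    "write_input_dir",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data generator.

    Rates are events per unit branch length on an ultrametric species tree
    of depth ``tree_depth``; ``decay`` is the per-unit-gene-tree-distance
    score multiplier; ``noise_sigma`` the standard deviation of log10 score
    noise; lengths are amino acids.
    """

    n_species: int = 5
    n_families: int = 200
    tree_depth: float = 1.0
    duplication_rate: float = 0.2
    loss_rate: float = 0.1
    length_log_mean: float = math.log(300.0)  # median protein ~300 aa
    length_log_sigma: float = 0.4
    length_jitter: float = 0.1
    a_true: float = 0.4
    b_true: float = 1.1
    decay: float = 0.7
    decay_jitter: float = 0.1  # per-species-pair relative jitter of decay
    noise_sigma: float = 0.1
    background_fraction: float = 0.001
    background_factor: float = 0.05  # extra suppression of cross-family hits
    score_floor: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must be in (0, 1]")


class _GNode:
    """Gene-tree split node: parent pointer + time from the family root."""

    __slots__ = ("parent", "time")

    def __init__(self, parent: "_GNode | None", time: float) -> None:
        self.parent = parent
        self.time = time


@dataclass
class _SpeciesNode:
    time: float
    children: list["_SpeciesNode"] = field(default_factory=list)
    species_id: int | None = None


def _random_species_tree(
    n_species: int, depth: float, rng: np.random.Generator
) -> _SpeciesNode:
    """Random ultrametric binary tree: leaves at ``depth``, random split
    times strictly increasing from root to leaves."""

    def build(species: list[int], t_min: float) -> _SpeciesNode:
        if len(species) == 1:
            return _SpeciesNode(time=depth, species_id=species[0])
        t_split = t_min + (depth - t_min) * rng.uniform(0.15, 0.6)
        k = int(rng.integers(1, len(species)))
        perm = list(rng.permutation(species))
        node = _SpeciesNode(time=t_split)
        node.children = [build(perm[:k], t_split), build(perm[k:], t_split)]
        return node

    return build(list(range(n_species)), 0.0)


@dataclass
class SyntheticTruth:
    """Simulated gene catalogue with its true orthogroup labels."""

    catalog: SequenceCatalog
    true_partition: Partition
    families: list[list[int]]  # gene ids per surviving ancestral family
    config: SimulationConfig
    _gene_nodes: list[_GNode] = field(default_factory=list, repr=False)

    def gene_tree_distance(self, q: int, h: int) -> float:
        """Patristic distance between two same-family genes on the
        (ultrametric) gene tree: ``2 * (depth - t_mrca)``."""
        ancestors: dict[int, float] = {}
        node: _GNode | None = self._gene_nodes[q]
        while node is not None:
            ancestors[id(node)] = node.time
            node = node.parent
        node = self._gene_nodes[h]
        while node is not None:
            if id(node) in ancestors:
                return 2.0 * (self.config.tree_depth - node.time)
            node = node.parent
        raise ValueError("genes share no ancestor (different families?)")


def _evolve_lineage(
    node: _GNode,
    t: float,
    t_end: float,
    dup: float,
    loss: float,
    rng: np.random.Generator,
) -> list[_GNode]:
    """Birth-death along one branch; returns surviving lineage tips (their
    current split nodes) at the branch end."""
    total = dup + loss
    if total == 0:
        return [node]
    while True:
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            return [node]
        t += dt
        if rng.random() < dup / total:
            split = _GNode(node, t)
            left = _evolve_lineage(split, t, t_end, dup, loss, rng)
            right = _evolve_lineage(split, t, t_end, dup, loss, rng)
            return left + right
        return []  # loss


def simulate_families(config: SimulationConfig) -> SyntheticTruth:
    """Grow gene families along a random species tree.

    Each family starts as a single gene at time 0 and duplicates/dies with
    the configured Poisson rates; at speciation nodes every surviving
    lineage enters both descendant branches.  Protein lengths are drawn
    per family from the configured log-normal and jittered per member.
    """
    rng = np.random.default_rng(config.seed)
    tree = _random_species_tree(config.n_species, config.tree_depth, rng)

    families_raw: list[list[tuple[int, _GNode]]] = []
    for _ in range(config.n_families):
        root = _GNode(None, 0.0)
        leaves: list[tuple[int, _GNode]] = []

        def descend(sp_node: _SpeciesNode, genes: list[_GNode], t: float) -> None:
            survivors: list[_GNode] = []
            for g in genes:
                survivors.extend(
                    _evolve_lineage(g, t, sp_node.time,
                                    config.duplication_rate,
                                    config.loss_rate, rng)
                )
            if sp_node.species_id is not None:
                leaves.extend((sp_node.species_id, g) for g in survivors)
                return
            # speciation: each surviving lineage splits into both children
            split_nodes = [_GNode(g, sp_node.time) for g in survivors]
            for child in sp_node.children:
                descend(child, split_nodes, sp_node.time)

        descend(tree, [root], 0.0)
        families_raw.append(leaves)

    if all(len(f) == 0 for f in families_raw):
        raise SimulationError(
            "all families went extinct; lower loss_rate or raise "
            "duplication_rate"
        )

    # assemble catalogue: dense gene ids in (family, species, index) order
    species_names = [f"species_{s}" for s in range(config.n_species)]
    gene_species: list[int] = []
    gene_names: list[str] = []
    lengths: list[int] = []
    gene_nodes: list[_GNode] = []
    families: list[list[int]] = []
    per_species_count = [0] * config.n_species

    for fam_idx, leaves in enumerate(families_raw):
        if not leaves:
            continue
        base_len = rng.lognormal(config.length_log_mean, config.length_log_sigma)
        fam_genes: list[int] = []
        for sp, gnode in sorted(leaves, key=lambda x: x[0]):
            jitter = rng.uniform(1 - config.length_jitter,
                                 1 + config.length_jitter)
            length = max(30, int(round(base_len * jitter)))
            gid = len(gene_names)
            gene_names.append(f"sp{sp}_g{per_species_count[sp]:05d}")
            per_species_count[sp] += 1
            gene_species.append(sp)
            lengths.append(length)
            gene_nodes.append(gnode)
            fam_genes.append(gid)
        families.append(fam_genes)

    catalog = SequenceCatalog(
        species_names=species_names,
        gene_species=np.asarray(gene_species, dtype=np.int64),
        gene_names=gene_names,
        gene_headers=list(gene_names),
        lengths=np.asarray(lengths, dtype=np.int64),
    )
    partition = Partition.from_clusters(
        [set(f) for f in families], set(range(catalog.n_genes))
    )
    return SyntheticTruth(
        catalog=catalog,
        true_partition=partition,
        families=families,
        config=config,
        _gene_nodes=gene_nodes,
    )


def simulate_hits(
    truth: SyntheticTruth, config: SimulationConfig | None = None
) -> dict[tuple[int, int], HitTable]:
    """Generate per-ordered-species-pair hit tables under the score model.

    Every within-family ordered gene pair gets a hit (both directions, with
    independent noise, so scores are asymmetric as in real searches);
    ``background_fraction`` of random cross-family ordered pairs get
    suppressed background hits.  Hits below ``score_floor`` are dropped.
    """
    config = config or truth.config
    # separate stream from family simulation, still derived from the seed
    rng = np.random.default_rng(config.seed + 1_000_003)
    catalog = truth.catalog
    n_sp = config.n_species

    # per-ordered-species-pair decay constants, jittered around config.decay
    decay_pair: dict[tuple[int, int], float] = {}
    for sa in range(n_sp):
        for sb in range(n_sp):
            jit = rng.uniform(1 - config.decay_jitter, 1 + config.decay_jitter)
            decay_pair[(sa, sb)] = min(1.0, config.decay * jit)

    rows: dict[tuple[int, int], list[tuple[int, int, float]]] = {
        (sa, sb): [] for sa in range(n_sp) for sb in range(n_sp)
    }

    lengths = catalog.lengths
    species = catalog.gene_species

    def emit(q: int, h: int, factor: float) -> None:
        pair = (int(species[q]), int(species[h]))
        l_qh = float(lengths[q]) * float(lengths[h])
        eps = rng.normal(0.0, config.noise_sigma)
        score = (10.0 ** config.b_true) * (l_qh ** config.a_true) * factor \
            * (10.0 ** eps)
        if score >= config.score_floor:
            rows[pair].append((q, h, score))

    for fam in truth.families:
        for q in fam:
            for h in fam:
                if q == h:
                    continue
                d = truth.gene_tree_distance(q, h)
                pair = (int(species[q]), int(species[h]))
                emit(q, h, decay_pair[pair] ** d)

    if config.background_fraction > 0:
        fam_of = {g: i for i, f in enumerate(truth.families) for g in f}
        genes_by_sp = [catalog.genes_of_species(s) for s in range(n_sp)]
        for sa in range(n_sp):
            for sb in range(n_sp):
                n_possible = len(genes_by_sp[sa]) * len(genes_by_sp[sb])
                n_bg = rng.poisson(config.background_fraction * n_possible)
                for _ in range(n_bg):
                    q = int(rng.choice(genes_by_sp[sa]))
                    h = int(rng.choice(genes_by_sp[sb]))
                    if q == h or fam_of.get(q) == fam_of.get(h):
                        continue
                    emit(q, h, config.background_factor)

    tables: dict[tuple[int, int], HitTable] = {}
    for pair, triples in rows.items():
        if not triples:
            continue
        df = pd.DataFrame(triples, columns=["query", "subject", "bitscore"])
        df["query"] = df["query"].astype(np.int64)
        df["subject"] = df["subject"].astype(np.int64)
        # synthetic e-value consistent with the score (only used for filters)
        df["evalue"] = 10.0 ** (-df["bitscore"] / 2.0)
        df = df.sort_values(["query", "subject"], kind="stable").reset_index(
            drop=True
        )
        tables[pair] = HitTable(pair, df)
    return tables


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[SyntheticTruth, dict[tuple[int, int], HitTable]]:
    """Convenience: families + hits under one config."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    truth = simulate_families(config)
    return truth, simulate_hits(truth, config)


def write_input_dir(
    truth: SyntheticTruth,
    tables: dict[tuple[int, int], HitTable],
    out_dir: str | Path,
) -> Path:
    """Materialise a complete fake input directory the CLI can consume:
    per-species FASTA files of 'X'-padded dummy sequences with the correct
    lengths, per-ordered-pair ``Blast<i>_<j>.txt`` tabular files, and the
    truth partition as ``truth_orthogroups.txt``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = truth.catalog
    for sp in range(catalog.n_species):
        with open(out_dir / f"{catalog.species_names[sp]}.fa", "w") as fh:
            for g in catalog.genes_of_species(sp):
                fh.write(f">{catalog.gene_names[g]}\n")
                fh.write("X" * int(catalog.lengths[g]) + "\n")
    for (sa, sb), table in sorted(tables.items()):
        with open(out_dir / f"Blast{sa}_{sb}.txt", "w") as fh:
            for row in table.hits.itertuples(index=False):
                fh.write(
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
    from .outputs import write_plain_text  # local import to avoid cycle

    with open(out_dir / "truth_orthogroups.txt", "w") as fh:
        write_plain_text(truth.true_partition, catalog, fh)
    return out_dir
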