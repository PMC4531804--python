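"""End-to-end orchestration: hits -> normalised scores -> RBNH thresholds ->
orthogroup graph -> Markov clustering -> output files.

`infer_orthogroups` is the in-memory core used by the CLI, the evaluation
harness and the tests; `run_pipeline` adds directory I/O, logging and
resumability on top of it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from . import data_io, mcl, normalization, orthogroup_graph, outputs
from .data_io import HitTable, SequenceCatalog
from .mcl import Partition

__all__ = ["PipelineConfig", "PipelineResult", "infer_orthogroups", "run_pipeline"]

logger = logging.getLogger("orthokit")


@dataclass(frozen=True)
class PipelineConfig:
    evalue_max: float = data_io.DEFAULT_EVALUE_MAX
    top_fraction: float = normalization.TOP_FRACTION
    inflation: float = mcl.DEFAULT_INFLATION
    self_loop: float = mcl.DEFAULT_SELF_LOOP
    prune_threshold: float = mcl.DEFAULT_PRUNE
    max_iter: int = mcl.DEFAULT_MAX_ITER
    include_within_species: bool = True
    mcl_engine: str = "builtin"  # or "external"


@dataclass
class PipelineResult:
    partition: Partition
    graph: orthogroup_graph.OrthogroupGraph
    models: dict[tuple[int, int], normalization.FitModel]
    rbnhs: orthogroup_graph.RBNHSet
    thresholds: dict[int, float]


def infer_orthogroups(
    catalog: SequenceCatalog,
    hit_tables: dict[tuple[int, int], HitTable],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the core inference on already-parsed hit tables.

    Hit tables are deduplicated, normalised per ordered species pair, RBNHs
    and per-gene inclusion thresholds computed, the weighted graph built and
    clustered with the built-in MCL engine.  Genes without any edge end up
    unassigned.  Fully deterministic for fixed inputs.
    """
    config = config or PipelineConfig()
    deduped = {
        pair: data_io.dedupe_hits(table) for pair, table in hit_tables.items()
    }
    for pair, table in sorted(deduped.items()):
        logger.info("pair %s: %d hits after dedup", pair, len(table))
    normalized = normalization.normalize_all_pairs(
        deduped, catalog, fraction=config.top_fraction
    )
    for pair, nt in sorted(normalized.items()):
        logger.info(
            "pair %s: fit a=%.4f b=%.4f on %d hits",
            pair, nt.model.a, nt.model.b, nt.model.n_hits_fit,
        )
    rbnhs = orthogroup_graph.find_rbnhs(normalized)
    thresholds = orthogroup_graph.compute_thresholds(rbnhs, normalized)
    logger.info(
        "%d RBNH pairs, %d genes with thresholds",
        len(rbnhs.pairs()), len(thresholds),
    )
    graph = orthogroup_graph.build_graph(
        normalized,
        thresholds,
        rbnhs,
        n_genes=catalog.n_genes,
        gene_species=catalog.gene_species,
        include_within_species=config.include_within_species,
    )
    logger.info("orthogroup graph: %d edges", graph.n_edges)
    partition = mcl.cluster_graph(
        graph,
        inflation=config.inflation,
        self_loop=config.self_loop,
        prune_threshold=config.prune_threshold,
        max_iter=config.max_iter,
    )
    logger.info(
        "%d orthogroups, %d genes assigned, %d unassigned",
        len(partition.orthogroups), partition.n_assigned,
        len(partition.unassigned),
    )
    return PipelineResult(
        partition=partition, graph=graph, models={
            pair: nt.model for pair, nt in normalized.items()
        },
        rbnhs=rbnhs, thresholds=thresholds,
    )


def load_input_dir(
    input_dir: str | Path, evalue_max: float = data_io.DEFAULT_EVALUE_MAX
) -> tuple[SequenceCatalog, dict[tuple[int, int], HitTable]]:
    """Read an input directory: one FASTA per species (``*.fa``/``*.fasta``/
    ``*.faa``, sorted by name) plus per-ordered-pair ``Blast<i>_<j>.txt``."""
    input_dir = Path(input_dir)
    fastas = sorted(
        p for ext in ("*.fa", "*.fasta", "*.faa") for p in input_dir.glob(ext)
    )
    if len(fastas) < 2:
        raise data_io.DataError(
            f"need at least 2 FASTA files in {input_dir}, found {len(fastas)}"
        )
    catalog = data_io.read_fasta_lengths([(p.stem, p) for p in fastas])
    n = catalog.n_species
    missing = [
        (i, j) for i in range(n) for j in range(n)
        if not (input_dir / f"Blast{i}_{j}.txt").exists()
    ]
    if missing:
        raise data_io.DataError(
            "missing per-pair similarity files: "
            + ", ".join(f"Blast{i}_{j}.txt" for i, j in missing)
        )
    tables = {}
    for i in range(n):
        for j in range(n):
            tables[(i, j)] = data_io.parse_blast_tabular(
                input_dir / f"Blast{i}_{j}.txt", catalog, (i, j),
                evalue_max=evalue_max,
            )
    return catalog, tables


def _write_fit_cache(models, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_species\tsubject_species\ta\tb\tn_hits_fit\n")
        for (sa, sb), m in sorted(models.items()):
            fh.write(f"{sa}\t{sb}\t{m.a!r}\t{m.b!r}\t{m.n_hits_fit}\n")


def _read_fit_cache(path: Path) -> dict[tuple[int, int], normalization.FitModel]:
    models = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            sa, sb, a, b, n = line.split("\t")
            models[(int(sa), int(sb))] = normalization.FitModel(
                (int(sa), int(sb)), float(a), float(b), int(n)
            )
    return models


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Directory-level pipeline run with logging and resumability.

    Writes orthogroups (plain text + OrthoXML), the unassigned-gene list,
    the graph in MCL abc format, id maps, per-pair fit coefficients and a
    log under ``output_dir``.  If cached fit coefficients from a previous
    run are present and the clustering outputs were deleted, normalisation
    reuses the cached models, reproducing identical final files.
    """
    config = config or PipelineConfig()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(output_dir / "orthokit.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("parameters: %s", dataclasses.asdict(config))
        catalog, tables = load_input_dir(input_dir, evalue_max=config.evalue_max)
        logger.info(
            "%d species, %d genes", catalog.n_species, catalog.n_genes
        )
        data_io.write_id_maps(catalog, output_dir)

        fit_cache = output_dir / "fit_coefficients.tsv"
        deduped = {p: data_io.dedupe_hits(t) for p, t in tables.items()}
        if fit_cache.exists():
            logger.info("reusing cached fit coefficients from %s", fit_cache)
            models = _read_fit_cache(fit_cache)
            normalized = {
                pair: normalization.normalize_scores(
                    deduped[pair], models[pair], catalog
                )
                for pair in models
                if pair in deduped and len(deduped[pair]) > 0
            }
        else:
            normalized = normalization.normalize_all_pairs(
                deduped, catalog, fraction=config.top_fraction
            )
            _write_fit_cache(
                {p: nt.model for p, nt in normalized.items()}, fit_cache
            )
        for pair, nt in sorted(normalized.items()):
            logger.info("pair %s: a=%.4f b=%.4f (n=%d)",
                        pair, nt.model.a, nt.model.b, nt.model.n_hits_fit)

        rbnhs = orthogroup_graph.find_rbnhs(normalized)
        thresholds = orthogroup_graph.compute_thresholds(rbnhs, normalized)
        logger.info("%d RBNH pairs, %d thresholded genes",
                    len(rbnhs.pairs()), len(thresholds))
        graph = orthogroup_graph.build_graph(
            normalized, thresholds, rbnhs,
            n_genes=catalog.n_genes,
            gene_species=catalog.gene_species,
            include_within_species=config.include_within_species,
        )
        logger.info("graph: %d edges", graph.n_edges)
        abc_path = output_dir / "orthogroup_graph.abc"
        with open(abc_path, "w") as fh:
            orthogroup_graph.write_graph(graph, fh)

        if config.mcl_engine == "external":
            partition = mcl.run_external_mcl(
                abc_path, catalog.n_genes, inflation=config.inflation
            )
        else:
            partition = mcl.cluster_graph(
                graph, inflation=config.inflation,
                self_loop=config.self_loop,
                prune_threshold=config.prune_threshold,
                max_iter=config.max_iter,
            )
        partition.validate()
        logger.info("%d orthogroups, %d unassigned",
                    len(partition.orthogroups), len(partition.unassigned))

        with open(output_dir / "orthogroups.txt", "w") as fh:
            outputs.write_plain_text(partition, catalog, fh)
        with open(output_dir / "orthogroups_unassigned.txt", "w") as fh:
            outputs.write_unassigned(partition, catalog, fh)
        with open(output_dir / "orthogroups.orthoxml", "wb") as fh:
            outputs.write_orthoxml(partition, catalog, fh)
        return output_dir
    finally:
        logger.removeHandler(handler)
        handler.close()
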