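"""End-to-end orchestration of the annotation workflow.

load -> log-normalize -> restrict to markers -> cluster with several
backends -> drop the least diverse -> unanimous consensus graph -> Louvain
representative clusters -> per-cluster boosted-stump annotation -> UMAP +
kNN propagation -> assembled per-cell labels with provenance. Every
intermediate artifact can be written to an output directory for audit.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    UNASSIGNED_LABEL,
    BoosterParams,
    CellTypeScoreTable,
    annotate_representative_clusters,
)
from .consensus import (
    AriMatrix,
    Partition,
    RepresentativeClusters,
    consensus_adjacency,
    representative_clusters,
    run_clusterings,
    select_diverse,
)
from .io_preprocess import (
    UNKNOWN_LABEL,
    ExpressionMatrix,
    MarkerDB,
    RawCounts,
    lognormalize,
    restrict_to_markers,
)
from .propagation import Embedding2D, embed_2d, knn_assign

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one annotation run; one global seed fans out per stage."""

    backends: list[str] | None = None
    partition_files: list[str] = field(default_factory=list)
    threshold: int = 10
    resolution: float = 1.0
    k: int = 1
    booster: BoosterParams = field(default_factory=BoosterParams)
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    normalization: str = "size-factor-log"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global one."""
        return (zlib.crc32(f"{stage}:{self.seed}".encode()) ^ self.seed) % (2**31)


@dataclass
class AnnotationResult:
    labels: dict[str, str]
    provenance: dict[str, str]  # representative | propagated | unknown
    cluster_of: dict[str, int]  # cell -> representative cluster id
    score_tables: list[CellTypeScoreTable]
    ari: AriMatrix | None
    reps: RepresentativeClusters | None
    embedding: Embedding2D | None
    metrics: dict[str, float] | None = None
    config: RunConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c,
                "label": self.labels[c],
                "provenance": self.provenance[c],
                "cluster_id": self.cluster_of.get(c, -1),
            }
            for c in self.labels
        ]
        return pd.DataFrame(rows).set_index("cell_id")


def run(
    raw: RawCounts,
    db: MarkerDB,
    config: RunConfig | None = None,
    truth: dict[str, str] | None = None,
    out_dir: str | Path | None = None,
) -> AnnotationResult:
    """Execute the full annotation workflow on in-memory inputs."""
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: normalization (%s)", config.normalization)
    normalized = lognormalize(raw, mode=config.normalization)
    dropped_cells = set(raw.cell_ids) - set(normalized.cell_ids)

    logger.info("stage: marker restriction")
    expr, unknown = restrict_to_markers(normalized, db)
    unknown |= dropped_cells  # zero-total cells are equally unannotatable
    db = db.restricted_to(set(expr.gene_ids))

    logger.info("stage: clustering")
    partitions = _gather_partitions(expr, config)
    if out is not None:
        for p in partitions:
            p.to_tsv(out / f"partition_{p.method_name}.tsv")

    retained, R = select_diverse(partitions)
    if out is not None:
        pd.DataFrame(R.values, index=R.method_names, columns=R.method_names).to_csv(
            out / "ari_matrix.tsv", sep="\t"
        )

    logger.info("stage: consensus graph")
    graph = consensus_adjacency(retained)
    if out is not None:
        with open(out / "consensus_edges.tsv", "w") as fh:
            fh.write("cell_u\tcell_v\n")
            for u, v in sorted(graph.edges):
                fh.write(f"{u}\t{v}\n")

    logger.info("stage: representative clusters")
    reps = representative_clusters(
        graph,
        threshold=config.threshold,
        resolution=config.resolution,
        seed=config.stage_seed("louvain"),
    )

    logger.info("stage: cluster annotation")
    tables = annotate_representative_clusters(
        expr, reps.clusters, db,
        params=config.booster, seed=config.stage_seed("xgboost"),
    )
    if out is not None:
        _write_score_tables(tables, out / "score_tables.tsv")

    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    for cid, (cluster, table) in enumerate(zip(reps.clusters, tables)):
        for c in cluster:
            labels[c] = table.winner
            provenance[c] = "representative"
            cluster_of[c] = cid

    logger.info("stage: embedding + propagation")
    embedding = embed_2d(
        expr,
        n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist,
        seed=config.stage_seed("umap"),
    )
    if out is not None:
        with open(out / "embedding.tsv", "w") as fh:
            fh.write("cell_id\tx\ty\n")
            for c, (x, y) in embedding.coords.items():
                fh.write(f"{c}\t{x:.6f}\t{y:.6f}\n")

    propagated = knn_assign(embedding, labels, reps.leftover, k=config.k)
    for c, lab in propagated.items():
        labels[c] = lab
        provenance[c] = "propagated"
    for c in unknown:
        labels[c] = UNKNOWN_LABEL
        provenance[c] = "unknown"

    result = AnnotationResult(
        labels=labels, provenance=provenance, cluster_of=cluster_of,
        score_tables=tables, ari=R, reps=reps, embedding=embedding,
        config=config,
    )

    if truth is not None:
        from .metrics import confusion, evaluate

        common = {c: truth[c] for c in labels if c in truth}
        cm = confusion(common, {c: labels[c] for c in common})
        result.metrics = evaluate(cm)
        logger.info("metrics: %s", result.metrics)

    if out is not None:
        result.to_frame().to_csv(out / "labels.tsv", sep="\t")
        meta = {
            "version": __version__,
            "seed": config.seed,
            "threshold": config.threshold,
            "k": config.k,
            "backends": config.backends or "default",
            "normalization": config.normalization,
            "n_cells": len(labels),
            "n_representative_clusters": len(reps.clusters),
            "metrics": result.metrics,
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return result


def _gather_partitions(expr: ExpressionMatrix, config: RunConfig) -> list[Partition]:
    partitions: list[Partition] = []
    for path in config.partition_files:
        p = Partition.from_tsv(path)
        if p.cells != frozenset(expr.cell_ids):
            missing = frozenset(expr.cell_ids) - p.cells
            raise ValueError(
                f"partition file {path} does not cover the retained cells "
                f"({len(missing)} missing)"
            )
        partitions.append(p)
    if config.backends is None:
        from .backends import DEFAULT_BACKENDS

        n_needed = max(0, len(DEFAULT_BACKENDS) - len(partitions))
        names = DEFAULT_BACKENDS[:n_needed]
    else:
        names = list(config.backends)
    if names:
        partitions += run_clusterings(
            expr, names, seed=config.stage_seed("clustering"),
            min_backends=1 if partitions else 3,
        )
    if len(partitions) < 3:
        raise ValueError("need at least 3 partitions in total")
    return partitions


def _write_score_tables(tables: list[CellTypeScoreTable], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcell_type\tscore\twinner_flag\n")
        for t in tables:
            for cell_type, score in sorted(t.scores.items()):
                flag = int(cell_type == t.winner)
                fh.write(f"{t.cluster_id}\t{cell_type}\t{score:.6g}\t{flag}\n")
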