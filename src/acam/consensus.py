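"""Consensus clustering: diversity selection, unanimous co-clustering, Louvain.

Several clustering backends each partition the cells. The method keeps the
most mutually diverse subset by dropping the partition whose row of the
pairwise-ARI matrix has minimum variance, intersects the survivors'
co-clustering relations into a consensus graph (an edge requires the pair
to share a cluster in EVERY retained partition), and takes Louvain
communities above a size threshold as the representative clusters —
high-confidence cell groups every method agrees on.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .backends import BACKEND_REGISTRY, DEFAULT_BACKENDS
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """One clustering's assignment of every cell to a cluster label."""

    assignment: dict[str, int | str]
    method_name: str

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def cells(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def labels_for(self, order: list[str]) -> np.ndarray:
        return np.asarray([self.assignment[c] for c in order])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cell_id\tcluster\n")
            for c in sorted(self.assignment):
                fh.write(f"{c}\t{self.assignment[c]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, method_name: str | None = None) -> "Partition":
        assignment: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("cell_id"):
                raise ValueError("partition file must start with a cell_id header")
            for line in fh:
                if line.strip():
                    cell, label = line.rstrip("\n").split("\t")
                    assignment[cell] = label
        return cls(assignment=assignment, method_name=method_name or str(path))


@dataclass
class AriMatrix:
    values: np.ndarray
    method_names: list[str]


@dataclass
class ConsensusGraph:
    """Undirected graph whose edges are unanimously co-clustered cell pairs.

    Because unanimity means "identical label combination across all
    retained partitions", the graph is a disjoint union of cliques; the
    clique membership is kept alongside the edge set.
    """

    cells: list[str]
    edges: set[tuple[str, str]]  # lexicographically ordered pairs
    groups: list[set[str]]       # the cliques (cells sharing a label tuple)


@dataclass
class RepresentativeClusters:
    clusters: list[set[str]]
    threshold: int
    leftover: set[str]


def run_clusterings(
    expr: ExpressionMatrix,
    backends: list[str] | None = None,
    seed: int = 0,
    min_backends: int = 3,
) -> list[Partition]:
    """Run each backend independently on the marker expression matrix.

    Backends see cells x genes; each gets its own sub-seed derived from
    the global seed and its position so runs are reproducible and backends
    are decoupled. At least three backends are required unless externally
    produced partitions make up the difference (``min_backends``).
    """
    names = list(backends) if backends is not None else list(DEFAULT_BACKENDS)
    if len(names) < min_backends:
        raise ValueError("need at least 3 backends (at least 2 must survive removal)")
    x = expr.values.T  # cells x genes
    partitions = []
    for i, name in enumerate(names):
        if name not in BACKEND_REGISTRY:
            raise ValueError(f"unknown backend {name!r}; available: {sorted(BACKEND_REGISTRY)}")
        labels = BACKEND_REGISTRY[name](x, seed=seed + 1000 * i)
        if len(labels) != expr.n_cells:
            raise ValueError(f"backend {name!r} returned labels for a different cell set")
        part = Partition(
            assignment={c: int(l) for c, l in zip(expr.cell_ids, labels)},
            method_name=name,
        )
        logger.info("backend %s found k=%d clusters", name, part.k)
        partitions.append(part)
    return partitions


def ari(p: Partition, q: Partition) -> float:
    """Adjusted Rand index (permutation-model pair counting) of two partitions."""
    if p.cells != q.cells:
        raise ValueError("partitions cover different cell sets")
    order = sorted(p.cells)
    a = [str(v) for v in p.labels_for(order)]
    b = [str(v) for v in q.labels_for(order)]
    return float(adjusted_rand_score(a, b))


def ari_matrix(partitions: list[Partition]) -> AriMatrix:
    m = len(partitions)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = ari(partitions[i], partitions[j])
    return AriMatrix(values=values, method_names=[p.method_name for p in partitions])


def select_diverse(
    partitions: list[Partition],
    include_diagonal: bool = False,
) -> tuple[list[Partition], AriMatrix]:
    """Drop the single partition that disagrees least with its peers.

    The variance of each method's ARIs against the other methods (row of
    the ARI matrix, diagonal excluded by default) measures how unevenly it
    agrees across the ensemble; the minimum-variance method contributes
    least diversity and is removed. Ties go to the earliest backend.
    """
    if len(partitions) < 3:
        raise ValueError("need at least 3 partitions to select from")
    R = ari_matrix(partitions)
    m = len(partitions)
    variances = np.empty(m)
    for i in range(m):
        row = R.values[i] if include_diagonal else np.delete(R.values[i], i)
        variances[i] = np.var(row)
    drop = int(np.argmin(variances))  # argmin takes the earliest on ties
    logger.info(
        "removing backend %r (row variance %.4g; variances %s)",
        partitions[drop].method_name, variances[drop],
        np.array2string(variances, precision=4),
    )
    return [p for i, p in enumerate(partitions) if i != drop], R


def consensus_adjacency(partitions: list[Partition]) -> ConsensusGraph:
    """Intersect co-clustering relations: an edge needs unanimous agreement.

    Two cells are joined iff they share a cluster in every partition,
    i.e. iff their tuples of labels across partitions are identical; the
    summed binary co-membership matrix equals the number of partitions
    exactly on these pairs.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions for a consensus")
    cells0 = partitions[0].cells
    if any(p.cells != cells0 for p in partitions):
        raise ValueError("partitions cover different cell sets")
    order = sorted(cells0)
    signatures: dict[tuple, list[str]] = {}
    for c in order:
        sig = tuple(p.assignment[c] for p in partitions)
        signatures.setdefault(sig, []).append(c)
    edges: set[tuple[str, str]] = set()
    groups: list[set[str]] = []
    for members in signatures.values():
        groups.append(set(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add((members[i], members[j]))
    return ConsensusGraph(cells=order, edges=edges, groups=groups)


def representative_clusters(
    g: ConsensusGraph,
    threshold: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> RepresentativeClusters:
    """Louvain communities of the consensus graph, filtered by size.

    Communities with strictly more than ``threshold`` cells become the
    representative clusters; everything else joins the leftover set, to be
    labeled later by propagation.
    """
    import igraph

    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    index = {c: i for i, c in enumerate(g.cells)}
    graph = igraph.Graph(
        n=len(g.cells), edges=[(index[u], index[v]) for u, v in g.edges]
    )
    igraph.set_random_number_generator(random.Random(seed))
    communities = graph.community_multilevel(resolution=resolution)
    clusters, leftover = [], set()
    for comm in communities:
        members = {g.cells[i] for i in comm}
        if len(members) > threshold:
            clusters.append(members)
        else:
            leftover |= members
    if not clusters:
        raise ValueError(
            f"no consensus community exceeds size threshold {threshold}; "
            "lower the threshold"
        )
    clusters.sort(key=lambda s: (-len(s), min(s)))
    logger.info(
        "%d representative cluster(s) (sizes %s), %d leftover cell(s)",
        len(clusters), [len(c) for c in clusters], len(leftover),
    )
    return RepresentativeClusters(clusters=clusters, threshold=threshold, leftover=leftover)
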