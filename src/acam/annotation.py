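"""Cluster annotation by boosted-stump feature importance over marker genes.

Each representative cluster is contrasted one-vs-rest against all other
retained cells. The target group is oversampled to the adversarial group's
size, genes not up-regulated in the target are removed, and a gradient
boosted ensemble of depth-1 trees (stumps) with a hinge objective is fit
to the binary problem. A stump ensemble suits marker genes: one clean
threshold on a marker separates the type. Summing per-gene total-gain
importances over each cell type's marker set gives the type score, and the
cluster takes the argmax type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb

from .io_preprocess import ExpressionMatrix, MarkerDB

logger = logging.getLogger(__name__)

#: label for a representative cluster with no marker signal
UNASSIGNED_LABEL = "unassigned"


@dataclass
class BoosterParams:
    """Gradient-boosting knobs; depth 1 and hinge loss define the method,
    the rest follow the booster's defaults."""

    n_rounds: int = 100
    learning_rate: float = 0.3
    max_depth: int = 1
    objective: str = "binary:hinge"
    importance_type: str = "total_gain"


@dataclass
class ImportanceVector:
    cluster_id: int
    importances: dict[str, float]  # gene -> w_m over admitted genes
    genes_removed_by_prefilter: set[str] = field(default_factory=set)

    def get(self, gene: str) -> float:
        return self.importances.get(gene, 0.0)


@dataclass
class CellTypeScoreTable:
    cluster_id: int
    scores: dict[str, float]
    winner: str
    margin: float


def oversample(cluster: set[str], target_size: int, seed: int) -> list[str]:
    """Pad a cell set to ``target_size`` by uniform draws with replacement.

    Every original cell appears at least once; the extra draws balance the
    one-vs-rest fit when the cluster is much smaller than its complement.
    """
    cells = sorted(cluster)
    if not cells:
        raise ValueError("cannot oversample an empty cluster")
    if target_size < len(cells):
        raise ValueError("target_size must be >= cluster size")
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(cells), size=target_size - len(cells), replace=True)
    return cells + [cells[i] for i in extra]


def prefilter_genes(expr: ExpressionMatrix, cluster: set[str]) -> set[str]:
    """Keep genes whose mean expression is strictly higher inside the cluster.

    Marker genes of the cluster's type should be up-regulated in it; genes
    not higher in the target group can only confuse the booster. Means are
    taken over the original cluster (not the oversampled multiset, whose
    expectation is the same) against all remaining cells.
    """
    in_idx = expr.cell_index(cluster)
    if len(in_idx) == 0 or len(in_idx) == expr.n_cells:
        raise ValueError("cluster must be a proper nonempty subset of the cells")
    mask = np.zeros(expr.n_cells, dtype=bool)
    mask[in_idx] = True
    mean_in = expr.values[:, mask].mean(axis=1)
    mean_out = expr.values[:, ~mask].mean(axis=1)
    return {g for g, a, b in zip(expr.gene_ids, mean_in, mean_out) if a > b}


def feature_importance(
    expr: ExpressionMatrix,
    target: list[str],
    adversarial: set[str],
    genes: set[str],
    params: BoosterParams | None = None,
    seed: int = 0,
    cluster_id: int = 0,
) -> ImportanceVector:
    """Fit stumps on target-vs-adversarial cells and read per-gene gain.

    ``target`` is a multiset (oversampled cells may repeat). Genes the
    ensemble never splits on get importance 0.
    """
    params = params or BoosterParams()
    gene_order = [g for g in expr.gene_ids if g in genes]
    if not gene_order:
        raise ValueError("no genes admitted to the model")
    row_idx = [expr.gene_ids.index(g) for g in gene_order]
    col_of = {c: i for i, c in enumerate(expr.cell_ids)}
    adv = sorted(adversarial)
    cols = [col_of[c] for c in target] + [col_of[c] for c in adv]
    x = expr.values[np.ix_(row_idx, cols)].T  # samples x genes
    y = np.r_[np.ones(len(target)), np.zeros(len(adv))]

    dtrain = xgb.DMatrix(x, label=y, feature_names=gene_order)
    booster = xgb.train(
        {
            "objective": params.objective,
            "max_depth": params.max_depth,
            "eta": params.learning_rate,
            "seed": seed,
            "nthread": 1,
            "verbosity": 0,
        },
        dtrain,
        num_boost_round=params.n_rounds,
    )
    gains = booster.get_score(importance_type=params.importance_type)
    importances = {g: float(gains.get(g, 0.0)) for g in gene_order}
    return ImportanceVector(
        cluster_id=cluster_id,
        importances=importances,
        genes_removed_by_prefilter=set(expr.gene_ids) - genes,
    )


def score_cell_types(w: ImportanceVector, db: MarkerDB) -> CellTypeScoreTable:
    """Score_t = sum of importances over type t's markers; winner = argmax.

    A gene in several marker sets contributes to each. All-zero scores
    mean no marker carried any signal and the cluster is "unassigned".
    Ties break to the lexicographically smallest type name.
    """
    scores = {
        t: float(sum(w.get(g) for g in db.gene_sets[t])) for t in db.cell_types
    }
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] <= 0:
        logger.warning("cluster %d: every cell-type score is 0 -> %s",
                       w.cluster_id, UNASSIGNED_LABEL)
        return CellTypeScoreTable(
            cluster_id=w.cluster_id, scores=scores,
            winner=UNASSIGNED_LABEL, margin=0.0,
        )
    margin = ranked[0][1] - (ranked[1][1] if len(ranked) > 1 else 0.0)
    if len(ranked) > 1 and margin == 0.0:
        logger.warning("cluster %d: score tie between %r and %r; taking %r",
                       w.cluster_id, ranked[0][0], ranked[1][0], ranked[0][0])
    return CellTypeScoreTable(
        cluster_id=w.cluster_id, scores=scores, winner=ranked[0][0], margin=margin
    )


def annotate_representative_clusters(
    expr: ExpressionMatrix,
    clusters: list[set[str]],
    db: MarkerDB,
    params: BoosterParams | None = None,
    seed: int = 0,
) -> list[CellTypeScoreTable]:
    """One-vs-rest annotate every representative cluster independently.

    Clusters may receive the same type; there is no exclusivity. A cluster
    whose prefilter removes every gene, or whose fit yields no nonzero
    importance, is "unassigned".
    """
    if not clusters:
        raise ValueError("no representative clusters to annotate")
    tables = []
    all_cells = set(expr.cell_ids)
    for cid, cluster in enumerate(clusters):
        adversarial = all_cells - cluster
        genes = prefilter_genes(expr, cluster)
        if not genes:
            logger.warning(
                "cluster %d: no gene is up-regulated in the cluster -> %s",
                cid, UNASSIGNED_LABEL,
            )
            tables.append(CellTypeScoreTable(
                cluster_id=cid, scores={t: 0.0 for t in db.cell_types},
                winner=UNASSIGNED_LABEL, margin=0.0,
            ))
            continue
        target = oversample(
            cluster, max(len(cluster), len(adversarial)), seed=seed + cid
        )
        w = feature_importance(
            expr, target, adversarial, genes,
            params=params, seed=seed + cid, cluster_id=cid,
        )
        tables.append(score_cell_types(w, db))
    return tables
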