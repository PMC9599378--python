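"""Label propagation: UMAP to 2-D, then nearest-labeled-neighbor transfer.

Cells outside every representative cluster inherit a label from the
annotated cells. The whole retained matrix is first projected to two
dimensions with UMAP (which doubles as the visualization coordinate
system), and each unlabeled cell takes the majority label of its k nearest
labeled cells there, with k = 1 by default.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding2D:
    coords: dict[str, tuple[float, float]]
    n_neighbors: int
    min_dist: float
    seed: int

    def array_for(self, cells: list[str]) -> np.ndarray:
        return np.asarray([self.coords[c] for c in cells], dtype=float)


def embed_2d(
    expr: ExpressionMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> Embedding2D:
    """UMAP projection of all retained cells from the marker matrix.

    Deterministic for a fixed seed. With fewer cells than the neighbor
    count, the neighbor count is clamped with a warning.
    """
    import umap

    n = expr.n_cells
    if n < 3:
        raise ValueError("need at least 3 cells to embed")
    k = n_neighbors
    if k >= n:
        k = n - 1
        logger.warning("n_neighbors clamped to %d for %d cells", k, n)
    emb = umap.UMAP(
        n_components=2, n_neighbors=k, min_dist=min_dist, random_state=seed
    ).fit_transform(expr.values.T)
    coords = {c: (float(x), float(y)) for c, (x, y) in zip(expr.cell_ids, emb)}
    return Embedding2D(coords=coords, n_neighbors=k, min_dist=min_dist, seed=seed)


def knn_assign(
    emb: Embedding2D,
    labeled: dict[str, str],
    unlabeled: set[str],
    k: int = 1,
) -> dict[str, str]:
    """Majority vote among the k nearest labeled cells in the embedding.

    Euclidean distance in 2-D; distance ties break to the labeled cell of
    smallest index (position in the embedding's cell order), vote ties to
    the lexicographically smallest label. Labeled cells are never
    relabeled.
    """
    if not labeled:
        raise ValueError("no labeled cells to propagate from")
    if set(labeled) & unlabeled:
        raise ValueError("labeled and unlabeled cell sets overlap")
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_cells = [c for c in emb.coords if c in labeled]
    ref = emb.array_for(ref_cells)
    k = min(k, len(ref_cells))
    out: dict[str, str] = {}
    for cell in sorted(unlabeled):
        d = np.linalg.norm(ref - np.asarray(emb.coords[cell]), axis=1)
        # stable argsort keeps embedding-order (lowest index) on distance ties
        nearest = np.argsort(d, kind="stable")[:k]
        votes = Counter(labeled[ref_cells[i]] for i in nearest)
        top = max(votes.values())
        out[cell] = min(lab for lab, v in votes.items() if v == top)
    return out
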