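"""Synthetic scRNA-seq counts with planted cell types and marker genes.

The generator draws negative-binomial counts with per-cell lognormal
library-size factors and independent dropout, and boosts each type's
marker genes by a fold change in that type's cells only — the minimal
model with the overdispersion and sparsity that make real droplet data
hard, and exactly the structure the annotation method assumes (markers
highly expressed in their own type, weakly elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import MarkerDB, RawCounts


@dataclass
class SyntheticSpec:
    """Parameters of the planted-marker generative model.

    ``dispersion`` is the negative-binomial size parameter r
    (var = mu + mu^2 / r); large r approaches Poisson. ``dropout_rate`` is
    the probability that any single count is zeroed after sampling.
    ``marker_overlap_frac`` shares that fraction of each type's markers
    with the next type, mimicking real marker databases where types
    overlap.
    """

    n_cells_per_type: list[int] = field(default_factory=lambda: [150, 150, 150])
    markers_per_type: int = 10
    n_background_genes: int = 200
    marker_fold_change: float = 10.0
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    marker_overlap_frac: float = 0.0
    library_size_cv: float = 0.1
    species: str = "Synthetic"
    tissue: str = "Simulated"
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_cells_per_type) < 2:
            raise ValueError("need at least 2 cell types")
        if any(n < 1 for n in self.n_cells_per_type):
            raise ValueError("each type needs at least 1 cell")
        if self.markers_per_type < 1:
            raise ValueError("markers_per_type must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0 <= self.marker_overlap_frac < 1):
            raise ValueError("marker_overlap_frac must be in [0, 1)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be >= 0")

    @property
    def n_types(self) -> int:
        return len(self.n_cells_per_type)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_r: float) -> np.ndarray:
    p = size_r / (size_r + mean)
    return rng.negative_binomial(size_r, p)


def generate(spec: SyntheticSpec) -> tuple[RawCounts, dict[str, str], MarkerDB]:
    """Draw one dataset: counts, per-cell true labels, matching marker table.

    Marker gene ``Mk_t_j`` of type t has mean ``baseline * fold`` in type-t
    cells and ``baseline`` elsewhere; background genes ``Bg_j`` sit at the
    baseline everywhere. Deterministic for a fixed spec (including seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    types = [f"type{i + 1}" for i in range(spec.n_types)]

    marker_sets: dict[str, list[str]] = {
        t: [f"Mk_{t}_{j + 1}" for j in range(spec.markers_per_type)] for t in types
    }
    gene_ids = [g for t in types for g in marker_sets[t]]
    gene_ids += [f"Bg_{j + 1}" for j in range(spec.n_background_genes)]

    # optional sharing: each type also claims the head of the next type's list
    gene_sets: dict[str, set[str]] = {t: set(marker_sets[t]) for t in types}
    n_shared = int(round(spec.marker_overlap_frac * spec.markers_per_type))
    if n_shared:
        for i, t in enumerate(types):
            nxt = types[(i + 1) % spec.n_types]
            gene_sets[t] |= set(marker_sets[nxt][:n_shared])

    labels_per_cell = [t for t, n in zip(types, spec.n_cells_per_type) for _ in range(n)]
    n_cells = len(labels_per_cell)
    cell_ids = [f"cell{i + 1}" for i in range(n_cells)]

    mean = np.full((len(gene_ids), n_cells), spec.baseline_mean)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    col = 0
    for t, n in zip(types, spec.n_cells_per_type):
        rows = [gene_index[g] for g in marker_sets[t]]
        mean[np.ix_(rows, range(col, col + n))] *= spec.marker_fold_change
        col += n

    if spec.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(spec.library_size_cv**2))
        factors = rng.lognormal(-(sigma**2) / 2, sigma, size=n_cells)
        mean = mean * factors[None, :]

    counts = _nb_sample(rng, mean, spec.dispersion).astype(float)
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0

    raw = RawCounts(values=counts, gene_ids=gene_ids, cell_ids=cell_ids)
    truth = dict(zip(cell_ids, labels_per_cell))
    db = MarkerDB(
        cell_types=types, gene_sets=gene_sets,
        species=spec.species, tissue=spec.tissue,
    )
    return raw, truth, db


def oracle_classify(raw: RawCounts, db: MarkerDB) -> dict[str, str]:
    """Assign each cell the type whose markers have the largest mean in it.

    A deliberately naive classifier used to certify that a generated
    dataset is informative at all before the full pipeline is judged on it.
    """
    gene_index = {g: i for i, g in enumerate(raw.gene_ids)}
    means = np.empty((len(db.cell_types), raw.n_cells))
    for ti, t in enumerate(db.cell_types):
        rows = [gene_index[g] for g in db.gene_sets[t] if g in gene_index]
        means[ti] = raw.values[rows, :].mean(axis=0)
    winners = np.argmax(means, axis=0)
    return {c: db.cell_types[w] for c, w in zip(raw.cell_ids, winners)}


def write_dataset(
    raw: RawCounts, truth: dict[str, str], db: MarkerDB, out_dir
) -> None:
    """Write counts.csv, markers.tsv and truth.tsv in the formats the
    readers accept, so synthetic fixtures exercise the I/O path too."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(raw.values, index=raw.gene_ids, columns=raw.cell_ids).to_csv(
        out / "counts.csv"
    )
    rows = [
        {
            "speciesType": db.species,
            "tissueType": db.tissue,
            "markerResource": "Single-cell sequencing",
            "shortname": t,
            "cellMarker": g,
        }
        for t in db.cell_types
        for g in sorted(db.gene_sets[t])
    ]
    pd.DataFrame(rows).to_csv(out / "markers.tsv", sep="\t", index=False)
    pd.Series(truth, name="label").rename_axis("cell_id").to_csv(
        out / "truth.tsv", sep="\t"
    )
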