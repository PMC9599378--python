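import numpy as np
import pytest

from acam import MarkerDB, RawCounts, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated 3-type dataset, 60 cells/type, strong markers."""
    spec = SyntheticSpec(
        n_cells_per_type=[60, 60, 60],
        markers_per_type=8,
        n_background_genes=80,
        marker_fold_change=10.0,
        dropout_rate=0.1,
        seed=7,
    )
    return generate(spec)


@pytest.fixture
def tiny_db():
    return MarkerDB(
        cell_types=["A", "B"],
        gene_sets={"A": {"g1", "g2"}, "B": {"g3"}},
        species="Mouse",
        tissue="Kidney",
    )


@pytest.fixture
def tiny_counts():
    # 4 genes x 4 cells; c4 is zero on the markers g1-g3
    values = np.array(
        [
            [5.0, 0.0, 1.0, 0.0],  # g1
            [2.0, 3.0, 0.0, 0.0],  # g2
            [0.0, 4.0, 2.0, 0.0],  # g3
            [1.0, 1.0, 1.0, 6.0],  # g4 (not a marker)
        ]
    )
    return RawCounts(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4"],
        cell_ids=["c1", "c2", "c3", "c4"],
    )


def random_partition(rng: np.random.Generator, cells: list[str], k_max: int = 5):
    from acam import Partition

    k = int(rng.integers(1, k_max + 1))
    labels = rng.integers(0, k, size=len(cells))
    return Partition(
        assignment={c: int(l) for c, l in zip(cells, labels)},
        method_name=f"rand{rng.integers(1 << 30)}",
    )
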