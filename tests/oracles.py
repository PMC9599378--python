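"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and libraries) the package uses:
pair counting by explicit enumeration, metric formulas transcribed with
plain Python loops, exhaustive nearest-neighbor search.
"""

from itertools import combinations
from math import comb, sqrt


def brute_force_ari(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index by enumerating all cell pairs."""
    n = len(labels_a)
    assert len(labels_b) == n
    n11 = same_a = same_b = 0
    for i, j in combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        same_a += sa
        same_b += sb
        n11 += sa and sb
    total = comb(n, 2)
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def brute_force_metrics(cm: list[list[int]]) -> dict[str, float]:
    """The four evaluation metrics from a rows=true confusion matrix."""
    T = len(cm)
    n = sum(sum(row) for row in cm)
    tp = [cm[t][t] for t in range(T)]
    row = [sum(cm[t]) for t in range(T)]
    col = [sum(cm[s][t] for s in range(T)) for t in range(T)]

    accuracy = sum(tp) / n
    recall = [tp[t] / row[t] if row[t] else 0.0 for t in range(T)]
    precision = [tp[t] / col[t] if col[t] else 0.0 for t in range(T)]
    ba = sum(recall) / T
    avg_p = sum(precision) / T
    avg_r = sum(recall) / T
    macro_f1 = 2 * avg_p * avg_r / (avg_p + avg_r) if avg_p + avg_r else 0.0
    num = sum(tp) * n - sum(c * r for c, r in zip(col, row))
    den = sqrt(n**2 - sum(c**2 for c in col)) * sqrt(n**2 - sum(r**2 for r in row))
    mcc = num / den if den else 0.0
    return {
        "accuracy": accuracy,
        "balanced_accuracy": ba,
        "macro_f1": macro_f1,
        "mcc": mcc,
    }


def brute_force_consensus_edges(partitions) -> set[tuple[str, str]]:
    """All pairs co-clustered in EVERY partition, by direct enumeration."""
    cells = sorted(partitions[0].assignment)
    edges = set()
    for u, v in combinations(cells, 2):
        if all(p.assignment[u] == p.assignment[v] for p in partitions):
            edges.add((u, v))
    return edges


def brute_force_row_variances(partitions) -> list[float]:
    """Off-diagonal ARI row variance of every partition, by enumeration."""
    m = len(partitions)
    cells = sorted(partitions[0].assignment)
    R = [
        [
            brute_force_ari(
                [partitions[i].assignment[c] for c in cells],
                [partitions[j].assignment[c] for c in cells],
            )
            for j in range(m)
        ]
        for i in range(m)
    ]
    variances = []
    for i in range(m):
        vals = [R[i][j] for j in range(m) if j != i]
        mean = sum(vals) / len(vals)
        variances.append(sum((v - mean) ** 2 for v in vals) / len(vals))
    return variances


def brute_force_min_variance_row(partitions) -> int:
    """Index of the partition with minimum off-diagonal ARI row variance."""
    variances = brute_force_row_variances(partitions)
    return variances.index(min(variances))


def brute_force_nn(coords: dict, labeled: dict, unlabeled: set) -> dict:
    """Exhaustive 1-nearest-labeled-neighbor search (squared distances)."""
    order = list(coords)  # insertion order = cell index order
    out = {}
    for cell in unlabeled:
        x, y = coords[cell]
        best, best_d = None, float("inf")
        for ref in order:
            if ref not in labeled:
                continue
            rx, ry = coords[ref]
            d = (x - rx) ** 2 + (y - ry) ** 2
            if d < best_d:  # strict: first (lowest-index) cell wins ties
                best, best_d = ref, d
        out[cell] = labeled[best]
    return out
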