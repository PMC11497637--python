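"""Run-to-run cluster stability metrics for SOM partitions.

Three summary statistics quantify whether a trained map is stable:

* **AD** (average distance) — mean Euclidean distance of cells to their
  nearest node; a converged map sits at a low, stable AD.
* **AMJI** (average maximum Jaccard index) — for each node of the first
  run, the best Jaccard overlap with any node of the second run,
  averaged over nodes; 1 means the two runs partition the cells
  identically at the node level.
* **PMJIOT** (percentage of maximum Jaccard index over a threshold) —
  the percentage of first-run nodes whose best match strictly exceeds a
  threshold ``t`` (0.5 and 0.7 conventionally).

AMJI and PMJIOT are directional: rows of the Jaccard matrix are the
first run's nodes.  Sweeps pass (earlier run, later run) in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .som import NodeAssignment

__all__ = [
    "JaccardMatrix",
    "StabilityPoint",
    "average_distance",
    "jaccard_index",
    "jaccard_matrix",
    "amji",
    "pmjiot",
    "match_nodes",
    "contamination_fraction",
]


@dataclass(frozen=True)
class JaccardMatrix:
    """Pairwise node-overlap matrix between two runs over the same cells.

    ``values[i, j]`` is the Jaccard index between node ``i`` of run A
    and node ``j`` of run B; 1 exactly when the two (non-empty) node
    cell sets coincide.
    """

    values: np.ndarray
    run_a_id: str = "run_a"
    run_b_id: str = "run_b"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("Jaccard matrix must be 2-D and non-empty")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("Jaccard indices must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_max(self) -> np.ndarray:
        return self.values.max(axis=1)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.values,
            index=[f"{self.run_a_id}:{i}" for i in range(self.shape[0])],
            columns=[f"{self.run_b_id}:{j}" for j in range(self.shape[1])],
        )
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class StabilityPoint:
    """One row of a stability series: metrics at a given rlen."""

    rlen: int
    AD: float
    AMJI: float | None
    PMJIOT: dict[float, float]

    def __post_init__(self) -> None:
        if self.AD < 0:
            raise ValueError("AD must be non-negative")
        if self.AMJI is not None and not 0 <= self.AMJI <= 1:
            raise ValueError("AMJI must lie in [0, 1]")
        for t, p in self.PMJIOT.items():
            if not 0 <= p <= 100:
                raise ValueError(f"PMJIOT({t}) = {p} outside [0, 100]")


def average_distance(assignment: NodeAssignment) -> float:
    """AD: arithmetic mean of each cell's distance to its nearest node."""
    if assignment.n_cells == 0:
        raise ValueError("assignment is empty")
    return float(assignment.distance.mean())


def jaccard_index(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two cell-index sets.

    Two empty sets have an empty union; the index is defined as 0 (with
    a warning) so that downstream averages treat empty-vs-empty node
    pairs as dissimilar rather than identical.
    """
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        warnings.warn("Jaccard of two empty sets defined as 0", RuntimeWarning)
        return 0.0
    return len(a & b) / union


def jaccard_matrix(
    run_a: NodeAssignment,
    run_b: NodeAssignment,
    run_a_id: str = "run_a",
    run_b_id: str = "run_b",
) -> JaccardMatrix:
    """All-pairs Jaccard indices between the nodes of two runs.

    Both runs must partition the same cells (same count, same order).
    Computed via the k_A x k_B contingency table: for nodes with sizes
    ``|N_i|``, ``|M_j|`` and intersection ``C_ij``, the union is
    ``|N_i| + |M_j| - C_ij``.
    """
    if run_a.n_cells != run_b.n_cells:
        raise ValueError(
            f"runs partition different cell sets: {run_a.n_cells} vs "
            f"{run_b.n_cells} cells"
        )
    ka, kb = run_a.k, run_b.k
    pair = run_a.node_index * kb + run_b.node_index
    inter = np.bincount(pair, minlength=ka * kb).reshape(ka, kb).astype(np.float64)
    size_a = run_a.node_sizes().astype(np.float64)
    size_b = run_b.node_sizes().astype(np.float64)
    union = size_a[:, None] + size_b[None, :] - inter
    if (union == 0).any():
        warnings.warn(
            "empty-vs-empty node pairs present; their Jaccard is 0",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return JaccardMatrix(values, run_a_id, run_b_id)


def amji(jm: JaccardMatrix) -> float:
    """Average maximum Jaccard index: mean over run-A nodes of the best
    overlap with any run-B node."""
    return float(jm.row_max().mean())


def pmjiot(jm: JaccardMatrix, t: float) -> float:
    """Percentage of run-A nodes whose maximum Jaccard index strictly
    exceeds ``t`` (the indicator uses ``> t``, so a row maximum exactly
    at the threshold does not count)."""
    if not 0 <= t < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {t}")
    return float((jm.row_max() > t).mean() * 100.0)


def match_nodes(jm: JaccardMatrix) -> list[tuple[int, int, float]]:
    """Match every run-A node to its maximum-Jaccard run-B node.

    Returns one ``(node_a, node_b, J)`` triple per run-A node (so two
    12 x 12 runs yield 144 pairs).  The matching may be many-to-one;
    argmax ties break to the lowest run-B index.
    """
    best = np.argmax(jm.values, axis=1)  # first occurrence on ties
    return [
        (int(i), int(j), float(jm.values[i, j])) for i, j in enumerate(best)
    ]


def contamination_fraction(
    assignment: NodeAssignment, truth_labels, node: int
) -> float:
    """Fraction of a node's cells not belonging to its majority label.

    0 for a pure node; 0.5 for an exact half/half split.  Ground-truth
    labels come from the synthetic generator (or any external
    annotation of the same cells).
    """
    truth_labels = np.asarray(truth_labels)
    if len(truth_labels) != assignment.n_cells:
        raise ValueError("truth_labels length does not match assignment")
    cells = assignment.partition[node]
    if len(cells) == 0:
        raise ValueError(f"node {node} is empty; contamination undefined")
    _, counts = np.unique(truth_labels[cells], return_counts=True)
    return 1.0 - counts.max() / len(cells)
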