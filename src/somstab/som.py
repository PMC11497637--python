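"""Online Kohonen self-organizing maps with 64-bit-safe scheduling.

The total number of node updates is ``niter = rlen * n_cells``.  Stored
as a C ``int``, that product wraps around for tens of millions of cells
at moderate epoch counts, silently yielding a truncated — or, when the
wrapped value is negative, an entirely untrained — map.
:func:`schedule_iterations` computes the product exactly;
:func:`emulate_niter_32bit` reproduces the wraparound deterministically
so the failure mode can be audited and tested without a 27-million-cell
dataset.

The statsmodels-style entry point is :class:`SOM` (built from an
:class:`~somstab.preprocess.ExpressionMatrix` or a plain array), whose
:meth:`SOM.fit` returns a :class:`SOMResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .preprocess import ExpressionMatrix

__all__ = [
    "SOMConfig",
    "TrainingSchedule",
    "SOMModel",
    "NodeAssignment",
    "SOM",
    "SOMResults",
    "init_codebook",
    "schedule_iterations",
    "emulate_niter_32bit",
    "train_som",
    "assign_cells",
    "metacluster_codebook",
    "pseudo_bulk",
]

_INT32_MAX = 2**31 - 1
_MAX_METACLUSTERS = 80


@dataclass(frozen=True)
class SOMConfig:
    """Training settings for one SOM run.

    xdim, ydim : grid width and height; the map has ``k = xdim * ydim``
        nodes.
    rlen : number of epochs over the whole dataset; total updates are
        ``rlen * n_cells``.
    alpha_start, alpha_end : learning rate at the first and last update;
        decays linearly in between.
    seed : controls codebook initialization (k distinct cells).
    """

    xdim: int = 10
    ydim: int = 10
    rlen: int = 10
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    seed: int = 0
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.xdim < 1 or self.ydim < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.rlen < 0:
            raise ValueError("rlen must be >= 0")
        if not (0 < self.alpha_end <= self.alpha_start < 1):
            raise ValueError(
                "require 0 < alpha_end <= alpha_start < 1, got "
                f"({self.alpha_start}, {self.alpha_end})"
            )
        if self.distance != "euclidean":
            raise ValueError("only Euclidean distance is supported")

    @property
    def k(self) -> int:
        return self.xdim * self.ydim


@dataclass(frozen=True)
class TrainingSchedule:
    """Exact iteration count plus the per-step decay schedules."""

    niter: int
    alpha_start: float
    alpha_end: float
    radius0: float

    def alpha_at(self, t: int) -> float:
        """Learning rate at step ``t`` (0-based), linear decay."""
        if self.niter <= 0:
            return self.alpha_start
        return self.alpha_start - (self.alpha_start - self.alpha_end) * (t / self.niter)

    def radius_at(self, t: int) -> float:
        """Bubble-neighborhood radius at step ``t``, linear decay to 0."""
        if self.niter <= 0:
            return self.radius0
        return self.radius0 * (1.0 - t / self.niter)


def schedule_iterations(
    rlen: int,
    n_cells: int,
    alpha_start: float = 0.05,
    alpha_end: float = 0.01,
    radius0: float = 0.0,
) -> TrainingSchedule:
    """Compute ``niter = rlen * n_cells`` with an explicit 64-bit guard.

    The product is exact for all values below 2**63; anything larger
    raises rather than wrapping silently.
    """
    if rlen < 0 or n_cells < 1:
        raise ValueError("require rlen >= 0 and n_cells >= 1")
    niter = int(rlen) * int(n_cells)  # Python ints: no wraparound possible
    if niter >= 2**63:
        raise OverflowError(
            f"rlen * n_cells = {niter} exceeds the 64-bit scheduler range"
        )
    return TrainingSchedule(niter, alpha_start, alpha_end, radius0)


def emulate_niter_32bit(rlen: int, n_cells: int) -> int:
    """Signed-32-bit wraparound of ``rlen * n_cells``.

    Models storing the iteration count in a C ``int``: the true product
    is reduced to the two's-complement value
    ``((rlen * n_cells + 2**31) mod 2**32) - 2**31``.  A negative result
    means training performs no updates and the map stays at its
    initialization; a positive-but-truncated result silently under-trains.
    """
    if rlen < 0 or n_cells < 0:
        raise ValueError("rlen and n_cells must be non-negative")
    return ((int(rlen) * int(n_cells) + 2**31) % 2**32) - 2**31


def _grid_coords(xdim: int, ydim: int) -> np.ndarray:
    """Node positions: node ``j`` sits at column ``j % xdim``, row ``j // xdim``."""
    cols, rows = np.meshgrid(np.arange(xdim), np.arange(ydim))
    return np.column_stack([cols.ravel(), rows.ravel()]).astype(np.int64)


def _default_radius(grid_coords: np.ndarray) -> float:
    """Initial bubble radius: 0.67 quantile of inter-node grid distances."""
    if len(grid_coords) == 1:
        return 0.0
    return float(np.quantile(pdist(grid_coords.astype(float)), 0.67))


@dataclass(frozen=True)
class SOMModel:
    """A trained (or initialized) map: codebook plus provenance."""

    codebook: np.ndarray  # k x m node weight vectors
    grid_coords: np.ndarray  # k x 2 integer (col, row) positions
    config: SOMConfig
    init_codebook: np.ndarray  # retained for overflow/identity audits

    def __post_init__(self) -> None:
        k = self.config.k
        if self.codebook.shape[0] != k or self.grid_coords.shape != (k, 2):
            raise ValueError("codebook/grid shapes inconsistent with config")
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook contains non-finite values")

    @property
    def k(self) -> int:
        return self.config.k

    def save(self, directory) -> None:
        """Serialize as JSON metadata plus binary matrices (.npy)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "somstab-model-v1",
            "config": {
                "xdim": self.config.xdim,
                "ydim": self.config.ydim,
                "rlen": self.config.rlen,
                "alpha_start": self.config.alpha_start,
                "alpha_end": self.config.alpha_end,
                "seed": self.config.seed,
                "distance": self.config.distance,
            },
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.save(directory / "codebook.npy", self.codebook)
        np.save(directory / "init_codebook.npy", self.init_codebook)
        np.save(directory / "grid_coords.npy", self.grid_coords)

    @classmethod
    def load(cls, directory) -> "SOMModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta.get("format") != "somstab-model-v1":
            raise ValueError("not a somstab model container")
        return cls(
            codebook=np.load(directory / "codebook.npy"),
            grid_coords=np.load(directory / "grid_coords.npy"),
            config=SOMConfig(**meta["config"]),
            init_codebook=np.load(directory / "init_codebook.npy"),
        )

    def codebook_to_tsv(self, path, channel_names=None) -> None:
        import pandas as pd

        cols = list(channel_names) if channel_names is not None else [
            f"ch{c}" for c in range(self.codebook.shape[1])
        ]
        pd.DataFrame(self.codebook, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NodeAssignment:
    """Per-cell nearest node and the induced partition of the cell set.

    Node indices are 0-based.  ``partition[j]`` holds the (sorted) cell
    indices mapped to node ``j``; empty nodes yield empty arrays.
    """

    node_index: np.ndarray
    distance: np.ndarray
    k: int
    partition: tuple[np.ndarray, ...] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        node_index = np.asarray(self.node_index, dtype=np.int64)
        distance = np.asarray(self.distance, dtype=np.float64)
        if node_index.shape != distance.shape or node_index.ndim != 1:
            raise ValueError("node_index and distance must be equal-length 1-D")
        if len(node_index) and (node_index.min() < 0 or node_index.max() >= self.k):
            raise ValueError("node indices out of range")
        if (distance < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "node_index", node_index)
        object.__setattr__(self, "distance", distance)
        order = np.argsort(node_index, kind="stable")
        bounds = np.searchsorted(node_index[order], np.arange(self.k + 1))
        parts = tuple(
            np.sort(order[bounds[j] : bounds[j + 1]]) for j in range(self.k)
        )
        object.__setattr__(self, "partition", parts)

    @property
    def n_cells(self) -> int:
        return len(self.node_index)

    def node_sizes(self) -> np.ndarray:
        return np.bincount(self.node_index, minlength=self.k)


def _as_values(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


def init_codebook(x, config: SOMConfig) -> SOMModel:
    """Initialize the codebook with ``k`` distinct cells drawn by seed."""
    values = _as_values(x)
    k = config.k
    if values.shape[0] < k:
        raise ValueError(
            f"need at least k={k} cells to initialize, got {values.shape[0]}"
        )
    rng = np.random.default_rng(config.seed)
    rows = rng.choice(values.shape[0], size=k, replace=False)
    codebook = values[rows].astype(np.float64).copy()
    return SOMModel(
        codebook=codebook,
        grid_coords=_grid_coords(config.xdim, config.ydim),
        config=config,
        init_codebook=codebook.copy(),
    )


def train_som(
    x,
    config: SOMConfig,
    buggy_mode: bool = False,
    init: SOMModel | None = None,
) -> SOMModel:
    """Train an online SOM; returns a new model (initialization retained).

    With ``buggy_mode=True`` the exact iteration count is replaced by its
    signed-32-bit wraparound, clamped below at zero — so an overflowed
    negative count reproduces the untrained-map failure exactly.

    ``init`` allows several runs (e.g. an rlen ladder) to share one
    initialization; it must match ``config``'s grid and the data's
    channel count.
    """
    values = np.ascontiguousarray(_as_values(x), dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("training data contains non-finite values")
    if isinstance(x, ExpressionMatrix) and x.transform_state != "arcsinh_scaled":
        warnings.warn(
            f"training on transform_state={x.transform_state!r}; "
            "the standard pipeline trains on arcsinh-scaled data",
            RuntimeWarning,
        )
    model = init if init is not None else init_codebook(values, config)
    if model.codebook.shape[1] != values.shape[1]:
        raise ValueError("init codebook channel count does not match data")
    n = values.shape[0]

    schedule = schedule_iterations(
        config.rlen, n, config.alpha_start, config.alpha_end,
        _default_radius(model.grid_coords),
    )
    niter = schedule.niter
    if buggy_mode:
        emulated = emulate_niter_32bit(config.rlen, n)
        if emulated != niter:
            warnings.warn(
                f"32-bit niter overflow: true product {niter} wraps to "
                f"{emulated}; map will be "
                + ("left at initialization" if emulated < 0 else "under-trained"),
                RuntimeWarning,
            )
        niter = max(emulated, 0)

    codebook = model.init_codebook.astype(np.float64).copy()
    if niter > 0:
        from ._kernel import online_update

        griddist = cdist(
            model.grid_coords.astype(float), model.grid_coords.astype(float)
        )
        online_update(
            codebook, values, griddist, np.int64(niter),
            config.alpha_start, config.alpha_end, schedule.radius0,
        )
    return SOMModel(
        codebook=codebook,
        grid_coords=model.grid_coords,
        config=config,
        init_codebook=model.init_codebook.copy(),
    )


def assign_cells(x, model: SOMModel) -> NodeAssignment:
    """Map each cell to its nearest codebook vector (Euclidean).

    Ties go to the lowest node index; a node attracting no cells simply
    has an empty partition set.
    """
    values = _as_values(x)
    if values.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"data has {values.shape[1]} channels, codebook has "
            f"{model.codebook.shape[1]}"
        )
    d = cdist(values, model.codebook)
    idx = np.argmin(d, axis=1)
    return NodeAssignment(
        node_index=idx,
        distance=d[np.arange(len(idx)), idx],
        k=model.k,
    )


def metacluster_codebook(
    model: SOMModel, n_meta: int, max_meta: int = _MAX_METACLUSTERS
) -> np.ndarray:
    """Merge similar nodes: average-linkage hierarchical clustering of the
    codebook, cut at ``n_meta`` metaclusters.

    Returns a 0-based node -> metacluster map of length k; every
    metacluster is non-empty by construction of the cut.
    """
    k = model.k
    if not 1 <= n_meta <= min(k, max_meta):
        raise ValueError(
            f"n_meta must be in [1, {min(k, max_meta)}], got {n_meta}"
        )
    if n_meta == k:
        return np.arange(k)
    if k == 1:
        return np.zeros(1, dtype=np.int64)
    tree = linkage(model.codebook, method="average", metric="euclidean")
    labels = fcluster(tree, t=n_meta, criterion="maxclust") - 1
    return labels.astype(np.int64)


def pseudo_bulk(x, assignment: NodeAssignment) -> np.ndarray:
    """Per-node mean expression: row j = channel means over node j's cells.

    Empty nodes are flagged with NaN rows.
    """
    values = _as_values(x)
    if values.shape[0] != assignment.n_cells:
        raise ValueError("assignment does not refer to this matrix")
    k, m = assignment.k, values.shape[1]
    sums = np.zeros((k, m))
    np.add.at(sums, assignment.node_index, values)
    sizes = assignment.node_sizes().astype(float)
    with np.errstate(invalid="ignore"):
        means = sums / sizes[:, None]
    means[sizes == 0] = np.nan
    return means


class SOM:
    """Self-organizing map model bound to a dataset.

    Parameters
    ----------
    data : ExpressionMatrix or array-like
        Cells x channels; for the standard pipeline this is
        arcsinh-transformed and scaled.
    xdim, ydim, rlen, alpha, seed :
        See :class:`SOMConfig`; ``alpha`` is the (start, end) pair.

    Examples
    --------
    >>> res = SOM(data, xdim=10, ydim=10, rlen=10, seed=1).fit()
    >>> res.average_distance
    """

    def __init__(
        self,
        data,
        xdim: int = 10,
        ydim: int = 10,
        rlen: int = 10,
        alpha: tuple[float, float] = (0.05, 0.01),
        seed: int = 0,
    ):
        self.data = data
        self.config = SOMConfig(
            xdim=xdim, ydim=ydim, rlen=rlen,
            alpha_start=alpha[0], alpha_end=alpha[1], seed=seed,
        )
        self._init: SOMModel | None = None

    def initialize(self) -> SOMModel:
        """Draw (and cache) the seeded initial codebook."""
        if self._init is None:
            self._init = init_codebook(self.data, self.config)
        return self._init

    def fit(self, rlen: int | None = None, buggy_mode: bool = False) -> "SOMResults":
        """Train and return results; ``rlen`` overrides the configured value.

        Repeated fits (e.g. along an rlen ladder) share the cached
        initialization, so runs differ only in their iteration count.
        """
        config = self.config if rlen is None else SOMConfig(
            xdim=self.config.xdim, ydim=self.config.ydim, rlen=rlen,
            alpha_start=self.config.alpha_start,
            alpha_end=self.config.alpha_end, seed=self.config.seed,
        )
        init = self.initialize()
        model = train_som(self.data, config, buggy_mode=buggy_mode, init=init)
        return SOMResults(self, model)


class SOMResults:
    """Results of one SOM fit: trained codebook, assignment, diagnostics."""

    def __init__(self, som: SOM, model: SOMModel):
        self.som = som
        self.model = model
        self._assignment: NodeAssignment | None = None

    @property
    def codebook(self) -> np.ndarray:
        return self.model.codebook

    @property
    def assignment(self) -> NodeAssignment:
        if self._assignment is None:
            self._assignment = assign_cells(self.som.data, self.model)
        return self._assignment

    @property
    def average_distance(self) -> float:
        """Mean Euclidean distance of cells to their nearest node (AD)."""
        from .stability import average_distance

        return average_distance(self.assignment)

    def metacluster(self, n_meta: int) -> np.ndarray:
        return metacluster_codebook(self.model, n_meta)

    def pseudo_bulk(self) -> np.ndarray:
        return pseudo_bulk(self.som.data, self.assignment)

    def summary(self) -> str:
        cfg = self.model.config
        sizes = self.assignment.node_sizes()
        lines = [
            "Self-organizing map results",
            "===========================",
            f"grid:            {cfg.xdim} x {cfg.ydim} ({cfg.k} nodes)",
            f"cells:           {self.assignment.n_cells}",
            f"rlen (epochs):   {cfg.rlen}",
            f"niter:           {cfg.rlen * self.assignment.n_cells}",
            f"alpha:           ({cfg.alpha_start}, {cfg.alpha_end})",
            f"seed:            {cfg.seed}",
            f"average distance:{self.average_distance: .6f}",
            f"empty nodes:     {int((sizes == 0).sum())}",
            f"largest node:    {int(sizes.max())} cells",
        ]
        return "\n".join(lines)
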