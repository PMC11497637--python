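"""Seeded generator of cytometry-like Gaussian mixtures with ground truth.

Cells are drawn directly in arcsinh-transformed space with diagonal
covariance: each population is a multivariate Gaussian over the marker
channels, so population means are known in closed form and every
downstream metric has an exact oracle.  What the generator deliberately
does not emulate: ion-count noise, spillover, batch effects,
acquisition-time drift, doublets.

The default layout mirrors a PBMC-style panel: a handful of lineage
markers (CD3/CD4/CD8a/CD19/CD56) separate the populations strongly, the
remaining channels carry population-specific but weaker structure, for
39 channels in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ExpressionMatrix

__all__ = [
    "PopulationSpec",
    "SyntheticDataset",
    "generate_mixture",
    "default_populations",
    "make_contamination_scenario",
    "write_fcs",
    "read_labels",
]

_LINEAGE = ("CD3", "CD4", "CD8a", "CD19", "CD56")

#: arcsinh-domain intensity for a positively expressed lineage marker,
#: background level, and the common per-channel noise sd.
_HI, _LO, _SD = 3.5, 0.5, 0.4


def channel_names(m_channels: int) -> tuple[str, ...]:
    base = list(_LINEAGE[:m_channels])
    base += [f"marker{i:02d}" for i in range(len(base), m_channels)]
    return tuple(base)


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component: mixing proportion plus per-channel mean/sd
    in arcsinh units."""

    name: str
    proportion: float
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=np.float64)
        sd = np.asarray(self.sd, dtype=np.float64)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and sd must be equal-length vectors")
        if not 0 < self.proportion <= 1:
            raise ValueError(f"proportion must be in (0, 1], got {self.proportion}")
        if (sd <= 0).any():
            raise ValueError("all sd entries must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated mixture: expression matrix, per-cell truth labels, and
    the spec + seed that produced it."""

    matrix: ExpressionMatrix
    truth_labels: np.ndarray
    populations: tuple[PopulationSpec, ...]
    seed: int
    designated_channels: tuple[str, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells


def generate_mixture(
    populations: list[PopulationSpec],
    n_cells: int,
    m_channels: int | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw ``n_cells`` from the mixture; deterministic per seed.

    Population counts follow a multinomial draw from the proportions;
    cells are then generated per population and shuffled, with the true
    population name recorded for every cell.
    """
    props = np.array([p.proportion for p in populations])
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    m = len(populations[0].mean)
    if m_channels is not None and m_channels != m:
        raise ValueError(
            f"m_channels={m_channels} but population vectors have length {m}"
        )
    for p in populations:
        if len(p.mean) != m:
            raise ValueError("all populations must share one channel count")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, props)
    blocks, labels = [], []
    for pop, c in zip(populations, counts):
        if c == 0:
            continue
        blocks.append(rng.normal(pop.mean, pop.sd, size=(c, m)))
        labels += [pop.name] * c
    values = np.vstack(blocks)
    order = rng.permutation(n_cells)
    matrix = ExpressionMatrix(
        values[order], channel_names(m), transform_state="arcsinh"
    )
    return SyntheticDataset(
        matrix=matrix,
        truth_labels=np.asarray(labels, dtype=object)[order],
        populations=tuple(populations),
        seed=seed,
    )


#: Default PBMC-like panel: (name, proportion, lineage-positive markers).
#: Proportions span major subsets down to two rare (0.5%) populations.
_DEFAULT_PANEL = (
    ("CD4_T_naive", 0.22, ("CD3", "CD4")),
    ("CD4_T_memory", 0.15, ("CD3", "CD4")),
    ("CD8_T_naive", 0.12, ("CD3", "CD8a")),
    ("CD8_T_memory", 0.10, ("CD3", "CD8a")),
    ("B_naive", 0.10, ("CD19",)),
    ("B_memory", 0.05, ("CD19",)),
    ("NK", 0.08, ("CD56",)),
    ("NKT", 0.04, ("CD3", "CD56")),
    ("mono_classical", 0.08, ()),
    ("mono_nonclassical", 0.03, ()),
    ("dendritic", 0.02, ()),
    ("basophil", 0.005, ()),
    ("pDC", 0.005, ()),
)


def default_populations(m_channels: int = 39) -> list[PopulationSpec]:
    """A 13-population PBMC-like mixture with two rare (0.5%) subsets.

    Lineage markers (CD3/CD4/CD8a/CD19/CD56) follow the populations'
    canonical phenotypes; each population additionally expresses a fixed
    population-specific signature on ~10 of the remaining channels
    (deterministic construction), so subsets that share lineage markers
    remain separable — the multi-marker structure that anchors SOM nodes
    in real cytometry data.
    """
    if m_channels < 6:
        raise ValueError("default panel needs at least 6 channels")
    names = channel_names(m_channels)
    idx = {n: i for i, n in enumerate(names)}
    rng = np.random.default_rng(2024)  # fixed: the panel is a constant
    pops = []
    for name, prop, lineage in _DEFAULT_PANEL:
        mean = np.full(m_channels, _LO)
        for mk in lineage:
            mean[idx[mk]] = _HI
        n_sig = min(10, m_channels - 5)
        sig = rng.choice(np.arange(5, m_channels), size=n_sig, replace=False)
        mean[sig] = rng.uniform(2.0, 4.0, size=n_sig)
        pops.append(PopulationSpec(name, prop, mean, np.full(m_channels, 0.3)))
    return pops


def make_contamination_scenario(
    n_cells: int, seed: int = 0, m_channels: int = 39
) -> SyntheticDataset:
    """The default panel with a CD4/CD8 T-cell pair built to mix.

    The panel's naive CD4 and CD8 T populations are replaced by a
    "CD4_T"/"CD8_T" pair that shares high CD3 and near-identical minor
    channels: they differ by 4.5 sd on the designated "CD4" and "CD8a"
    channels (so each designated channel is clearly bimodal in the
    pooled data), while the minor channels carry most of the per-cell
    variance.  A raw sampled-cell codebook therefore attracts these
    cells by noise rather than phenotype, and under-trained maps mix
    the two populations inside single nodes — the contamination effect
    this scenario is built to expose.  The remaining panel populations
    keep the map busy, so low-epoch runs are unstable the way they are
    on real many-population data.
    """
    if n_cells < 1000:
        raise ValueError("contamination scenario needs n_cells >= 1000")
    names = channel_names(m_channels)
    idx = {n: i for i, n in enumerate(names)}

    base = np.full(m_channels, _LO)
    base[idx["CD3"]] = _HI

    # Designated channels: a 4.5-sd gap (0.5 vs 2.3, sd 0.4) — clearly
    # bimodal, yet small against the pooled spread of the minor channels.
    mean_cd4 = base.copy()
    mean_cd4[idx["CD4"]] = 2.3
    mean_cd8 = base.copy()
    mean_cd8[idx["CD8a"]] = 2.3
    # partially overlapping minor channels: small, opposite-sign shifts
    rng = np.random.default_rng(7)
    wiggle = rng.uniform(0.02, 0.08, size=m_channels - 5)
    mean_cd4[5:] += wiggle
    mean_cd8[5:] -= wiggle
    pair_sd = np.full(m_channels, 0.6)
    pair_sd[[idx["CD4"], idx["CD8a"]]] = 0.4

    populations = []
    for p in default_populations(m_channels):
        if p.name == "CD4_T_naive":
            populations.append(
                PopulationSpec("CD4_T", p.proportion, mean_cd4, pair_sd)
            )
        elif p.name == "CD8_T_naive":
            populations.append(
                PopulationSpec("CD8_T", p.proportion, mean_cd8, pair_sd)
            )
        else:
            populations.append(p)
    ds = generate_mixture(populations, n_cells, seed=seed)
    return SyntheticDataset(
        matrix=ds.matrix,
        truth_labels=ds.truth_labels,
        populations=ds.populations,
        seed=seed,
        designated_channels=("CD4", "CD8a"),
    )


def write_fcs(dataset: SyntheticDataset, path) -> None:
    """Write the dataset as FCS 3.1 plus a truth-label sidecar TSV.

    Values are stored exactly as generated (arcsinh domain); the
    sidecar ``<stem>.labels.tsv`` has one label per cell in file order,
    keeping the FCS itself standard-clean.
    """
    from .fcs import write_fcs_matrix

    path = Path(path)
    write_fcs_matrix(dataset.matrix.values, list(dataset.matrix.channel_names), path)
    sidecar = path.with_suffix(".labels.tsv")
    with open(sidecar, "w") as fh:
        fh.write("label\n")
        fh.writelines(f"{lab}\n" for lab in dataset.truth_labels)


def read_labels(path) -> np.ndarray:
    """Read a truth-label sidecar written by :func:`write_fcs`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "label":
        raise ValueError(f"{path} is not a label sidecar")
    return np.asarray(lines[1:], dtype=object)
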