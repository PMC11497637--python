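"""Expression-matrix container and cytometry preprocessing.

Implements the standard CyTOF preprocessing chain: channel selection at
load time, the inverse-hyperbolic-sine (arcsinh) transform with a
configurable cofactor, per-channel standardization, and reproducible
down-sampling without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "TransformSpec",
    "TransformStateError",
    "transform_arcsinh",
    "scale_channels",
    "downsample",
    "plan_downsample_for_limit",
]

#: Legal transform states, in pipeline order.
_STATES = ("raw", "arcsinh", "arcsinh_scaled")


class TransformStateError(RuntimeError):
    """Raised when an operation is applied in the wrong transform state."""


@dataclass(frozen=True)
class TransformSpec:
    """Arcsinh transform settings.

    cofactor : divisor applied before asinh; 5 is the CyTOF convention.
    scale    : whether channels are standardized after the transform.
    """

    cofactor: float = 5.0
    scale: bool = True

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be positive, got {self.cofactor}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """An ``n_cells x n_channels`` matrix of marker intensities.

    ``values`` uses 64-bit addressing throughout (numpy), so matrices
    whose element count exceeds 2**31 - 1 are representable.

    ``scale_center``/``scale_sd`` record the standardization parameters
    once :func:`scale_channels` has been applied (provenance).
    """

    values: np.ndarray
    channel_names: tuple[str, ...]
    transform_state: str = "raw"
    scale_center: np.ndarray | None = field(default=None, compare=False)
    scale_sd: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one cell and one channel")
        if not np.isfinite(values).all():
            raise ValueError("matrix contains non-finite values")
        names = tuple(str(c) for c in self.channel_names)
        if len(names) != m:
            raise ValueError(f"{len(names)} channel names for {m} channels")
        if len(set(names)) != m:
            raise ValueError("channel names must be unique")
        if self.transform_state not in _STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, channels: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``channels``, in the order given."""
        idx = []
        for c in channels:
            if c not in self.channel_names:
                raise KeyError(
                    f"channel {c!r} not found; available: {list(self.channel_names)}"
                )
            idx.append(self.channel_names.index(c))
        return replace(
            self,
            values=self.values[:, idx].copy(),
            channel_names=tuple(channels),
            scale_center=None,
            scale_sd=None,
        )

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with a channel-name header row."""
        import pandas as pd

        pd.DataFrame(self.values, columns=list(self.channel_names)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, transform_state: str = "raw") -> "ExpressionMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=np.float64), tuple(df.columns), transform_state)


def transform_arcsinh(
    x: ExpressionMatrix, spec: TransformSpec = TransformSpec()
) -> ExpressionMatrix:
    """Apply ``asinh(value / cofactor)`` elementwise.

    Requires ``transform_state == "raw"``; the result is in state
    ``"arcsinh"``.  The transform is strictly monotone and odd, so it
    compresses high intensities while remaining near-linear around zero.
    """
    if x.transform_state != "raw":
        raise TransformStateError(
            f"arcsinh transform requires raw data, got {x.transform_state!r}"
        )
    return replace(x, values=np.arcsinh(x.values / spec.cofactor), transform_state="arcsinh")


def scale_channels(x: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each channel to mean 0, sample sd 1 (divisor n - 1).

    A zero-variance channel cannot be standardized; it is mapped to all
    zeros with a warning so downstream SOM training stays finite.
    """
    if x.transform_state != "arcsinh":
        raise TransformStateError(
            f"scaling requires arcsinh-transformed data, got {x.transform_state!r}"
        )
    center = x.values.mean(axis=0)
    sd = x.values.std(axis=0, ddof=1) if x.n_cells > 1 else np.zeros(x.n_channels)
    degenerate = sd <= 0
    if degenerate.any():
        bad = [x.channel_names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance channel(s) {bad} scaled to all zeros", RuntimeWarning
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    scaled = (x.values - center) / safe_sd
    scaled[:, degenerate] = 0.0
    return replace(
        x,
        values=scaled,
        transform_state="arcsinh_scaled",
        scale_center=center,
        scale_sd=sd,
    )


def downsample(x: ExpressionMatrix, target_n: int, seed: int) -> ExpressionMatrix:
    """Sample ``target_n`` distinct cells uniformly without replacement.

    The chosen cells keep their original row order, so the subset is a
    deterministic function of ``(x, target_n, seed)`` alone.
    """
    if not 1 <= target_n <= x.n_cells:
        raise ValueError(
            f"target_n must be in [1, {x.n_cells}], got {target_n}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(x.n_cells, size=target_n, replace=False))
    return replace(x, values=x.values[idx].copy())


def plan_downsample_for_limit(m_channels: int, element_budget: int) -> int:
    """Cell count whose ``cells x channels`` product fits an element budget.

    Returns ``round(element_budget / m_channels)`` (round-half-away at the
    midpoint).  For 39 channels and a 2**30-element budget this yields
    27,531,842 cells.
    """
    if m_channels < 1:
        raise ValueError(f"m_channels must be >= 1, got {m_channels}")
    if element_budget < m_channels:
        raise ValueError(
            f"element_budget must be >= m_channels, got {element_budget}"
        )
    q, r = divmod(element_budget, m_channels)
    return q + (1 if 2 * r >= m_channels else 0)
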