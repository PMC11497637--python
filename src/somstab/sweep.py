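"""Parameter sweep: stability curves over an rlen ladder, LOWESS
smoothing, plateau detection and a minimal-stable-rlen recommendation.

For each (grid dimension, learning-rate pair) the sweep trains one SOM
per rlen in the ladder, all sharing a single seeded initialization, and
scores stability between *consecutive* ladder runs with AMJI and
PMJIOT (plus per-run AD).  The smoothed PMJIOT(0.5) curve is scanned
for its plateau — the earliest rlen from which the curve stays within
an epsilon band of its maximum — which becomes the recommended minimal
rlen.  A pure-arithmetic 32-bit overflow audit flags ladder entries
whose ``rlen * n_cells`` product would wrap in a 32-bit iteration
counter.

Statsmodels-style entry point: ``StabilitySweep(data, spec).fit()``
returning :class:`SweepResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .som import SOM, emulate_niter_32bit
from .stability import amji, jaccard_matrix, pmjiot

__all__ = [
    "DEFAULT_RLEN_LADDER",
    "SweepSpec",
    "StabilitySeries",
    "StabilitySweep",
    "SweepResults",
    "run_rlen_ladder",
    "smooth_lowess",
    "detect_plateau",
    "audit_overflow",
]

#: The conventional optimization ladder of epoch counts.
DEFAULT_RLEN_LADDER: tuple[int, ...] = (
    1, 5, 10, 20, 40, 60, 80, 100, 120, 140, 160, 180, 200, 220, 240,
    260, 280, 300, 320, 340, 360, 380, 400, 600, 800, 1000,
)

DEFAULT_GRID_DIMS: tuple[tuple[int, int], ...] = (
    (10, 10), (12, 12), (14, 14), (16, 16),
)

DEFAULT_ALPHAS: tuple[tuple[float, float], ...] = (
    (0.05, 0.01), (0.05, 0.001), (0.01, 0.001), (0.1, 0.05),
)


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep and how to post-process the curves."""

    rlen_ladder: tuple[int, ...] = DEFAULT_RLEN_LADDER
    grid_dims: tuple[tuple[int, int], ...] = DEFAULT_GRID_DIMS
    alphas: tuple[tuple[float, float], ...] = DEFAULT_ALPHAS
    thresholds: tuple[float, ...] = (0.5, 0.7)
    shared_init_seed: int = 0
    lowess_frac: float = 0.3
    plateau_epsilon: float = 0.05

    def __post_init__(self) -> None:
        ladder = tuple(int(r) for r in self.rlen_ladder)
        if len(ladder) < 2 or any(
            b <= a for a, b in zip(ladder, ladder[1:])
        ):
            raise ValueError("rlen_ladder must be strictly increasing, length >= 2")
        if any(not 0 <= t < 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1)")
        if not 0 < self.lowess_frac <= 1:
            raise ValueError("lowess_frac must lie in (0, 1]")
        if self.plateau_epsilon <= 0:
            raise ValueError("plateau_epsilon must be positive")
        object.__setattr__(self, "rlen_ladder", ladder)
        object.__setattr__(self, "grid_dims", tuple(map(tuple, self.grid_dims)))
        object.__setattr__(self, "alphas", tuple(map(tuple, self.alphas)))
        object.__setattr__(self, "thresholds", tuple(self.thresholds))


@dataclass
class StabilitySeries:
    """Per-rlen stability metrics for one (grid, alpha) scenario.

    AD has one value per ladder entry; the pairwise metrics (AMJI,
    PMJIOT) compare consecutive runs and are indexed by the *earlier*
    rlen of each pair (that many epochs already agree with the next
    run), so they have ``len(ladder) - 1`` values.
    """

    grid: tuple[int, int]
    alpha: tuple[float, float]
    rlen: np.ndarray                      # full ladder
    AD: np.ndarray                        # len(ladder)
    pair_rlen: np.ndarray                 # ladder[:-1]
    AMJI: np.ndarray                      # len(ladder) - 1
    PMJIOT: dict[float, np.ndarray]       # threshold -> len(ladder) - 1
    smoothed: dict[str, np.ndarray] = field(default_factory=dict)

    def smooth(self, frac: float) -> None:
        """Attach LOWESS-smoothed AMJI and PMJIOT curves.

        Series too short to smooth (fewer than 3 pairwise points) are
        carried through unsmoothed.
        """
        def fit(vals):
            if len(self.pair_rlen) < 3:
                return np.asarray(vals, dtype=np.float64).copy()
            return smooth_lowess(list(zip(self.pair_rlen, vals)), frac)

        self.smoothed["AMJI"] = fit(self.AMJI)
        for t, vals in self.PMJIOT.items():
            self.smoothed[f"PMJIOT_{t}"] = fit(vals)

    def points(self):
        """The series as per-rlen :class:`~somstab.stability.StabilityPoint`
        records (pairwise metrics attach to the earlier rlen of each pair)."""
        from .stability import StabilityPoint

        out = []
        for i, r in enumerate(self.rlen):
            last = i == len(self.rlen) - 1
            out.append(StabilityPoint(
                rlen=int(r),
                AD=float(self.AD[i]),
                AMJI=None if last else float(self.AMJI[i]),
                PMJIOT={} if last else {
                    t: float(v[i]) for t, v in self.PMJIOT.items()
                },
            ))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rlen):
            row = {
                "xdim": self.grid[0], "ydim": self.grid[1],
                "alpha_start": self.alpha[0], "alpha_end": self.alpha[1],
                "rlen": int(r), "AD": self.AD[i],
            }
            if i < len(self.rlen) - 1:
                row["AMJI"] = self.AMJI[i]
                for t, vals in self.PMJIOT.items():
                    row[f"PMJIOT_{t}"] = vals[i]
            rows.append(row)
        return pd.DataFrame(rows)


def run_rlen_ladder(
    x, spec: SweepSpec, grid: tuple[int, int], alpha: tuple[float, float]
) -> StabilitySeries:
    """Train one SOM per ladder rlen (shared initialization) and score
    consecutive-run stability."""
    som = SOM(
        x, xdim=grid[0], ydim=grid[1],
        alpha=alpha, seed=spec.shared_init_seed,
    )
    ladder = spec.rlen_ladder
    ad, assignments = [], []
    for rlen in ladder:
        res = som.fit(rlen=rlen)
        assignments.append(res.assignment)
        ad.append(res.average_distance)

    amji_vals, pm_vals = [], {t: [] for t in spec.thresholds}
    for earlier, later in zip(assignments, assignments[1:]):
        jm = jaccard_matrix(earlier, later)
        amji_vals.append(amji(jm))
        for t in spec.thresholds:
            pm_vals[t].append(pmjiot(jm, t))

    series = StabilitySeries(
        grid=tuple(grid),
        alpha=tuple(alpha),
        rlen=np.asarray(ladder),
        AD=np.asarray(ad),
        pair_rlen=np.asarray(ladder[:-1]),
        AMJI=np.asarray(amji_vals),
        PMJIOT={t: np.asarray(v) for t, v in pm_vals.items()},
    )
    series.smooth(spec.lowess_frac)
    return series


def smooth_lowess(series, frac: float) -> np.ndarray:
    """LOWESS fit of (x, value) pairs, evaluated at the input x values.

    Locally weighted linear regression: a constant series comes back
    unchanged and an exactly linear series is reproduced to numerical
    precision.
    """
    pts = np.asarray(series, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("LOWESS smoothing needs at least 3 (x, value) points")
    if not 0 < frac <= 1:
        raise ValueError(f"frac must lie in (0, 1], got {frac}")
    out = _sm_lowess(pts[:, 1], pts[:, 0], frac=frac, return_sorted=False)
    return np.asarray(out, dtype=np.float64)


def detect_plateau(series, epsilon: float):
    """Earliest x from which the curve stays within ``epsilon`` of its max.

    ``series`` is a sequence of (x, smoothed value) pairs in increasing
    x order.  Returns the x of the earliest such point, or ``None`` when
    the band is only entered within the final two entries (too late to
    call a plateau).
    """
    pts = np.asarray(series, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("series must be non-empty (x, value) pairs")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = pts[:, 1]
    band = values.max() - epsilon
    inside = values >= band
    # suffix-scan: first index from which every later value stays inside
    ok_from = len(values)
    for i in range(len(values) - 1, -1, -1):
        if inside[i]:
            ok_from = i
        else:
            break
    if ok_from >= len(values) - 2 and len(values) >= 3:
        return None
    if ok_from == len(values):
        return None
    return pts[ok_from, 0]


def amji_heatmap(
    x, spec: SweepSpec, grid: tuple[int, int], alpha: tuple[float, float]
) -> pd.DataFrame:
    """All-pairs AMJI between every two ladder runs (rows = earlier run).

    Quadratic in the ladder length, hence optional; the sweep itself
    only scores consecutive runs.
    """
    som = SOM(x, xdim=grid[0], ydim=grid[1], alpha=alpha,
              seed=spec.shared_init_seed)
    assignments = [som.fit(rlen=r).assignment for r in spec.rlen_ladder]
    ladder = list(spec.rlen_ladder)
    values = np.ones((len(ladder), len(ladder)))
    for i in range(len(ladder)):
        for j in range(len(ladder)):
            if i != j:
                values[i, j] = amji(jaccard_matrix(assignments[i], assignments[j]))
    return pd.DataFrame(values, index=ladder, columns=ladder)


def audit_overflow(rlen_ladder, n_cells: int) -> pd.DataFrame:
    """Pure-arithmetic 32-bit overflow audit for ``niter = rlen * n``.

    A flag is raised where the emulated signed-32-bit product is <= 0
    (for rlen > 0): those runs would leave the map at its
    initialization (negative) or do nothing (zero).
    """
    rows = []
    for rlen in rlen_ladder:
        true = int(rlen) * int(n_cells)
        emu = emulate_niter_32bit(rlen, n_cells)
        rows.append({
            "rlen": int(rlen),
            "niter_true": true,
            "niter_32bit": emu,
            "overflowed": emu != true,
            "overflow_flag": bool(emu <= 0 and rlen > 0),
        })
    return pd.DataFrame(rows)


class StabilitySweep:
    """Sweep model bound to a dataset.

    Parameters
    ----------
    data : ExpressionMatrix or array
        Cells x channels (arcsinh-scaled for the standard pipeline).
    spec : SweepSpec
        Ladder, grids, alphas, thresholds, smoothing and plateau settings.
    declared_n_cells : int, optional
        Cell count to use for the overflow audit when auditing a larger
        dataset than the one being swept (metadata-only audit).
    """

    def __init__(self, data, spec: SweepSpec = SweepSpec(), declared_n_cells=None):
        self.data = data
        self.spec = spec
        self.declared_n_cells = declared_n_cells

    def fit(self, progress: bool = False) -> "SweepResults":
        series = {}
        for grid in self.spec.grid_dims:
            for alpha in self.spec.alphas:
                if progress:  # pragma: no cover - cosmetic
                    print(f"sweep: grid={grid} alpha={alpha}", flush=True)
                series[(grid, alpha)] = run_rlen_ladder(
                    self.data, self.spec, grid, alpha
                )
        return SweepResults(self, series)


class SweepResults:
    """Stability curves, recommendations and the overflow audit."""

    def __init__(self, sweep: StabilitySweep, series: dict):
        self.sweep = sweep
        self.series = series
        self.spec = sweep.spec
        n = sweep.declared_n_cells
        if n is None:
            values = sweep.data.values if hasattr(sweep.data, "values") else np.asarray(sweep.data)
            n = values.shape[0]
        self.audited_n_cells = int(n)
        self.overflow = audit_overflow(self.spec.rlen_ladder, self.audited_n_cells)
        self.recommended_rlen = {
            key: self._recommend(s) for key, s in series.items()
        }

    def _recommend(self, s: StabilitySeries):
        """Plateau of smoothed PMJIOT(0.5); fallback to smoothed AMJI."""
        eps = self.spec.plateau_epsilon
        key = "PMJIOT_0.5"
        if key in s.smoothed and s.smoothed[key].max() <= 0:
            # a PMJIOT curve that never leaves zero carries no plateau
            # signal; fall through to the AMJI curve instead
            key = "absent"
        if key in s.smoothed:
            # PMJIOT is on a 0-100 scale; epsilon is specified on [0, 1]
            plateau = detect_plateau(
                list(zip(s.pair_rlen, s.smoothed[key] / 100.0)), eps
            )
        else:
            plateau = None
        if plateau is None:
            plateau = detect_plateau(
                list(zip(s.pair_rlen, s.smoothed["AMJI"])), eps
            )
        if plateau is None:
            warnings.warn(
                f"no stability plateau found for grid={s.grid} alpha={s.alpha}",
                RuntimeWarning,
            )
            return None
        return int(plateau)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (grid, alpha, rlen)."""
        frames = []
        flag = dict(zip(self.overflow["rlen"], self.overflow["overflow_flag"]))
        for s in self.series.values():
            df = s.to_frame()
            df["overflow_flag"] = df["rlen"].map(flag)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "SOM stability sweep",
            "===================",
            f"cells (audited n): {self.audited_n_cells}",
            f"ladder: {list(self.spec.rlen_ladder)}",
            f"plateau rule: LOWESS(frac={self.spec.lowess_frac}) PMJIOT(0.5), "
            f"epsilon={self.spec.plateau_epsilon}",
            "",
            "recommended minimal stable rlen",
            "-------------------------------",
        ]
        for (grid, alpha), rec in self.recommended_rlen.items():
            lines.append(
                f"grid {grid[0]}x{grid[1]}, alpha {alpha}: "
                + (str(rec) if rec is not None else "none (no plateau)")
            )
        flagged = self.overflow.loc[self.overflow.overflow_flag, "rlen"].tolist()
        lines.append("")
        lines.append(
            "32-bit overflow-negative rlen values: "
            + (str(flagged) if flagged else "none")
        )
        return "\n".join(lines)
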