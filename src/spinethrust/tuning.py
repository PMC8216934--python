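"""Smoothing-parameter calibration by grid search, and repeatability.

The tuner runs the full pipeline for every (alpha, beta) cell of a grid
and scores each cell by the squared Pearson correlation between spine
thrust from a manual reference measurement and spine thrust from the
automatic detection, over the specimens the cell detects successfully.
The chosen optimum is the cell with the highest r2; among ties, the one
applying the least smoothing (smallest alpha+beta, then smallest beta).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contour_io import NormalizedContour
from .curvature import SmoothingParams
from .errors import PairingError, TuningError, UndefinedCorrelationError
from .pipeline import measure_contour

__all__ = [
    "GridSpec",
    "TuningResult",
    "RepeatabilityResult",
    "pearson_r2",
    "grid_search",
    "repeatability",
    "default_grid",
    "tuning_frame",
]

#: fewest surviving specimens for a cell's correlation to be defined
MIN_SPECIMENS = 3


@dataclass(frozen=True)
class GridSpec:
    """Strictly increasing alpha and beta values to explore."""

    alpha_values: tuple
    beta_values: tuple

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.alpha_values)
        b = tuple(float(v) for v in self.beta_values)
        if not a or not b:
            raise TuningError("grid must have at least one alpha and one beta value")
        if any(y <= x for x, y in zip(a[:-1], a[1:])) or any(
            y <= x for x, y in zip(b[:-1], b[1:])
        ):
            raise TuningError("grid values must be strictly increasing")
        object.__setattr__(self, "alpha_values", a)
        object.__setattr__(self, "beta_values", b)


def default_grid() -> GridSpec:
    """Default exploration grid bracketing the calibrated optimum."""
    return GridSpec(
        alpha_values=tuple(np.round(np.arange(0.005, 0.0501, 0.005), 3)),
        beta_values=tuple(np.round(np.arange(0.005, 0.1001, 0.005), 3)),
    )


@dataclass(frozen=True)
class TuningResult:
    """r2 surface over the grid with the selected optimum.

    Cells with fewer than MIN_SPECIMENS survivors (or zero variance) are
    NaN and never selected.
    """

    grid: GridSpec
    r2_surface: np.ndarray  # (len(alpha), len(beta)), NaN = undefined
    n_used: np.ndarray  # same shape, int
    best_alpha: float
    best_beta: float

    @property
    def best_r2(self) -> float:
        i = self.grid.alpha_values.index(self.best_alpha)
        j = self.grid.beta_values.index(self.best_beta)
        return float(self.r2_surface[i, j])


@dataclass(frozen=True)
class RepeatabilityResult:
    """OLS of second-pass ST on first-pass ST over paired specimens."""

    slope: float
    intercept: float
    r2: float
    n: int


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared sample Pearson correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < MIN_SPECIMENS:
        raise ValueError(f"need at least {MIN_SPECIMENS} pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the sequences")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def _select_best(
    surface: np.ndarray, grid: GridSpec
) -> tuple[float, float]:
    """Maximal r2; ties broken by smallest alpha+beta, then smallest beta."""
    if np.all(np.isnan(surface)):
        raise TuningError("every grid cell is undefined (too few valid detections)")
    best = np.nanmax(surface)
    cands = [
        (a, b)
        for i, a in enumerate(grid.alpha_values)
        for j, b in enumerate(grid.beta_values)
        if surface[i, j] == best
    ]
    return min(cands, key=lambda ab: (ab[0] + ab[1], ab[1]))


def grid_search(
    contours: Mapping[str, NormalizedContour],
    manual_st: Mapping[str, float],
    grid: GridSpec,
    base_params: SmoothingParams | None = None,
) -> TuningResult:
    """Score every (alpha, beta) cell against manual reference measurements.

    Per cell, the full pipeline runs from scratch on every specimen with
    a manual reference; specimens the cell excludes are dropped from that
    cell's correlation, and the survivor count is reported per cell.
    """
    if base_params is None:
        base_params = SmoothingParams()
    ids = [sid for sid in contours if sid in manual_st]
    if len(ids) < MIN_SPECIMENS:
        raise TuningError(
            f"need at least {MIN_SPECIMENS} specimens with manual reference, got {len(ids)}"
        )
    na, nb = len(grid.alpha_values), len(grid.beta_values)
    surface = np.full((na, nb), np.nan)
    n_used = np.zeros((na, nb), dtype=int)
    for i, a in enumerate(grid.alpha_values):
        for j, b in enumerate(grid.beta_values):
            params = replace(base_params, alpha=a, beta=b)
            auto, manual = [], []
            for sid in ids:
                out = measure_contour(contours[sid], params)
                if out.status == "valid":
                    auto.append(out.thrust.ST)
                    manual.append(manual_st[sid])
            n_used[i, j] = len(auto)
            if len(auto) >= MIN_SPECIMENS:
                try:
                    surface[i, j] = pearson_r2(manual, auto)
                except UndefinedCorrelationError:
                    pass
    best_alpha, best_beta = _select_best(surface, grid)
    return TuningResult(
        grid=grid,
        r2_surface=surface,
        n_used=n_used,
        best_alpha=best_alpha,
        best_beta=best_beta,
    )


def tuning_frame(result: TuningResult) -> pd.DataFrame:
    """Long-format (alpha, beta, r2, n_used, selected) table of the surface."""
    rows = []
    for i, a in enumerate(result.grid.alpha_values):
        for j, b in enumerate(result.grid.beta_values):
            rows.append(
                {
                    "alpha": a,
                    "beta": b,
                    "r2": result.r2_surface[i, j],
                    "n_used": int(result.n_used[i, j]),
                    "selected": a == result.best_alpha and b == result.best_beta,
                }
            )
    return pd.DataFrame(rows)


def repeatability(
    first: Mapping[str, float], second: Mapping[str, float]
) -> RepeatabilityResult:
    """Regress a second measurement pass on the first over paired specimens."""
    unpaired = sorted(set(first) ^ set(second))
    if unpaired:
        raise PairingError(f"unpaired specimen id(s): {', '.join(unpaired)}")
    ids = sorted(first)
    if len(ids) < MIN_SPECIMENS:
        raise ValueError(f"need at least {MIN_SPECIMENS} pairs, got {len(ids)}")
    x = np.array([first[i] for i in ids])
    y = np.array([second[i] for i in ids])
    fit = stats.linregress(x, y)
    return RepeatabilityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(ids),
    )
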