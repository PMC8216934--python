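"""Two-layer smoothing and circumscribed-circle curvature of open contours.

The pipeline is: (1) rectangular smoothing of the contour coordinates,
window fraction ``alpha``; (2) raw signed curvature from the circumcircle
of each point and its immediate neighbors; (3) refinement over an adaptive
window that widens where curvature is low; (4) triangular-weighted
smoothing of the curvature profile, window fraction ``beta``.

Sign convention
---------------
Signed curvature is positive where the contour turns *clockwise* in math
(y-up) coordinates.  This equals the z-component of the cross product
evaluated in image coordinates (y down), and it is the convention under
which the spine tips of a normalized branch contour (spines toward +Y,
traversal left to right) are curvature maxima and the cavities between
them are minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contour_io import NormalizedContour
from .errors import DegenerateGeometryError, ParameterError

__all__ = [
    "SmoothingParams",
    "SmoothedContour",
    "CurvatureProfile",
    "smooth_contour",
    "circumcircle_curvature",
    "adaptive_half_width",
    "raw_curvature_profile",
    "refine_curvature",
    "smooth_curvature_profile",
    "curvature_profile",
    "profile_frame",
]


def round_half_away(x: float) -> int:
    """Round a positive real to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SmoothingParams:
    """Tunable constants of the measurement pipeline.

    alpha, beta
        Smoothing window fractions (of the raw point count n) for the
        contour and the curvature profile.  Defaults are the calibrated
        values used for all production detections.
    refine_threshold
        Curvature (1/um) below which the refinement window widens to
        1/|k| points; at or above it the window is ``refine_cap`` points.
    exclusion_fraction
        Fraction of the smoothed-curvature profile ignored at each end
        when searching for landmarks (digitization start/end is noisy).
    midline_position
        Normalized abscissa treated as the axis of symmetry when picking
        the central landmark.
    """

    alpha: float = 0.025
    beta: float = 0.055
    refine_threshold: float = 0.1
    refine_cap: int = 10
    exclusion_fraction: float = 0.20
    midline_position: float = 0.475
    prominence: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 0.2):
            raise ParameterError(f"alpha must be in (0, 0.2], got {self.alpha}")
        if not (0 < self.beta <= 0.2):
            raise ParameterError(f"beta must be in (0, 0.2], got {self.beta}")
        if not (0 <= self.exclusion_fraction < 0.5):
            raise ParameterError(
                f"exclusion_fraction must be in [0, 0.5), got {self.exclusion_fraction}"
            )
        if not (
            self.exclusion_fraction
            <= self.midline_position
            <= 1 - self.exclusion_fraction
        ):
            raise ParameterError(
                "midline_position must lie inside the admissible window "
                f"[{self.exclusion_fraction}, {1 - self.exclusion_fraction}], "
                f"got {self.midline_position}"
            )
        if self.refine_threshold <= 0 or self.refine_cap < 1:
            raise ParameterError("refine_threshold must be > 0 and refine_cap >= 1")

    def margin(self, n: int, fraction: float) -> int:
        """Points trimmed per side by a smoothing stage: floor(fraction * n)."""
        m = int(math.floor(fraction * n))
        if m < 1:
            raise ParameterError(
                f"window fraction {fraction} gives an empty window for n={n}"
            )
        return m


@dataclass(frozen=True)
class SmoothedContour:
    """Contour after rectangular coordinate smoothing.

    ``margin`` points were trimmed on each side; point j corresponds to
    raw point j + margin.
    """

    points: np.ndarray
    parent: NormalizedContour
    margin: int

    @property
    def n_raw(self) -> int:
        return self.parent.n

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CurvatureProfile:
    """Curvilinear abscissa and the three curvature arrays.

    ``s`` is the abscissa of every smoothed-contour point (length L,
    starting at 0).  ``k_raw`` and ``k_refined`` live on the interior
    points 1..L-2; ``k_smoothed`` is additionally trimmed by the beta
    margin on each side.  ``margins`` records the trims per stage so any
    curvature sample can be indexed back to its contour point.
    """

    s: np.ndarray
    k_raw: np.ndarray
    n_raw: int
    k_refined: np.ndarray | None = None
    k_smoothed: np.ndarray | None = None
    margins: dict = field(default_factory=dict)

    @property
    def beta_margin(self) -> int | None:
        return self.margins.get("beta")

    def smoothed_support_indices(self) -> np.ndarray:
        """Smoothed-contour indices carrying k_smoothed samples."""
        if self.k_smoothed is None:
            raise ValueError("k_smoothed not computed yet")
        mb = self.margins["beta"]
        return np.arange(1 + mb, 1 + mb + len(self.k_smoothed))

    def s_smoothed(self) -> np.ndarray:
        """Abscissa restricted to the k_smoothed support."""
        return self.s[self.smoothed_support_indices()]

    def s_norm(self) -> np.ndarray:
        """Abscissa of the k_smoothed support normalized to [0, 1]."""
        s = self.s_smoothed()
        return (s - s[0]) / (s[-1] - s[0])


def smooth_contour(c: NormalizedContour, params: SmoothingParams) -> SmoothedContour:
    """Rectangular (moving-average) smoothing of the contour coordinates.

    Each output point is the arithmetic mean of the 2*floor(alpha*n)+1
    input points centered on it, so the result is floor(alpha*n) points
    shorter on each side.  The divisor is the true window count, keeping
    the filter mean-preserving.
    """
    n = c.n
    m = params.margin(n, params.alpha)
    if n - 2 * m < 3:
        raise ParameterError(
            f"alpha={params.alpha} leaves {n - 2 * m} points of {n}; "
            "too much contour smoothing"
        )
    kernel = np.full(2 * m + 1, 1.0 / (2 * m + 1))
    x = np.convolve(c.points[:, 0], kernel, mode="valid")
    y = np.convolve(c.points[:, 1], kernel, mode="valid")
    return SmoothedContour(np.column_stack([x, y]), parent=c, margin=m)


def _signed_curvature(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Vectorized signed inverse circumradius for point triples (A, B, C).

    Positive for clockwise turns in math coordinates; zero when collinear.
    Raises on coincident points.
    """
    A = np.atleast_2d(A).astype(float)
    B = np.atleast_2d(B).astype(float)
    C = np.atleast_2d(C).astype(float)
    AB = B - A
    BC = C - B
    CA = A - C
    d1 = np.hypot(AB[:, 0], AB[:, 1])
    d2 = np.hypot(BC[:, 0], BC[:, 1])
    d3 = np.hypot(CA[:, 0], CA[:, 1])
    bad = (d1 == 0) | (d2 == 0) | (d3 == 0)
    if bad.any():
        raise DegenerateGeometryError(
            f"coincident points in curvature triple at offset {int(np.argmax(bad))}"
        )
    cross_math = AB[:, 0] * BC[:, 1] - AB[:, 1] * BC[:, 0]
    # clockwise-positive: negate the math-frame cross product
    return -2.0 * cross_math / (d1 * d2 * d3)


def circumcircle_curvature(M, N, P) -> float:
    """Signed curvature at N from the circumcircle of triangle (M, N, P).

    The magnitude is the inverse circumradius; the sign is positive for a
    clockwise turn (see module docstring).  Collinear points give 0;
    coincident points raise :class:`DegenerateGeometryError`.
    """
    return float(_signed_curvature(np.asarray(M), np.asarray(N), np.asarray(P))[0])


def raw_curvature_profile(sc: SmoothedContour) -> CurvatureProfile:
    """Three-point sliding-window curvature plus the curvilinear abscissa.

    k_raw[j-1] is the curvature at smoothed point j computed from its
    immediate neighbors; s accumulates Euclidean segment lengths from the
    first smoothed point.
    """
    pts = sc.points
    if len(pts) < 3:
        raise ParameterError(f"smoothed contour has {len(pts)} points, need >= 3")
    seg = np.hypot(*(pts[1:] - pts[:-1]).T)
    if (seg == 0).any():
        i = int(np.argmax(seg == 0))
        raise DegenerateGeometryError(
            f"repeated point after smoothing at index {i}"
        )
    s = np.concatenate([[0.0], np.cumsum(seg)])
    k_raw = _signed_curvature(pts[:-2], pts[1:-1], pts[2:])
    return CurvatureProfile(
        s=s,
        k_raw=k_raw,
        n_raw=sc.n_raw,
        margins={"alpha": sc.margin, "raw": 1},
    )


def adaptive_half_width(k_raw: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Unclamped refinement half-width per point: round(1/|k|) below the
    threshold, ``refine_cap`` at or above it."""
    absk = np.abs(np.asarray(k_raw, dtype=float))
    with np.errstate(divide="ignore"):
        a_flat = np.floor(1.0 / absk + 0.5)
    return np.where(absk < params.refine_threshold, a_flat, float(params.refine_cap))


def refine_curvature(
    profile: CurvatureProfile, sc: SmoothedContour, params: SmoothingParams
) -> CurvatureProfile:
    """Second curvature pass over an adaptive symmetric window.

    Where |k_raw| is below ``refine_threshold`` the window half-width is
    round(1/|k_raw|) points (flat regions are measured over a larger
    span); otherwise it is ``refine_cap`` points.  The window is clamped
    so it never leaves the contour.
    """
    pts = sc.points
    L = len(pts)
    k_raw = profile.k_raw
    j = np.arange(1, L - 1)
    a = np.minimum(adaptive_half_width(k_raw, params), np.minimum(j, L - 1 - j))
    a = np.maximum(a, 1).astype(int)
    k_refined = np.empty_like(k_raw)
    for w in np.unique(a):
        sel = a == w
        jj = j[sel]
        k_refined[sel] = _signed_curvature(pts[jj - w], pts[jj], pts[jj + w])
    return replace(profile, k_refined=k_refined)


def smooth_curvature_profile(
    profile: CurvatureProfile, params: SmoothingParams
) -> CurvatureProfile:
    """Triangular-weighted moving average of the refined curvature.

    Weights fall linearly from floor(beta*n) at the center to 0 at the
    window edges (n is the raw contour point count); the output is
    floor(beta*n) samples shorter on each side.
    """
    if profile.k_refined is None:
        raise ValueError("refine_curvature must run before smooth_curvature_profile")
    mb = params.margin(profile.n_raw, params.beta)
    k = profile.k_refined
    if 2 * mb + 1 > len(k):
        raise ParameterError(
            f"beta={params.beta} gives window {2 * mb + 1} > profile length {len(k)}"
        )
    offsets = np.arange(-mb, mb + 1)
    w = (mb - np.abs(offsets)).astype(float)  # zero at both edges
    k_smoothed = np.convolve(k, w[::-1] / w.sum(), mode="valid")
    margins = dict(profile.margins)
    margins["beta"] = mb
    return replace(profile, k_smoothed=k_smoothed, margins=margins)


def curvature_profile(
    c: NormalizedContour, params: SmoothingParams
) -> tuple[SmoothedContour, CurvatureProfile]:
    """Run all four stages and return the smoothed contour and full profile."""
    sc = smooth_contour(c, params)
    prof = raw_curvature_profile(sc)
    prof = refine_curvature(prof, sc, params)
    prof = smooth_curvature_profile(prof, params)
    return sc, prof


def profile_frame(profile: CurvatureProfile) -> pd.DataFrame:
    """Tabulate the profile (one row per smoothed-contour point) for export."""
    L = len(profile.s)
    out = pd.DataFrame(
        {
            "index": np.arange(L),
            "s_um": profile.s,
            "k_raw": np.nan,
            "k_refined": np.nan,
            "k_smoothed": np.nan,
        }
    )
    out.loc[1 : L - 2, "k_raw"] = profile.k_raw
    if profile.k_refined is not None:
        out.loc[1 : L - 2, "k_refined"] = profile.k_refined
    if profile.k_smoothed is not None:
        idx = profile.smoothed_support_indices()
        out.loc[idx, "k_smoothed"] = profile.k_smoothed
    return out
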