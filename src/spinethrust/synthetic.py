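"""Synthetic ventral-branch contours with known ground truth.

The generator emulates what the measurement pipeline consumes: an open,
hand-digitized outline of a ventral branch — two lateral spine bumps
flanking a central ridge over a gently arched baseline — sampled at
500-1000 points with optionally correlated digitization jitter.  Every
specimen carries its construction ground truth (the five landmark
positions and the exact spine thrust they imply), so detection accuracy
can be scored without any real micrographs.

The base curve is a sum of Gaussian bumps on a parabolic arch:

    y(x) = arch(x) + h_s [G(x; x1) + G(x; x2)] + h_r G(x; m) - c [G(x; c1) + G(x; c2)]

with spine bumps at x1, x2, the ridge at the span midpoint m and explicit
cavity depressions at the midpoints c1, c2 between each spine and the
ridge.  Any smooth construction with five controlled extrema would do;
what the module guarantees is the ground-truth bookkeeping, with group
effects carried by geometry (bump heights), not by labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from .contour_io import (
    NormalizedContour,
    SpecimenRecord,
    write_contour_file,
    write_manifest,
)
from .errors import GeneratorError
from .landmarks import Extremum, LandmarkSet
from .thrust import spine_thrust

__all__ = [
    "BranchShapeParams",
    "SyntheticSpecimen",
    "GroupSpec",
    "PopulationSpec",
    "PopulationDataset",
    "generate_circle",
    "generate_branch_contour",
    "spine_height_for_st",
    "branch_params_for_st",
    "generate_population",
    "default_population",
]

#: pixel scale used when synthetic datasets are written to disk
SCALE_UM_PER_PX = 0.5


@dataclass(frozen=True)
class BranchShapeParams:
    """Geometry and sampling of one synthetic branch contour.

    Heights and widths are in micrometers.  ``baseline_height`` is the
    sag of the parabolic arch at the span midpoint; ``spine_height`` /
    ``ridge_height`` are the nominal Gaussian bump amplitudes (the exact
    landmark heights, including bump cross-talk, are recovered from the
    constructed curve, not from these nominal values).  ``jitter_sd`` is
    the standard deviation of the correlated displacement applied along
    the local normal, emulating freehand pen noise.
    """

    span: float = 60.0
    baseline_height: float = 2.0
    spine_height: float = 4.0
    ridge_height: float = 2.5
    spine_positions: tuple[float, float] = (0.30, 0.70)
    bump_width: float = 3.0
    cavity_depth: float = 1.5
    n_points: int = 700
    jitter_sd: float = 0.0
    jitter_corr_points: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise GeneratorError(f"n_points must be >= 3, got {self.n_points}")
        if self.jitter_sd < 0:
            raise GeneratorError("jitter_sd must be >= 0")
        p1, p2 = self.spine_positions
        if not (0 < p1 < 0.5 < p2 < 1):
            raise GeneratorError(
                "spine_positions must straddle the midline inside (0, 1), "
                f"got {self.spine_positions}"
            )
        if self.bump_width <= 0 or self.span <= 0:
            raise GeneratorError("span and bump_width must be positive")


@dataclass(frozen=True)
class SyntheticSpecimen:
    """A generated contour plus its construction ground truth."""

    contour: NormalizedContour
    true_landmarks: LandmarkSet
    true_ST: float
    params: BranchShapeParams


def generate_circle(
    radius: float, arc_fraction: float = 0.5, n_points: int = 800
) -> NormalizedContour:
    """Evenly sampled open circular arc with analytic curvature 1/radius.

    The arc is a dome traversed left to right, so its signed curvature is
    +1/radius everywhere under the clockwise-positive convention.  The
    subtended angle is ``2 * pi * arc_fraction``.
    """
    if radius <= 0:
        raise GeneratorError(f"radius must be positive, got {radius}")
    if not (0 < arc_fraction <= 1):
        raise GeneratorError(f"arc_fraction must be in (0, 1], got {arc_fraction}")
    half = math.pi * arc_fraction
    theta = np.linspace(math.pi / 2 + half, math.pi / 2 - half, n_points)
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return NormalizedContour(pts, provenance={"synthetic": "circle", "radius": radius})


def _curve_functions(
    p: BranchShapeParams,
) -> tuple[Callable, Callable, Callable]:
    """Analytic y(x), y'(x), y''(x) of the noise-free construction."""
    W = p.span
    w2 = p.bump_width**2
    x1, x2 = p.spine_positions[0] * W, p.spine_positions[1] * W
    centers = np.array([x1, x2, 0.5 * W, (x1 + 0.5 * W) / 2, (x2 + 0.5 * W) / 2])
    amps = np.array(
        [p.spine_height, p.spine_height, p.ridge_height, -p.cavity_depth, -p.cavity_depth]
    )
    sag = p.baseline_height

    def y(x):
        x = np.asarray(x, dtype=float)
        u = x[..., None] - centers
        g = np.exp(-(u**2) / (2 * w2))
        return 4 * sag * (x / W) * (1 - x / W) + (amps * g).sum(axis=-1)

    def yp(x):
        x = np.asarray(x, dtype=float)
        u = x[..., None] - centers
        g = np.exp(-(u**2) / (2 * w2))
        return 4 * sag / W * (1 - 2 * x / W) + (amps * g * (-u / w2)).sum(axis=-1)

    def ypp(x):
        x = np.asarray(x, dtype=float)
        u = x[..., None] - centers
        g = np.exp(-(u**2) / (2 * w2))
        return -8 * sag / W**2 + (amps * g * (u**2 / w2 - 1) / w2).sum(axis=-1)

    return y, yp, ypp


def _true_landmarks(p: BranchShapeParams) -> LandmarkSet:
    """Locate the five y-extrema of the analytic curve exactly.

    The tips and ridge are y-maxima (curvature maxima under the pipeline
    sign convention), the cavities y-minima.  Anything other than the
    alternation max/min/max/min/max means the requested bump geometry
    merged or split features.
    """
    y, yp, ypp = _curve_functions(p)
    W = p.span
    grid = np.linspace(0.0, W, 2001)
    d = yp(grid)
    sign = np.sign(d)
    roots: list[float] = []
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(brentq(lambda x: float(yp(x)), grid[i], grid[i + 1], xtol=1e-10))
    roots.extend(grid[1:-1][d[1:-1] == 0.0])
    roots = sorted(roots)
    kinds = ["maximum" if ypp(r) < 0 else "minimum" for r in roots]
    if len(roots) != 5 or kinds != ["maximum", "minimum", "maximum", "minimum", "maximum"]:
        raise GeneratorError(
            f"construction yields {len(roots)} extrema ({kinds}); "
            "use wider spacing or taller/shallower bumps"
        )
    lms = []
    for i, (r, kind) in enumerate(zip(roots, kinds)):
        slope = float(yp(r))
        curv = -float(ypp(r)) / (1 + slope**2) ** 1.5  # clockwise-positive
        lms.append(
            Extremum(
                index=i,
                s_norm=float(r / W),
                value=curv,
                kind=kind,
                x=float(r),
                y=float(y(r)),
            )
        )
    return LandmarkSet(*lms)


def true_spine_thrust(p: BranchShapeParams) -> float:
    """Exact ST implied by the construction's ground-truth landmarks."""
    return spine_thrust(_true_landmarks(p)).ST


def generate_branch_contour(p: BranchShapeParams) -> SyntheticSpecimen:
    """Sample the construction into an open contour with optional jitter.

    Points are spaced uniformly in arc length.  Jitter is white Gaussian
    noise low-pass filtered along the contour (correlation length
    ``jitter_corr_points`` samples), rescaled to ``jitter_sd`` and applied
    along the local normal — a freehand pen wobbles smoothly, it does not
    flicker per point.  Identical parameters (including seed) give an
    identical contour.
    """
    lm = _true_landmarks(p)
    y, yp, _ = _curve_functions(p)
    dense_x = np.linspace(0.0, p.span, max(4000, 6 * p.n_points))
    dense_y = y(dense_x)
    seg = np.hypot(np.diff(dense_x), np.diff(dense_y))
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    s_target = np.linspace(0.0, s_dense[-1], p.n_points)
    xs = np.interp(s_target, s_dense, dense_x)
    ys = y(xs)
    pts = np.column_stack([xs, ys])
    if p.jitter_sd > 0:
        rng = np.random.default_rng(p.seed)
        noise = gaussian_filter1d(
            rng.standard_normal(p.n_points), sigma=p.jitter_corr_points, mode="reflect"
        )
        sd = noise.std()
        if sd > 0:
            noise *= p.jitter_sd / sd
        slope = yp(xs)
        norm = np.sqrt(1 + slope**2)
        normals = np.column_stack([-slope / norm, 1 / norm])
        pts = pts + noise[:, None] * normals
    contour = NormalizedContour(pts, provenance={"synthetic": "branch", "seed": p.seed})
    return SyntheticSpecimen(
        contour=contour,
        true_landmarks=lm,
        true_ST=spine_thrust(lm).ST,
        params=p,
    )


def spine_height_for_st(
    target_st: float, base: BranchShapeParams | None = None
) -> float:
    """Solve for the spine bump height giving an exact ground-truth ST.

    Bump cross-talk and the arch make the nominal heights differ from the
    realized landmark heights; the mapping spine_height -> true ST is
    smooth and increasing, so a root find recovers the exact height.
    """
    if base is None:
        base = BranchShapeParams()

    def f(h: float) -> float:
        return true_spine_thrust(replace(base, spine_height=h)) - target_st

    lo = None
    for cand in (0.3, 0.5, 0.8, 1.2, 2.0):
        try:
            flo = f(cand)
        except GeneratorError:
            continue
        lo, flo_val = cand, flo
        break
    if lo is None:
        raise GeneratorError("no valid lower bracket for spine height")
    if flo_val > 0:
        raise GeneratorError(
            f"target ST {target_st} um is below the construction's range "
            f"(needs spine height < {lo} um, where extrema merge)"
        )
    hi = max(lo + 1.0, target_st + base.ridge_height + base.baseline_height + 5.0)
    while f(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise GeneratorError(f"target ST {target_st} um out of reach")
    return float(brentq(f, lo, hi, xtol=1e-8))


def branch_params_for_st(
    target_st: float, base: BranchShapeParams | None = None
) -> BranchShapeParams:
    """Shape parameters whose ground-truth ST equals ``target_st`` exactly.

    Spiny targets are reached by raising the spine bumps.  Very rounded
    (strongly negative) targets fall below the range where spine bumps
    remain distinct extrema; those are reached the way rounded branches
    are actually shaped — small fixed spines over a taller central ridge
    — by solving for the ridge height instead.
    """
    if base is None:
        base = BranchShapeParams()
    try:
        return replace(base, spine_height=spine_height_for_st(target_st, base))
    except GeneratorError:
        pass
    small = replace(base, spine_height=1.0)

    def f(r: float) -> float:
        return true_spine_thrust(replace(small, ridge_height=r)) - target_st

    lo = base.ridge_height
    if f(lo) < 0:
        raise GeneratorError(f"target ST {target_st} um out of the construction's range")
    hi = lo + abs(target_st) + 5.0
    while f(hi) > 0:
        hi *= 2
        if hi > 1e3:
            raise GeneratorError(f"target ST {target_st} um out of reach")
    return replace(small, ridge_height=float(brentq(f, lo, hi, xtol=1e-8)))


@dataclass(frozen=True)
class GroupSpec:
    """One simulated population group and its mean spine thrust."""

    species: str
    temperature_C: float
    n: int
    mean_st: float
    strain: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeneratorError("group size must be >= 1")
        if not self.strain:
            object.__setattr__(self, "strain", f"sim-{self.species}")


@dataclass(frozen=True)
class PopulationSpec:
    """Design of a simulated multi-group dataset.

    Group mean shifts are realized geometrically: each individual's
    target ST is drawn around its group mean and its spine bump height is
    solved to match that target exactly before jitter is applied.
    """

    groups: tuple[GroupSpec, ...]
    base_params: BranchShapeParams = field(default_factory=BranchShapeParams)
    between_individual_sd: float = 1.5
    collection_year: int = 2016
    seed: int = 0


@dataclass(frozen=True)
class PopulationDataset:
    """In-memory simulated dataset, writable in the pipeline's file formats."""

    records: tuple[SpecimenRecord, ...]
    specimens: dict  # specimen_id -> SyntheticSpecimen
    truth: pd.DataFrame  # specimen_id, species, temperature_C, true_ST

    def write(self, out_dir: str | Path) -> Path:
        """Write manifest + per-specimen pixel contour CSVs + truth sidecar."""
        out_dir = Path(out_dir)
        (out_dir / "contours").mkdir(parents=True, exist_ok=True)
        write_manifest(out_dir / "manifest.csv", self.records)
        for rec in self.records:
            sp = self.specimens[rec.specimen_id]
            pts = sp.contour.points
            px = np.column_stack([pts[:, 0], -pts[:, 1]]) / rec.scale_um_per_px
            write_contour_file(out_dir / rec.source_file, px)
        self.truth.to_csv(out_dir / "truth.csv", index=False)
        return out_dir


def default_population(
    n_per_group: int = 30, seed: int = 0
) -> PopulationSpec:
    """The two-species, two-temperature design.

    The santomea-like species is plastic: its 18 C group mean is 3.4 um
    above its 25 C group mean.  The yakuba-like species is spiny (about
    9 um above santomea at 25 C) and insensitive to temperature.
    """
    return PopulationSpec(
        groups=(
            GroupSpec("santomea", 25.0, n_per_group, 0.0),
            GroupSpec("santomea", 18.0, n_per_group, 3.4),
            GroupSpec("yakuba", 25.0, n_per_group, 9.0),
            GroupSpec("yakuba", 18.0, n_per_group, 9.0),
        ),
        seed=seed,
    )


def generate_population(spec: PopulationSpec) -> PopulationDataset:
    """Draw individuals for every group and build their contours.

    All randomness flows from ``spec.seed``; individual target STs are
    Gaussian around the group mean with ``between_individual_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SpecimenRecord] = []
    specimens: dict[str, SyntheticSpecimen] = {}
    truth_rows = []
    for g in spec.groups:
        for i in range(g.n):
            sid = f"{g.species}-{g.temperature_C:g}C-{i:03d}"
            target = g.mean_st + rng.normal(0.0, spec.between_individual_sd)
            p = replace(
                branch_params_for_st(target, spec.base_params),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sp = generate_branch_contour(p)
            specimens[sid] = sp
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=g.species,
                    strain=g.strain,
                    temperature_C=g.temperature_C,
                    collection_year=spec.collection_year,
                    scale_um_per_px=SCALE_UM_PER_PX,
                    source_file=f"contours/{sid}.csv",
                )
            )
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "species": g.species,
                    "strain": g.strain,
                    "temperature_C": g.temperature_C,
                    "true_ST": sp.true_ST,
                }
            )
    return PopulationDataset(
        records=tuple(records),
        specimens=specimens,
        truth=pd.DataFrame(truth_rows),
    )
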