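"""Curvature-extremum detection and the five-landmark assignment rules.

The five landmarks are local-geometry (Bookstein type 2) landmarks on the
smoothed curvature profile: the two lateral spine tips and the central
ridge are curvature maxima (landmarks 1, 3, 5), the two cavities between
them are minima (landmarks 2, 4).  Specimens whose profile does not
display all five roles are excluded, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .curvature import CurvatureProfile, SmoothedContour, SmoothingParams

__all__ = [
    "Extremum",
    "LandmarkSet",
    "DetectionOutcome",
    "find_extrema",
    "assign_landmarks",
    "detect_landmarks",
    "estimate_midline",
]

Kind = Literal["maximum", "minimum"]


@dataclass(frozen=True)
class Extremum:
    """A strict local extremum of the smoothed curvature profile.

    ``index`` is the position within k_smoothed; ``s_norm`` the abscissa
    normalized to [0, 1] over the smoothed-curvature support; ``value``
    the curvature there.  ``x``/``y`` are contour coordinates in
    micrometers when known (they are not needed for role assignment).
    """

    index: int
    s_norm: float
    value: float
    kind: Kind
    x: float | None = None
    y: float | None = None

    @property
    def xy(self) -> np.ndarray:
        if self.x is None or self.y is None:
            raise ValueError("extremum carries no contour coordinates")
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class LandmarkSet:
    """The five assigned landmarks, ordered along the contour."""

    L1: Extremum
    L2: Extremum
    L3: Extremum
    L4: Extremum
    L5: Extremum

    def __iter__(self):
        return iter((self.L1, self.L2, self.L3, self.L4, self.L5))

    def coordinates(self) -> np.ndarray:
        """(5, 2) array of landmark coordinates in micrometers."""
        return np.array([lm.xy for lm in self])


@dataclass(frozen=True)
class DetectionOutcome:
    """Either a valid LandmarkSet or an enumerated exclusion reason."""

    status: Literal["valid", "excluded"]
    landmarks: LandmarkSet | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        assert (self.status == "valid") == (self.landmarks is not None)


def find_extrema(
    profile: CurvatureProfile, params: SmoothingParams
) -> list[Extremum]:
    """Strict local extrema of k_smoothed inside the admissible window.

    Extrema are sign changes of the first difference; a plateau reports
    its first index.  The first and last ``exclusion_fraction`` of the
    normalized abscissa are ignored (digitization start/end noise).
    """
    if profile.k_smoothed is None:
        raise ValueError("profile has no smoothed curvature")
    k = profile.k_smoothed
    s_norm = profile.s_norm()
    d = np.sign(np.diff(k))
    nz = np.flatnonzero(d)
    out: list[Extremum] = []
    lo = params.exclusion_fraction
    hi = 1.0 - params.exclusion_fraction
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] == d[b]:
            continue
        kind: Kind = "maximum" if d[a] > 0 else "minimum"
        i = int(a) + 1  # first index of the extremum (or of its plateau)
        if lo <= s_norm[i] <= hi:
            out.append(Extremum(index=i, s_norm=float(s_norm[i]), value=float(k[i]), kind=kind))
    return out


def _closest(cands: Sequence[Extremum], target: float) -> Extremum:
    """Extremum with s_norm nearest target; ties toward the smaller index."""
    return min(cands, key=lambda e: (abs(e.s_norm - target), e.index))


def _lowest(cands: Sequence[Extremum]) -> Extremum:
    """Minimum with the lowest curvature value; ties toward the smaller index."""
    return min(cands, key=lambda e: (e.value, e.index))


def assign_landmarks(
    extrema: Sequence[Extremum], params: SmoothingParams
) -> DetectionOutcome:
    """Assign roles 1..5 to detected extrema, or exclude the specimen.

    Rules: landmark 3 is the maximum closest to the midline position;
    landmark 2 the lowest minimum left of 3 and landmark 1 the maximum
    closest to (and left of) 2; symmetrically landmark 4 is the lowest
    minimum right of 3 and landmark 5 the maximum closest to (and right
    of) 4.  If more than one maximum then lies strictly between 2 and 4,
    landmark 3 is reassigned to the highest of them.  Any missing role
    excludes the specimen with a reason naming the role.
    """
    if params.prominence > 0:
        extrema = [e for e in extrema if abs(e.value) >= params.prominence]
    maxima = [e for e in extrema if e.kind == "maximum"]
    minima = [e for e in extrema if e.kind == "minimum"]
    if not maxima:
        return DetectionOutcome("excluded", reason="missing-L3")
    L3 = _closest(maxima, params.midline_position)

    left_min = [e for e in minima if e.index < L3.index]
    if not left_min:
        return DetectionOutcome("excluded", reason="missing-L2")
    L2 = _lowest(left_min)

    left_max = [e for e in maxima if e.index < L2.index]
    if not left_max:
        return DetectionOutcome("excluded", reason="missing-L1")
    L1 = _closest(left_max, L2.s_norm)

    right_min = [e for e in minima if e.index > L3.index]
    if not right_min:
        return DetectionOutcome("excluded", reason="missing-L4")
    L4 = _lowest(right_min)

    right_max = [e for e in maxima if e.index > L4.index]
    if not right_max:
        return DetectionOutcome("excluded", reason="missing-L5")
    L5 = _closest(right_max, L4.s_norm)

    # central-landmark resampling: if several maxima lie strictly between
    # the two cavities, take the highest one (ties toward smaller index)
    between = [e for e in maxima if L2.index < e.index < L4.index]
    if len(between) > 1:
        L3 = min(between, key=lambda e: (-e.value, e.index))

    lms = (L1, L2, L3, L4, L5)
    idx = [e.index for e in lms]
    if any(b <= a for a, b in zip(idx[:-1], idx[1:])):
        return DetectionOutcome("excluded", reason="landmark-order")
    return DetectionOutcome("valid", landmarks=LandmarkSet(*lms))


def _attach_coordinates(
    lm: LandmarkSet, sc: SmoothedContour, profile: CurvatureProfile
) -> LandmarkSet:
    """Fill each landmark's (x, y) from the smoothed contour."""
    support = profile.smoothed_support_indices()
    filled = []
    for e in lm:
        p = sc.points[support[e.index]]
        filled.append(replace(e, x=float(p[0]), y=float(p[1])))
    return LandmarkSet(*filled)


def detect_landmarks(
    sc: SmoothedContour, profile: CurvatureProfile, params: SmoothingParams
) -> DetectionOutcome:
    """find_extrema + assign_landmarks, with coordinates attached."""
    outcome = assign_landmarks(find_extrema(profile, params), params)
    if outcome.status != "valid":
        return outcome
    return DetectionOutcome(
        "valid", landmarks=_attach_coordinates(outcome.landmarks, sc, profile)
    )


def estimate_midline(profiles: Sequence[CurvatureProfile]) -> float:
    """Dataset-level midline estimate (extension, not part of the core method).

    Returns the mean normalized abscissa of the global maximum of each
    smoothed curvature profile.  Useful when re-calibrating the midline
    constant for a new structure; the default 0.475 reflects the slight
    left-right asymmetry of freehand digitization.
    """
    pos = []
    for p in profiles:
        k = p.k_smoothed
        if k is None or len(k) == 0:
            continue
        pos.append(p.s_norm()[int(np.argmax(k))])
    if not pos:
        raise ValueError("no usable profiles")
    return float(np.mean(pos))
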