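"""Per-specimen composition of the measurement stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .contour_io import NormalizedContour
from .curvature import SmoothingParams, curvature_profile
from .errors import DegenerateGeometryError, ParameterError
from .landmarks import DetectionOutcome, LandmarkSet, detect_landmarks
from .thrust import ThrustMeasure, spine_thrust

__all__ = ["MeasurementOutcome", "measure_contour"]


@dataclass(frozen=True)
class MeasurementOutcome:
    """Result of running one contour through the full pipeline."""

    status: Literal["valid", "excluded"]
    thrust: ThrustMeasure | None = None
    landmarks: LandmarkSet | None = None
    reason: str | None = None


def measure_contour(
    c: NormalizedContour, params: SmoothingParams
) -> MeasurementOutcome:
    """Smooth, compute curvature, detect landmarks and measure spine thrust.

    Detection failures (a missing landmark role, a degenerate frame, a
    smoothing window that does not fit the contour) yield an excluded
    outcome with a reason rather than an exception, so batch runs account
    for every specimen.
    """
    try:
        sc, profile = curvature_profile(c, params)
    except (ParameterError, DegenerateGeometryError) as exc:
        return MeasurementOutcome("excluded", reason=f"pipeline-error: {exc}")
    outcome: DetectionOutcome = detect_landmarks(sc, profile, params)
    if outcome.status != "valid":
        return MeasurementOutcome("excluded", reason=outcome.reason)
    try:
        tm = spine_thrust(outcome.landmarks)
    except DegenerateGeometryError as exc:
        return MeasurementOutcome("excluded", reason=f"degenerate-frame: {exc}")
    return MeasurementOutcome("valid", thrust=tm, landmarks=outcome.landmarks)
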