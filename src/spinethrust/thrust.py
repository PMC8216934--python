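"""Spine thrust: the form statistic computed in the landmark-2/4 frame.

Spine thrust (ST) measures how far the two lateral spine tips rise above
the central ridge, along the axis perpendicular to the line through the
two cavity landmarks:

    ST = (Y_L1 + Y_L5) / 2 - Y_L3

where Y is the coordinate in the orthonormal frame whose X axis runs from
landmark 2 to landmark 4 and whose Y axis is X rotated +90 degrees
(counterclockwise).  Spiny forms give ST > 0; rounded forms give ST near
zero or negative.  ST is invariant under rigid motion and scales linearly
with size (form, not pure shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .landmarks import LandmarkSet

__all__ = ["BranchFrame", "ThrustMeasure", "spine_thrust"]


@dataclass(frozen=True)
class BranchFrame:
    """Right-handed orthonormal frame anchored at landmark 2."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray

    @classmethod
    def from_cavities(cls, l2: np.ndarray, l4: np.ndarray) -> "BranchFrame":
        l2 = np.asarray(l2, dtype=float)
        l4 = np.asarray(l4, dtype=float)
        d = l4 - l2
        norm = float(np.hypot(*d))
        if norm == 0.0:
            raise DegenerateGeometryError("landmarks 2 and 4 coincide; no frame axis")
        x = d / norm
        y = np.array([-x[1], x[0]])  # +90 deg counterclockwise
        return cls(origin=l2, x_axis=x, y_axis=y)

    def project_y(self, p: np.ndarray) -> float:
        return float((np.asarray(p, dtype=float) - self.origin) @ self.y_axis)


@dataclass(frozen=True)
class ThrustMeasure:
    """ST in micrometers plus the three frame-projected heights."""

    ST: float
    Y_L1: float
    Y_L3: float
    Y_L5: float


def spine_thrust(lm: LandmarkSet) -> ThrustMeasure:
    """Compute spine thrust from a valid landmark set (micrometers)."""
    frame = BranchFrame.from_cavities(lm.L2.xy, lm.L4.xy)
    y1 = frame.project_y(lm.L1.xy)
    y3 = frame.project_y(lm.L3.xy)
    y5 = frame.project_y(lm.L5.xy)
    return ThrustMeasure(ST=(y1 + y5) / 2.0 - y3, Y_L1=y1, Y_L3=y3, Y_L5=y5)
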