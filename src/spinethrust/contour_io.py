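"""Reading, validating and writing contours, manifests and measurement tables.

A contour file is a plain CSV with two numeric columns (x, y) in pixel
coordinates, one digitized specimen per file, with an optional ``x,y``
header.  A manifest is a CSV with one row per specimen carrying metadata
and the pixel-to-micrometer scale.  Measurement tables are CSV files whose
floating-point cells are written with ``repr`` so that a write-then-read
round trip is bit exact.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContourParseError,
    MalformedContourError,
    SchemaError,
    UniquenessError,
)

MANIFEST_COLUMNS = (
    "specimen_id",
    "species",
    "strain",
    "temperature_C",
    "collection_year",
    "scale_um_per_px",
    "source_file",
)


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one digitized specimen."""

    specimen_id: str
    species: str
    strain: str
    temperature_C: float
    collection_year: int
    scale_um_per_px: float
    source_file: str

    def __post_init__(self) -> None:
        if not self.scale_um_per_px > 0:
            raise SchemaError(
                f"specimen {self.specimen_id!r}: scale_um_per_px must be > 0, "
                f"got {self.scale_um_per_px}"
            )


@dataclass(frozen=True)
class RawContour:
    """Ordered open polyline of hand-digitized points, pixel units.

    The contour is the point series p_1 .. p_n drawn in a single freehand
    stroke along the structure's outline; endpoints are not joined and are
    not themselves meaningful.
    """

    points: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise MalformedContourError(f"expected (n, 2) points, got {pts.shape}")
        if len(pts) < 3:
            raise MalformedContourError(
                f"a contour needs at least 3 points, got {len(pts)}"
            )
        same = np.all(pts[1:] == pts[:-1], axis=1)
        if same.any():
            i = int(np.argmax(same))
            raise MalformedContourError(
                f"consecutive identical points at rows {i} and {i + 1}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class NormalizedContour:
    """Contour in micrometers, math orientation, left-to-right traversal.

    ``provenance`` stores the transform applied to the source pixels
    (scale, y flip, whether the traversal was reversed) so normalization
    is invertible.
    """

    points: np.ndarray  # (n, 2) float, micrometers
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    @property
    def n(self) -> int:
        return len(self.points)


def read_contour_file(path: str | Path) -> RawContour:
    """Read a two-column x,y CSV into a :class:`RawContour`.

    A single non-numeric first row is accepted as a header; any other
    non-numeric row raises :class:`ContourParseError` naming the row.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            if len(row) != 2:
                raise ContourParseError(
                    f"{path.name}: row {lineno}: expected 2 columns, got {len(row)}"
                )
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise ContourParseError(
                    f"{path.name}: row {lineno}: non-numeric value in {row!r}"
                ) from None
    if len(rows) < 3:
        raise MalformedContourError(
            f"{path.name}: contour has {len(rows)} points, need at least 3"
        )
    return RawContour(np.array(rows, dtype=float))


def write_contour_file(path: str | Path, points: np.ndarray, header: bool = True) -> Path:
    """Write pixel points as a two-column CSV (inverse of read_contour_file)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(["x", "y"])
        for x, y in np.asarray(points, dtype=float):
            w.writerow([repr(float(x)), repr(float(y))])
    return path


def normalize_contour(
    c: RawContour, scale_um_per_px: float | None = None
) -> NormalizedContour:
    """Convert pixels to micrometers and fix orientation.

    Image y (down) is flipped to math y (up) so the spines of a correctly
    digitized branch point toward +Y, and traversal is reversed if needed
    so the first point is not to the right of the last.  The refinement
    threshold downstream is in inverse micrometers, so the physical scale
    matters; a missing scale falls back to 1.0 with a warning.
    """
    if scale_um_per_px is None:
        warnings.warn(
            "no pixel-to-micrometer scale supplied; assuming 1.0 "
            "(curvature thresholds are scale dependent)",
            stacklevel=2,
        )
        scale_um_per_px = 1.0
    if not scale_um_per_px > 0:
        raise SchemaError(f"scale_um_per_px must be > 0, got {scale_um_per_px}")
    pts = c.points * float(scale_um_per_px)
    pts = np.column_stack([pts[:, 0], -pts[:, 1]])
    reversed_ = bool(pts[0, 0] > pts[-1, 0])
    if reversed_:
        pts = pts[::-1]
    return NormalizedContour(
        pts,
        provenance={
            "scale_um_per_px": float(scale_um_per_px),
            "y_flipped": True,
            "traversal_reversed": reversed_,
        },
    )


def denormalize_contour(nc: NormalizedContour) -> np.ndarray:
    """Invert :func:`normalize_contour` back to pixel coordinates."""
    pts = nc.points
    if nc.provenance.get("traversal_reversed", False):
        pts = pts[::-1]
    pts = np.column_stack([pts[:, 0], -pts[:, 1]])
    return pts / nc.provenance.get("scale_um_per_px", 1.0)


def load_manifest(path: str | Path) -> list[SpecimenRecord]:
    """Load a manifest CSV into validated :class:`SpecimenRecord` rows."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing manifest column(s): {', '.join(missing)}")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise UniquenessError(
            f"{path.name}: duplicate specimen_id(s): {', '.join(sorted(set(dup)))}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                strain=str(row["strain"]),
                temperature_C=float(row["temperature_C"]),
                collection_year=int(row["collection_year"]),
                scale_um_per_px=float(row["scale_um_per_px"]),
                source_file=str(row["source_file"]),
            )
        )
    return records


def write_manifest(path: str | Path, records: Sequence[SpecimenRecord]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.specimen_id,
                    r.species,
                    r.strain,
                    repr(float(r.temperature_C)),
                    r.collection_year,
                    repr(float(r.scale_um_per_px)),
                    r.source_file,
                ]
            )
    return path


#: column order of the measurements table
MEASUREMENT_COLUMNS = (
    "specimen_id",
    "species",
    "strain",
    "temperature_C",
    "collection_year",
    "status",
    "exclusion_reason",
    "ST_um",
    "Y_L1_um",
    "Y_L3_um",
    "Y_L5_um",
    "L1_x_um",
    "L1_y_um",
    "L2_x_um",
    "L2_y_um",
    "L3_x_um",
    "L3_y_um",
    "L4_x_um",
    "L4_y_um",
    "L5_x_um",
    "L5_y_um",
)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_measurements(path: str | Path, rows: Iterable[Mapping]) -> Path:
    """Write one row per specimen: measured values or an exclusion reason.

    Floats are serialized with ``repr`` so reading the file back restores
    them bit-exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MEASUREMENT_COLUMNS)
        for row in rows:
            w.writerow([_fmt(row.get(c)) for c in MEASUREMENT_COLUMNS])
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"specimen_id": str})


def write_tps(path: str | Path, landmark_sets: Mapping[str, np.ndarray]) -> Path:
    """Export landmarks as TPS ``LM=5`` blocks (micrometer coordinates)."""
    path = Path(path)
    with open(path, "w") as fh:
        for sid, coords in landmark_sets.items():
            coords = np.asarray(coords, dtype=float)
            fh.write(f"LM={len(coords)}\n")
            for x, y in coords:
                fh.write(f"{repr(float(x))} {repr(float(y))}\n")
            fh.write(f"ID={sid}\n")
    return path


def read_tps(path: str | Path) -> dict[str, np.ndarray]:
    """Read TPS landmark blocks back into {specimen_id: (k, 2) array}."""
    out: dict[str, np.ndarray] = {}
    coords: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.upper().startswith("LM="):
                expect = int(line.split("=", 1)[1])
                coords = []
            elif line.upper().startswith("ID="):
                sid = line.split("=", 1)[1]
                if len(coords) != expect:
                    raise ContourParseError(
                        f"TPS block {sid!r}: expected {expect} landmarks, got {len(coords)}"
                    )
                out[sid] = np.array(coords, dtype=float)
            else:
                parts = line.split()
                coords.append([float(parts[0]), float(parts[1])])
    return out
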