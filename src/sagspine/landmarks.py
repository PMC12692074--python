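"""Landmark and measurement data model for lateral lumbar radiographs.

A digitized subject is a set of 18 named x-y points (mm) on a standing
lateral lumbar film: the posterior vertebral body corners from the
posterior-inferior corner of T12 down to the posterior-inferior corner of
S1, the anterior-inferior corner of T12, the anterior-superior corner of
S1, the superior aspect of each femoral head and the pubic symphysis.

Coordinate frame: x positive anterior, y positive superior, origin
arbitrary, units mm.  Relative (intersegmental) angles are frame
invariant; gravity-referenced angles assume the y-axis is the plumb
vertical of the upright radiograph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Point",
    "TangentLine",
    "LandmarkSet",
    "MeasurementRecord",
    "CANONICAL_LANDMARKS",
    "POSTERIOR_ARC",
    "MEASUREMENT_COLUMNS",
    "GROUPS",
    "LandmarkFormatError",
    "read_landmarks",
    "write_measurements",
    "read_measurements",
]


class LandmarkFormatError(ValueError):
    """Raised for malformed landmark CSV content."""


class Point(NamedTuple):
    """A digitized x-y point in mm (x anterior-positive, y superior-positive)."""

    x: float
    y: float

    def __add__(self, other):  # type: ignore[override]
        return Point(self.x + other[0], self.y + other[1])

    def __sub__(self, other):
        return Point(self.x - other[0], self.y - other[1])

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class TangentLine(NamedTuple):
    """A line through ``anchor`` with unit ``direction`` oriented cranially."""

    anchor: Point
    direction: Point


#: The 13 posterior body corners in craniocaudal order; these define the
#: lordotic arc modeled by the ellipse fit.
POSTERIOR_ARC: tuple[str, ...] = (
    "T12_pi",
    "L1_ps", "L1_pi",
    "L2_ps", "L2_pi",
    "L3_ps", "L3_pi",
    "L4_ps", "L4_pi",
    "L5_ps", "L5_pi",
    "S1_ps", "S1_pi",
)

#: Exactly the 18 canonical landmark names of a complete subject.
CANONICAL_LANDMARKS: tuple[str, ...] = POSTERIOR_ARC + (
    "T12_ai", "S1_as", "FEM_L", "FEM_R", "PUBIS",
)

GROUPS = ("normal", "albp", "unknown")


@dataclass
class LandmarkSet:
    """The named digitized points of one subject.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        ``"normal"``, ``"albp"`` or ``"unknown"``.
    points : mapping of landmark name to :class:`Point`
        Keys must come from :data:`CANONICAL_LANDMARKS`.
    """

    subject_id: str
    group: str = "unknown"
    points: dict[str, Point] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        bad = set(self.points) - set(CANONICAL_LANDMARKS)
        if bad:
            raise LandmarkFormatError(
                f"subject {self.subject_id!r}: unknown landmark name(s) {sorted(bad)}"
            )
        for name, p in list(self.points.items()):
            if not isinstance(p, Point):
                p = Point(float(p[0]), float(p[1]))
                self.points[name] = p
            if not (math.isfinite(p.x) and math.isfinite(p.y)):
                raise LandmarkFormatError(
                    f"subject {self.subject_id!r}: non-finite coordinate for {name}"
                )

    @property
    def is_complete(self) -> bool:
        """True when every one of the 18 canonical landmarks is present."""
        return set(self.points) == set(CANONICAL_LANDMARKS)

    def missing(self) -> tuple[str, ...]:
        return tuple(n for n in CANONICAL_LANDMARKS if n not in self.points)

    def __getitem__(self, name: str) -> Point:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def posterior_arc_array(self) -> np.ndarray:
        """The 13 posterior corners as a (13, 2) array, craniocaudal order."""
        missing = [n for n in POSTERIOR_ARC if n not in self.points]
        if missing:
            raise KeyError(f"subject {self.subject_id!r}: missing {missing}")
        return np.array([[self.points[n].x, self.points[n].y] for n in POSTERIOR_ARC])

    def sanity_check(self) -> list[str]:
        """Soft anatomical plausibility checks (warn-level, never raising).

        Returns the list of messages (also emitted as warnings):
        posterior corner heights should decrease craniocaudally, and
        anterior points should lie anterior to their posterior partners.
        """
        msgs: list[str] = []
        ys = [self.points[n].y for n in POSTERIOR_ARC if n in self.points]
        if any(nxt >= prev for prev, nxt in zip(ys, ys[1:])):
            msgs.append("posterior corner y-coordinates are not strictly "
                        "decreasing craniocaudally")
        for ant, post in (("T12_ai", "T12_pi"), ("S1_as", "S1_ps")):
            if ant in self.points and post in self.points:
                if self.points[ant].x <= self.points[post].x:
                    msgs.append(f"{ant} is not anterior to {post}")
        for m in msgs:
            warnings.warn(f"subject {self.subject_id!r}: {m}", stacklevel=2)
        return msgs


#: Measurement CSV column order: identifier columns, then the radiographic
#: variables in the order of the study's descriptive table, then the
#: constituent pelvic angles kept for completeness.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "subject_id", "group",
    "ARA_L1L5", "ARA_T12S1", "Cobb_T12S1", "SBA", "PT_S1", "API", "PTPIA",
    "ba_ratio",
    "API_minus_ARA_T12S1", "API_minus_ARA_L1L5", "API_minus_Cobb_T12S1",
    "PT", "SS", "sacral_tilt",
)

_ANGLE_FIELDS = tuple(c for c in MEASUREMENT_COLUMNS
                      if c not in ("subject_id", "group", "ba_ratio"))


@dataclass
class MeasurementRecord:
    """All per-subject sagittal alignment measures, angles in degrees.

    Sign convention: a negative lordosis value (ARA, Cobb) indicates
    spinal extension; SBA, PT-S1 and sacral_tilt are reported as positive
    magnitudes.  ``API_minus_*`` fields are literal subtractions of the
    signed lordosis from API.  ``ba_ratio`` is dimensionless.  Missing
    (uncomputable) values are NaN.
    """

    subject_id: str
    group: str = "unknown"
    ARA_L1L5: float = math.nan
    ARA_T12S1: float = math.nan
    Cobb_T12S1: float = math.nan
    SBA: float = math.nan
    PT_S1: float = math.nan
    API: float = math.nan
    PTPIA: float = math.nan
    ba_ratio: float = math.nan
    API_minus_ARA_T12S1: float = math.nan
    API_minus_ARA_L1L5: float = math.nan
    API_minus_Cobb_T12S1: float = math.nan
    PT: float = math.nan
    SS: float = math.nan
    sacral_tilt: float = math.nan

    def as_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read a long-format landmark CSV into one :class:`LandmarkSet` per subject.

    The file must have columns ``subject_id, group, point, x_mm, y_mm``
    (UTF-8, ``.`` decimal, header mandatory), one row per landmark.
    Unknown point names and duplicate (subject, point) pairs are format
    errors.  Subjects with fewer than 18 points are parsed and returned
    but are incomplete (``LandmarkSet.is_complete`` is False); operations
    requiring the missing points will fail per-operation downstream.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "point": str})
    required = {"subject_id", "group", "point", "x_mm", "y_mm"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise LandmarkFormatError(
            f"{path}: missing required column(s) {sorted(missing_cols)}"
        )
    bad = ~df["point"].isin(CANONICAL_LANDMARKS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise LandmarkFormatError(
            f"{path}: unknown point name {df['point'].iloc[i]!r} "
            f"(subject {df['subject_id'].iloc[i]!r}, data row {i + 1})"
        )
    dup = df.duplicated(subset=["subject_id", "point"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise LandmarkFormatError(
            f"{path}: duplicate landmark {df['point'].iloc[i]!r} for "
            f"subject {df['subject_id'].iloc[i]!r} (data row {i + 1})"
        )
    out: list[LandmarkSet] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) > 1:
            raise LandmarkFormatError(
                f"{path}: subject {sid!r} has inconsistent group labels {list(groups)}"
            )
        pts = {row.point: Point(float(row.x_mm), float(row.y_mm))
               for row in sub.itertuples()}
        out.append(LandmarkSet(subject_id=str(sid), group=str(groups[0]), points=pts))
    return out


def write_landmarks(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets to the long-format CSV read by :func:`read_landmarks`."""
    rows = [
        {"subject_id": s.subject_id, "group": s.group, "point": name,
         "x_mm": round(p.x, 4), "y_mm": round(p.y, 4)}
        for s in sets
        for name, p in ((n, s.points[n]) for n in CANONICAL_LANDMARKS if n in s.points)
    ]
    pd.DataFrame(rows, columns=["subject_id", "group", "point", "x_mm", "y_mm"]).to_csv(
        path, index=False)


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write measurement records to a wide CSV, one row per subject.

    Columns follow :data:`MEASUREMENT_COLUMNS`; angles are written to
    0.1 degree, the b/a ratio to 0.001.
    """
    records = list(records)
    if not records:
        raise ValueError("no measurement records to write")
    df = pd.DataFrame([r.as_dict() for r in records], columns=MEASUREMENT_COLUMNS)
    df[list(_ANGLE_FIELDS)] = df[list(_ANGLE_FIELDS)].round(1)
    df["ba_ratio"] = df["ba_ratio"].round(3)
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a wide measurement CSV as written by :func:`write_measurements`."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df
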