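"""Radiographic angle constructions on a lateral lumbar landmark set.

Implements the posterior-tangent (absolute rotation angle) and Cobb
lordosis measures, the sacral angles, and the pelvic morphology angles
(pelvic incidence after Legaye and the posterior-tangent pelvic
incidence analog), all from the digitized corner points.

Conventions
-----------
* y is the plumb vertical of the upright film; x is anterior.
* Lordotic (extension) configurations yield negative ARA and Cobb.
* SBA, PT-S1 and sacral tilt are reported as positive magnitudes.
* Pelvic tilt PT is signed: positive when the S1 endplate midpoint lies
  posterior to the vertical through the hip axis.  On any noise-free
  pelvis API = PT + SS (Legaye identity) and PTPIA decomposes into the
  pelvic-radius-to-vertical angle plus the sacral tilt.

The T12 posterior tangent deserves a note: the 18-point scheme digitizes
only the posterior-inferior and anterior-inferior corners of T12, so its
posterior body line is not directly available.  It is constructed as the
line through T12_pi perpendicular to the T12 inferior endplate, which is
exact for a rectangular body outline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet, MeasurementRecord, Point, TangentLine

__all__ = [
    "DegenerateGeometryError",
    "IncompleteLandmarkError",
    "PelvicFrame",
    "angle_to_vertical",
    "angle_to_horizontal",
    "posterior_tangent",
    "ara",
    "cobb_t12_s1",
    "sacral_base_angle",
    "pt_s1",
    "api",
    "pelvic_tilt",
    "sacral_slope",
    "pelvic_frame",
    "ptpia",
    "measure_all",
]

_EPS = 1e-12

#: Levels with two digitized posterior corners.
_TANGENT_CORNERS = {
    "L1": ("L1_ps", "L1_pi"),
    "L2": ("L2_ps", "L2_pi"),
    "L3": ("L3_ps", "L3_pi"),
    "L4": ("L4_ps", "L4_pi"),
    "L5": ("L5_ps", "L5_pi"),
    "S1": ("S1_ps", "S1_pi"),
}


class DegenerateGeometryError(ValueError):
    """Coincident or zero-length constructions that admit no angle."""


class IncompleteLandmarkError(KeyError):
    """A required landmark is missing from the set."""


@dataclass(frozen=True)
class PelvicFrame:
    """Derived pelvic reference points: hip axis, S1 endplate midpoint, PR anchor."""

    HA: Point
    S1_mid_endplate: Point
    PR_anchor: Point


def _require(s: LandmarkSet, names: tuple[str, ...], what: str) -> None:
    missing = [n for n in names if n not in s]
    if missing:
        raise IncompleteLandmarkError(
            f"subject {s.subject_id!r}: {what} requires missing landmark(s) {missing}"
        )


def _unit(dx: float, dy: float, what: str = "direction") -> tuple[float, float]:
    n = math.hypot(dx, dy)
    if n < _EPS:
        raise DegenerateGeometryError(f"zero-length {what}")
    return dx / n, dy / n


def angle_to_vertical(line: TangentLine) -> float:
    """Signed angle (degrees) of a line to the vertical, in (-90, 90].

    Positive when the cranial end leans anterior.  Invariant to
    translation and uniform scaling of the underlying points.
    """
    dx, dy = _unit(line.direction[0], line.direction[1])
    if dy < 0 or (dy == 0 and dx < 0):  # orient cranially
        dx, dy = -dx, -dy
    ang = math.degrees(math.atan2(dx, dy))
    if ang <= -90.0:
        ang += 180.0
    return ang


def angle_to_horizontal(p1: Point, p2: Point) -> float:
    """Unsigned acute angle (degrees) of the line p1-p2 to the horizontal, in [0, 90]."""
    dx, dy = _unit(p2[0] - p1[0], p2[1] - p1[1], "segment (coincident points)")
    return math.degrees(math.atan2(abs(dy), abs(dx)))


def _signed_slope(p_post: Point, p_ant: Point) -> float:
    """Signed angle of the posterior-to-anterior endplate direction to the
    horizontal; positive when the endplate rises anteriorly."""
    dx, dy = _unit(p_ant[0] - p_post[0], p_ant[1] - p_post[1], "endplate")
    if dx < 0:
        dx, dy = -dx, -dy
    return math.degrees(math.atan2(dy, dx))


def posterior_tangent(s: LandmarkSet, level: str) -> TangentLine:
    """Posterior body tangent of a vertebral level, oriented cranially.

    For L1-L5 and S1 this is the line through the two digitized posterior
    corners.  For T12 it is the perpendicular to the inferior endplate
    through the posterior-inferior corner (see module docstring).
    """
    if level == "T12":
        _require(s, ("T12_pi", "T12_ai"), "T12 posterior tangent")
        e = (s["T12_ai"].x - s["T12_pi"].x, s["T12_ai"].y - s["T12_pi"].y)
        ex, ey = _unit(e[0], e[1], "T12 inferior endplate")
        dx, dy = -ey, ex  # perpendicular
        if dy < 0:
            dx, dy = -dx, -dy
        return TangentLine(s["T12_pi"], Point(dx, dy))
    if level not in _TANGENT_CORNERS:
        raise ValueError(f"no posterior tangent defined for level {level!r}")
    ps, pi = _TANGENT_CORNERS[level]
    _require(s, (ps, pi), f"{level} posterior tangent")
    dx, dy = _unit(s[ps].x - s[pi].x, s[ps].y - s[pi].y, f"{level} posterior wall")
    return TangentLine(s[pi], Point(dx, dy))


def ara(s: LandmarkSet, cranial: str = "L1", caudal: str = "L5") -> float:
    """Absolute rotation angle between two posterior tangents (degrees).

    ARA = phi(cranial) - phi(caudal) where phi is the signed
    angle-to-vertical of the posterior tangent.  Lordosis is negative.
    """
    return (angle_to_vertical(posterior_tangent(s, cranial))
            - angle_to_vertical(posterior_tangent(s, caudal)))


def cobb_t12_s1(s: LandmarkSet) -> float:
    """Cobb angle between the T12 inferior and S1 superior endplates (degrees).

    Signed: negative for lordosis (S1 base sloping downward anteriorly
    while the T12 inferior endplate rises anteriorly).
    """
    _require(s, ("T12_pi", "T12_ai", "S1_ps", "S1_as"), "Cobb T12-S1")
    return _signed_slope(s["S1_ps"], s["S1_as"]) - _signed_slope(s["T12_pi"], s["T12_ai"])


def sacral_base_angle(s: LandmarkSet) -> float:
    """Sacral base angle: S1 superior endplate to the horizontal (degrees, magnitude)."""
    _require(s, ("S1_ps", "S1_as"), "sacral base angle")
    return angle_to_horizontal(s["S1_ps"], s["S1_as"])


def pt_s1(s: LandmarkSet) -> float:
    """S1 posterior tangent to the vertical (degrees, magnitude)."""
    return abs(angle_to_vertical(posterior_tangent(s, "S1")))


def pelvic_frame(s: LandmarkSet) -> PelvicFrame:
    """Hip axis (femoral head midpoint), S1 endplate midpoint, and PR anchor."""
    _require(s, ("FEM_L", "FEM_R", "S1_ps", "S1_as"), "pelvic frame")
    ha = Point((s["FEM_L"].x + s["FEM_R"].x) / 2.0,
               (s["FEM_L"].y + s["FEM_R"].y) / 2.0)
    mid = Point((s["S1_ps"].x + s["S1_as"].x) / 2.0,
                (s["S1_ps"].y + s["S1_as"].y) / 2.0)
    return PelvicFrame(HA=ha, S1_mid_endplate=mid, PR_anchor=s["S1_ps"])


def api(s: LandmarkSet) -> float:
    """Angle of pelvic incidence (Legaye), degrees, unsigned.

    The angle at the S1 endplate midpoint between the perpendicular to
    the superior S1 endplate (taken caudally, into the sacrum) and the
    segment to the hip axis.  References no gravity line, hence is
    invariant under rotation of the whole landmark set.
    """
    fr = pelvic_frame(s)
    ex, ey = _unit(s["S1_as"].x - s["S1_ps"].x, s["S1_as"].y - s["S1_ps"].y,
                   "S1 endplate")
    # caudal (downward) endplate normal
    nx, ny = ey, -ex
    if ny > 0:
        nx, ny = -nx, -ny
    vx = fr.HA.x - fr.S1_mid_endplate.x
    vy = fr.HA.y - fr.S1_mid_endplate.y
    vx, vy = _unit(vx, vy, "mid-endplate to hip axis segment")
    dot = max(-1.0, min(1.0, nx * vx + ny * vy))
    return math.degrees(math.acos(dot))


def pelvic_tilt(s: LandmarkSet) -> float:
    """Pelvic tilt (degrees, signed).

    Angle at the hip axis between the vertical and the segment to the S1
    endplate midpoint; positive when the midpoint lies posterior to the
    vertical through the hip axis.
    """
    fr = pelvic_frame(s)
    vx = fr.S1_mid_endplate.x - fr.HA.x
    vy = fr.S1_mid_endplate.y - fr.HA.y
    if math.hypot(vx, vy) < _EPS:
        raise DegenerateGeometryError("hip axis coincides with the S1 endplate midpoint")
    return math.degrees(math.atan2(-vx, vy))


def sacral_slope(s: LandmarkSet) -> float:
    """Sacral slope, identical to the sacral base angle (degrees)."""
    return sacral_base_angle(s)


def ptpia(s: LandmarkSet) -> float:
    """Posterior tangent pelvic incidence analog (degrees, unsigned).

    Angle between the pelvic radius line (hip axis to the posterior-
    superior S1 corner) and the S1 posterior body tangent.  Uses internal
    lines only, hence rotation invariant.
    """
    _require(s, ("FEM_L", "FEM_R", "S1_ps", "S1_pi"), "PTPIA")
    ha = Point((s["FEM_L"].x + s["FEM_R"].x) / 2.0,
               (s["FEM_L"].y + s["FEM_R"].y) / 2.0)
    ux, uy = _unit(s["S1_ps"].x - ha.x, s["S1_ps"].y - ha.y, "pelvic radius line")
    if uy < 0:
        ux, uy = -ux, -uy
    t = posterior_tangent(s, "S1")
    tx, ty = t.direction
    if ty < 0:
        tx, ty = -tx, -ty
    dot = max(-1.0, min(1.0, ux * tx + uy * ty))
    return math.degrees(math.acos(dot))


def pr_to_vertical(s: LandmarkSet, signed: bool = False) -> float:
    """Pelvic radius line (hip axis to S1_ps) to the vertical (degrees).

    By default the magnitude is returned.  With ``signed=True`` the lean
    is positive when the PR line leans posterior going cranially (the
    standard anatomy, hip axis anterior to the sacrum) and negative when
    it leans anterior; in the signed form the exact decomposition
    PTPIA = PT-S1 + signed PR lean holds on every noise-free pelvis.
    """
    _require(s, ("FEM_L", "FEM_R", "S1_ps"), "PR line")
    ha = Point((s["FEM_L"].x + s["FEM_R"].x) / 2.0,
               (s["FEM_L"].y + s["FEM_R"].y) / 2.0)
    lean = angle_to_vertical(TangentLine(ha, Point(s["S1_ps"].x - ha.x,
                                                   s["S1_ps"].y - ha.y)))
    return -lean if signed else abs(lean)


def measure_all(s: LandmarkSet, fit_options=None, include_ellipse: bool = True
                ) -> MeasurementRecord:
    """Compute the full measurement record for one subject.

    Every variable that is computable from the available landmarks is
    populated; the rest are NaN (no exception is raised for incomplete
    sets).  The b/a ratio is delegated to the ellipse model unless
    ``include_ellipse`` is False.
    """
    rec = MeasurementRecord(subject_id=s.subject_id, group=s.group)

    def _try(fn, *a):
        try:
            return fn(*a)
        except (IncompleteLandmarkError, DegenerateGeometryError, KeyError):
            return math.nan

    rec.ARA_L1L5 = _try(ara, s, "L1", "L5")
    rec.ARA_T12S1 = _try(ara, s, "T12", "S1")
    rec.Cobb_T12S1 = _try(cobb_t12_s1, s)
    rec.SBA = _try(sacral_base_angle, s)
    rec.PT_S1 = _try(pt_s1, s)
    rec.API = _try(api, s)
    rec.PTPIA = _try(ptpia, s)
    rec.PT = _try(pelvic_tilt, s)
    rec.SS = rec.SBA
    rec.sacral_tilt = rec.PT_S1
    if include_ellipse:
        from .ellipse import EllipseFitError, LordosisEllipse, NoCurvatureError

        try:
            rec.ba_ratio = LordosisEllipse.from_landmarks(s).fit(fit_options).ba_ratio
        except (NoCurvatureError, EllipseFitError, IncompleteLandmarkError,
                KeyError, ValueError):
            rec.ba_ratio = math.nan
    # "API minus lordosis" variables subtract the lordosis magnitude;
    # with lordosis carried as a negative signed value this is a literal
    # addition (e.g. API 56.8, ARA -76.3 -> 56.8 - 76.3 = -19.5)
    rec.API_minus_ARA_T12S1 = rec.API + rec.ARA_T12S1
    rec.API_minus_ARA_L1L5 = rec.API + rec.ARA_L1L5
    rec.API_minus_Cobb_T12S1 = rec.API + rec.Cobb_T12S1
    return rec


def transform_landmarks(s: LandmarkSet, rotation_deg: float = 0.0,
                        translation: tuple[float, float] = (0.0, 0.0),
                        scale: float = 1.0) -> LandmarkSet:
    """Return a rigidly moved / uniformly scaled copy of a landmark set.

    Rotation is counterclockwise about the origin, in degrees.  Utility
    for invariance testing and film re-registration.
    """
    th = math.radians(rotation_deg)
    c, sn = math.cos(th), math.sin(th)
    pts = {
        n: Point(scale * (c * p.x - sn * p.y) + translation[0],
                 scale * (sn * p.x + c * p.y) + translation[1])
        for n, p in s.points.items()
    }
    return LandmarkSet(subject_id=s.subject_id, group=s.group, points=pts)
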