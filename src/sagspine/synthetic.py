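"""Synthetic landmark and cohort generation.

No public landmark data accompany the study conditions this package
targets, so every downstream stage is exercised against synthetic
subjects built by inverting the geometry: choose the target angles,
construct an 18-point landmark configuration that realizes them exactly,
then (optionally) add digitization noise.

A subject is parameterized by :class:`GeometryParams`.  The primary
generative parameters are the sacral base angle, the T12 inferior
endplate tilt, the S1 posterior-tangent lean, the pelvic incidence and
the elliptical arc shape (b/a, extent); the lordosis angles are emergent
through exact identities::

    Cobb T12-S1  = -(SBA + t12_tilt)
    ARA  T12-S1  = -(t12_tilt + sacral_tilt)
    PT           =  API - SBA          (Legaye identity PI = PT + SS)

Cohorts are drawn from (optionally correlated) Gaussian models of the
generative parameters via :class:`CohortSpec`; draws that are not
geometrically constructible are rejected and redrawn.  Everything is
reproducible from the spec seed.

The posterior corners are spaced along the elliptical arc by curve
length with a vertebral-wall : disc-gap pattern of 30 : 8 (posterior
body height ~30 mm, posterior disc height ~8 mm), not uniformly in
parameter angle; uniform parameter spacing on a flat ellipse would make
the cranial posterior walls unrealistically short and their tangent
angles unrealistically noise-sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ellipse import sample_arc
from .landmarks import CANONICAL_LANDMARKS, POSTERIOR_ARC, LandmarkSet, Point

__all__ = [
    "GeometryParams",
    "CohortSpec",
    "ConstructibilityError",
    "CohortSpecError",
    "VERTEBRAL_WEIGHTS",
    "spine_from_params",
    "generate_cohorts",
    "summary_cohort",
    "spearman_from_pearson",
    "nearest_psd",
]

#: Relative arc-length widths of the 12 intervals between the 13
#: posterior corners: disc gap (8 mm) alternating with vertebral wall
#: (30 mm), from the T12/L1 disc down to the S1 posterior wall.
VERTEBRAL_WEIGHTS: tuple[float, ...] = (8.0, 30.0) * 6

#: Default S1 body wedge: sacral tilt minus sacral base angle when no
#: explicit sacral tilt is requested (normal-group mean difference).
DEFAULT_S1_WEDGE = 10.9


class ConstructibilityError(ValueError):
    """The requested parameter combination admits no valid landmark geometry."""


class CohortSpecError(ValueError):
    """An infeasible cohort specification (e.g., rejection rate too high)."""


@dataclass(frozen=True)
class GeometryParams:
    """Geometric targets for one synthetic subject.

    Angles in degrees, lengths in mm.  ``sacral_orientation`` is the
    target sacral base angle; ``t12_tilt`` the T12 inferior-endplate
    tilt (rising anteriorly, i.e. opposite in sense to the sacral
    base); ``sacral_tilt`` the S1 posterior-tangent lean from vertical
    (default: sacral_orientation + 10.9, the normal-group S1 wedge);
    ``pelvic_incidence`` the target API; ``pelvic_radius`` the distance
    from the S1 endplate midpoint to the hip axis; ``scale`` the T12-S1
    posterior chord length; ``noise_sd`` the digitization noise SD per
    coordinate (0.7 mm lands the derived angle SEM near the ~2 deg
    reported for these measures).
    """

    ba: float = 0.389
    arc_extent: float = 85.0
    sacral_orientation: float = 39.4
    t12_tilt: float = 26.0
    sacral_tilt: float | None = None
    pelvic_incidence: float = 56.8
    pelvic_radius: float = 110.0
    scale: float = 210.0
    body_depth: float = 35.0
    noise_sd: float = 0.7

    def resolved_sacral_tilt(self) -> float:
        if self.sacral_tilt is not None:
            return self.sacral_tilt
        return self.sacral_orientation + DEFAULT_S1_WEDGE

    def validate(self) -> None:
        if not 0 < self.ba < 2:
            raise ConstructibilityError(f"ba {self.ba} outside (0, 2)")
        if not 10 < self.arc_extent < 180:
            raise ConstructibilityError(f"arc_extent {self.arc_extent} outside (10, 180)")
        for name in ("pelvic_radius", "scale", "body_depth"):
            if getattr(self, name) <= 0:
                raise ConstructibilityError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConstructibilityError("noise_sd must be >= 0")
        if not 0 < self.sacral_orientation < 90:
            raise ConstructibilityError(
                f"sacral_orientation {self.sacral_orientation} outside (0, 90)")
        if self.t12_tilt <= 0:
            raise ConstructibilityError(
                f"t12_tilt {self.t12_tilt} must be positive (derived as "
                "|Cobb| - SBA; the Cobb magnitude must exceed the SBA)")
        st = self.resolved_sacral_tilt()
        if not 0 < st < 90:
            raise ConstructibilityError(f"sacral_tilt {st} outside (0, 90)")
        pt = self.pelvic_incidence - self.sacral_orientation
        if not -80 < pt < 80:
            raise ConstructibilityError(
                f"pelvic tilt {pt:.1f} (API - SBA) places the hip axis "
                "above the S1 endplate")


def spine_from_params(p: GeometryParams, rng: np.random.Generator | None = None,
                      subject_id: str = "synthetic", group: str = "unknown"
                      ) -> tuple[LandmarkSet, dict[str, float]]:
    """Construct one 18-landmark subject realizing the parameter targets.

    Returns the (possibly noise-perturbed) landmark set and a truth
    record holding the noise-free target angles.  With ``noise_sd = 0``
    the measured angles reproduce the truth record exactly (to floating
    point).
    """
    p.validate()
    if p.noise_sd > 0 and rng is None:
        raise ValueError("an rng is required when noise_sd > 0")

    sba = math.radians(p.sacral_orientation)
    t12 = math.radians(p.t12_tilt)
    tilt = math.radians(p.resolved_sacral_tilt())

    # posterior corners on the elliptical arc, then rotate the arc so the
    # S1 posterior wall (chord S1_pi -> S1_ps) leans `sacral_tilt`
    # anteriorly from vertical
    arc = sample_arc(p.ba, p.arc_extent, 13, p.scale,
                     weights=np.array(VERTEBRAL_WEIGHTS, dtype=float),
                     spacing="arclength")
    wall = arc[-2] - arc[-1]  # S1_pi -> S1_ps, cranially oriented
    current = math.atan2(wall[0], wall[1])  # angle to vertical, anterior +
    delta = tilt - current  # rotate so angle-to-vertical becomes `tilt`
    c, s = math.cos(delta), math.sin(delta)
    rot = np.array([[c, s], [-s, c]])  # clockwise by delta adds delta to lean
    arc = (arc - arc[-2]) @ rot.T + np.array([250.0, 500.0])

    pts: dict[str, Point] = {
        name: Point(float(x), float(y)) for name, (x, y) in zip(POSTERIOR_ARC, arc)
    }
    s1_ps = pts["S1_ps"]
    # S1 superior endplate descends anteriorly at the sacral base angle
    pts["S1_as"] = Point(s1_ps.x + p.body_depth * math.cos(sba),
                         s1_ps.y - p.body_depth * math.sin(sba))
    t12_pi = pts["T12_pi"]
    # T12 inferior endplate rises anteriorly at the T12 tilt
    pts["T12_ai"] = Point(t12_pi.x + p.body_depth * math.cos(t12),
                          t12_pi.y + p.body_depth * math.sin(t12))
    mid = Point((s1_ps.x + pts["S1_as"].x) / 2.0, (s1_ps.y + pts["S1_as"].y) / 2.0)
    pt = math.radians(p.pelvic_incidence) - sba  # Legaye: PT = PI - SS
    ha = Point(mid.x + p.pelvic_radius * math.sin(pt),
               mid.y - p.pelvic_radius * math.cos(pt))
    if ha.y >= mid.y:
        raise ConstructibilityError("hip axis not below the S1 endplate midpoint")
    pts["FEM_L"] = Point(ha.x - 4.0, ha.y)
    pts["FEM_R"] = Point(ha.x + 4.0, ha.y)
    pts["PUBIS"] = Point(ha.x + 55.0, ha.y - 60.0)

    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=(len(CANONICAL_LANDMARKS), 2))
        pts = {
            name: Point(pts[name].x + noise[i, 0], pts[name].y + noise[i, 1])
            for i, name in enumerate(CANONICAL_LANDMARKS)
        }

    truth = {
        "SBA": p.sacral_orientation,
        "SS": p.sacral_orientation,
        "PT_S1": p.resolved_sacral_tilt(),
        "sacral_tilt": p.resolved_sacral_tilt(),
        "t12_tilt": p.t12_tilt,
        "Cobb_T12S1": -(p.sacral_orientation + p.t12_tilt),
        "ARA_T12S1": -(p.t12_tilt + p.resolved_sacral_tilt()),
        "API": p.pelvic_incidence,
        "PT": p.pelvic_incidence - p.sacral_orientation,
        "ba_ratio": p.ba,
        "arc_extent": p.arc_extent,
    }
    return LandmarkSet(subject_id=subject_id, group=group, points=pts), truth


# ---------------------------------------------------------------------------
# cohort models

#: Generative cohort variables.  Cobb is specified signed (negative,
#: lordotic) as printed; internally its magnitude is drawn and the T12
#: tilt derived as |Cobb| - SBA.
COHORT_VARIABLES = ("SBA", "Cobb", "PTS1", "API", "ba")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional specification of a two-group synthetic cohort.

    ``groups`` maps a group label to ``{variable: (mean, sd)}`` over
    :data:`COHORT_VARIABLES` (any subset; missing variables fall back to
    the geometry defaults, with zero spread).  ``correlation`` is an
    optional Pearson correlation matrix over ``corr_variables`` applied
    to the signed variables via a Gaussian copula.  ``bounds`` optionally
    clips each draw to an observed range by rejection.  ``n`` subjects
    per group; ``seed`` drives all randomness.
    """

    groups: dict[str, dict[str, tuple[float, float]]]
    n: int = 50
    seed: int = 0
    noise_sd: float = 0.0
    correlation: np.ndarray | None = None
    corr_variables: tuple[str, ...] = COHORT_VARIABLES
    bounds: dict[str, dict[str, tuple[float, float]]] | None = None
    geometry: GeometryParams = field(default_factory=GeometryParams)
    max_reject_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise CohortSpecError("n must be >= 2 per group")
        for g, dists in self.groups.items():
            for v, (m, sd) in dists.items():
                if v not in COHORT_VARIABLES:
                    raise CohortSpecError(f"unknown cohort variable {v!r}")
                if sd < 0:
                    raise CohortSpecError(f"{g}/{v}: sd must be >= 0")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            k = len(self.corr_variables)
            if C.shape != (k, k) or not np.allclose(C, C.T):
                raise CohortSpecError("correlation must be a symmetric k x k matrix")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise CohortSpecError("correlation matrix is not positive semi-definite")


def _draw_group(spec: CohortSpec, group: str, rng: np.random.Generator,
                n: int) -> pd.DataFrame:
    """Draw n parameter vectors for one group (signed variable scale)."""
    dists = spec.groups[group]
    cols = {}
    if spec.correlation is not None:
        C = np.asarray(spec.correlation, dtype=float)
        C = nearest_psd(C)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        z = rng.standard_normal((n, len(spec.corr_variables))) @ L.T
        zmap = dict(zip(spec.corr_variables, z.T))
    else:
        zmap = {}
    for v in COHORT_VARIABLES:
        if v in dists:
            m, sd = dists[v]
            zv = zmap.get(v)
            if zv is None:
                zv = rng.standard_normal(n)
            cols[v] = m + sd * zv
        else:
            defaults = {"SBA": spec.geometry.sacral_orientation,
                        "Cobb": -(spec.geometry.sacral_orientation
                                  + spec.geometry.t12_tilt),
                        "PTS1": spec.geometry.resolved_sacral_tilt(),
                        "API": spec.geometry.pelvic_incidence,
                        "ba": spec.geometry.ba}
            cols[v] = np.full(n, defaults[v])
    return pd.DataFrame(cols)


def _row_feasible(row, spec: CohortSpec, drawn: set[str]) -> bool:
    if not (0 < row["SBA"] < 90 and 0 < row["PTS1"] < 90):
        return False
    # drawn b/a must stay in the admissible (fittable) ratio range
    if not 0.02 < row["ba"] < 1.6:
        return False
    # the T12 tilt, derived as |Cobb| - SBA when a Cobb target is
    # requested, must stay positive
    if "Cobb" in drawn and abs(row["Cobb"]) - row["SBA"] <= 0.5:
        return False
    if not -80 < row["API"] - row["SBA"] < 80:
        return False
    return True


def _params_from_row(row, spec: CohortSpec, drawn: set[str]) -> GeometryParams:
    # A Cobb target fixes the T12 tilt through |Cobb| = SBA + t12_tilt;
    # without one, the tilt keeps its direct geometric default and the
    # Cobb angle is emergent.
    if "Cobb" in drawn:
        t12 = float(abs(row["Cobb"]) - row["SBA"])
    else:
        t12 = spec.geometry.t12_tilt
    return replace(spec.geometry,
                   ba=float(row["ba"]),
                   sacral_orientation=float(row["SBA"]),
                   t12_tilt=t12,
                   sacral_tilt=float(row["PTS1"]),
                   pelvic_incidence=float(row["API"]),
                   noise_sd=spec.noise_sd)


def generate_cohorts(spec: CohortSpec
                     ) -> tuple[dict[str, list[LandmarkSet]], pd.DataFrame]:
    """Generate landmark-level cohorts per the spec.

    Returns a mapping group -> list of landmark sets, and a truth table
    (one row per subject) of the noise-free target angles.  Fully
    reproducible from ``spec.seed``; draws violating group bounds or
    geometric constructibility are rejected and redrawn, and a rejection
    rate above ``max_reject_fraction`` raises :class:`CohortSpecError`.
    """
    rng = np.random.default_rng(spec.seed)
    cohorts: dict[str, list[LandmarkSet]] = {}
    truth_rows: list[dict] = []
    for group in spec.groups:
        drawn_vars = set(spec.groups[group])
        accepted: list[GeometryParams] = []
        n_drawn = 0
        while len(accepted) < spec.n:
            batch = _draw_group(spec, group, rng, spec.n)
            bounds = (spec.bounds or {}).get(group)
            for _, row in batch.iterrows():
                n_drawn += 1
                if bounds is not None and any(
                        not lo <= row[v] <= hi for v, (lo, hi) in bounds.items()):
                    continue
                if not _row_feasible(row, spec, drawn_vars):
                    continue
                accepted.append(_params_from_row(row, spec, drawn_vars))
                if len(accepted) == spec.n:
                    break
            if n_drawn >= 2 * spec.n and (
                    (n_drawn - len(accepted)) / n_drawn > spec.max_reject_fraction):
                raise CohortSpecError(
                    f"group {group!r}: rejection rate "
                    f"{(n_drawn - len(accepted)) / n_drawn:.0%} exceeds "
                    f"{spec.max_reject_fraction:.0%}; spec infeasible")
        sets = []
        for i, p in enumerate(accepted):
            sid = f"{group}_{i + 1:04d}"
            ls, truth = spine_from_params(p, rng, subject_id=sid, group=group)
            sets.append(ls)
            truth_rows.append({"subject_id": sid, "group": group, **truth})
        cohorts[group] = sets
    return cohorts, pd.DataFrame(truth_rows)


def summary_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject measurement vectors directly from the group
    Gaussian models, without constructing landmarks.

    Intended for statistics-only experiments (e.g. large-n ROC studies)
    where the binormal approximation of the group distributions is the
    object of interest.  Columns use the measurement names (``SBA``,
    ``Cobb_T12S1`` signed, ``PT_S1``, ``API``, ``ba_ratio``) plus
    ``subject_id`` and ``group``.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    rename = {"Cobb": "Cobb_T12S1", "PTS1": "PT_S1", "ba": "ba_ratio"}
    for group in spec.groups:
        df = _draw_group(spec, group, rng, spec.n).rename(columns=rename)
        df.insert(0, "group", group)
        df.insert(0, "subject_id",
                  [f"{group}_{i + 1:07d}" for i in range(spec.n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# correlation helpers

def spearman_from_pearson(rho: float) -> float:
    """Population Spearman correlation of a bivariate Gaussian with
    Pearson correlation ``rho``: (6/pi) * asin(rho / 2)."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


def pearson_from_spearman(rho_s: float) -> float:
    """Inverse of :func:`spearman_from_pearson`: 2 * sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def nearest_psd(C: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite
    correlation matrix (eigenvalue clipping + unit-diagonal rescale)."""
    C = np.asarray(C, dtype=float)
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() >= eps:
        return C
    w = np.clip(w, eps, None)
    M = (V * w) @ V.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)
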