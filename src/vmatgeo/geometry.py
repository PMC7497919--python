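"""Beam-frame construction and beam's-eye-view (BEV) projection.

The patient frame is DICOM LPS (+x patient left, +y posterior, +z superior),
head-first supine, units mm.  Machine angles follow the linac convention:

* gantry 0 puts the source anterior, so the beam travels anterior→posterior
  (+y); gantry 90 puts the source at the patient's left; gantry rotation is
  about the patient superior–inferior axis at couch 0.
* the couch rotates about the room-vertical axis (the patient's
  anterior–posterior axis when supine) and is applied before the gantry
  rotation.
* the collimator rotates the MLC within the BEV plane.

The BEV is the 2-D view a viewer looking *along* the beam sees: x to the
viewer's right (patient left at gantry 0), y up (patient superior at couch 0).
With that orientation ``cross(x_bev, y_bev) == -beam_dir`` — the triple
(x_bev, y_bev, -beam_dir) is right-handed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamGeometry",
    "ProjectedBoundary",
    "BevExtents",
    "beam_frame",
    "project_points",
    "compute_pob",
    "extents",
    "rotate_to_mlc_frame",
]

DEFAULT_SAD_MM = 1000.0


def _norm_angle(a: float, period: float = 360.0) -> float:
    a = float(a) % period
    return a + period if a < 0 else a


@dataclass(frozen=True)
class BeamGeometry:
    """One machine orientation: gantry/couch in [0,360), collimator in [0,180).

    The collimator angle is reduced mod 180 because opposed MLC leaf banks
    make apertures 180°-symmetric.
    """

    gantry_deg: float = 0.0
    couch_deg: float = 0.0
    collimator_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.gantry_deg)
            and math.isfinite(self.couch_deg)
            and math.isfinite(self.collimator_deg)
        ):
            raise ValueError("beam angles must be finite")
        object.__setattr__(self, "gantry_deg", _norm_angle(self.gantry_deg))
        object.__setattr__(self, "couch_deg", _norm_angle(self.couch_deg))
        object.__setattr__(
            self, "collimator_deg", _norm_angle(self.collimator_deg, 180.0)
        )


@dataclass
class BevExtents:
    """Maximum boundary distances from the isocenter in the four BEV
    directions: x1 (−X), x2 (+X), y1 (−Y), y2 (+Y).  All non-negative."""

    x1_mm: float
    x2_mm: float
    y1_mm: float
    y2_mm: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1_mm, self.x2_mm, self.y1_mm, self.y2_mm)


@dataclass
class ProjectedBoundary:
    """Projected outer boundary (POB) of a group of lesions in one BEV.

    One closed, simple polygon per lesion (its 2-D convex hull), coordinates
    in mm relative to the isocenter projection at the origin.
    """

    beam: BeamGeometry
    isocenter: np.ndarray
    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)
        self.polygons = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polygons]
        for p in self.polygons:
            if len(p) < 3:
                raise ValueError("POB polygons need >=3 vertices")

    def all_vertices(self) -> np.ndarray:
        return np.concatenate(self.polygons, axis=0)


def beam_frame(
    gantry_deg: float, couch_deg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (x_bev_dir, y_bev_dir, beam_dir): orthonormal vectors of the
    BEV axes and the beam travel direction, in the LPS patient frame.

    Couch rotation (about the patient A–P axis) is applied before the gantry
    rotation; a positive couch angle swings the gantry plane so the couch-0
    superior axis tilts toward patient-left.
    """
    g = math.radians(_norm_angle(gantry_deg))
    c = math.radians(_norm_angle(couch_deg))

    # couch-0 frame: gantry rotation in the axial (x,y) plane
    beam = np.array([-math.sin(g), math.cos(g), 0.0])
    x_bev = np.array([math.cos(g), math.sin(g), 0.0])
    y_bev = np.array([0.0, 0.0, 1.0])

    if c != 0.0:
        cc, sc = math.cos(c), math.sin(c)
        rot_y = np.array([[cc, 0.0, sc], [0.0, 1.0, 0.0], [-sc, 0.0, cc]])
        beam = rot_y @ beam
        x_bev = rot_y @ x_bev
        y_bev = rot_y @ y_bev
    return x_bev, y_bev, beam


def project_points(
    points_3d: np.ndarray,
    isocenter: np.ndarray,
    beam: BeamGeometry,
    mode: str = "parallel",
    sad_mm: float = DEFAULT_SAD_MM,
) -> np.ndarray:
    """Project patient-frame points into the BEV plane through the isocenter.

    ``parallel`` drops the depth coordinate (orthographic); ``divergent``
    performs a central projection from a source ``sad_mm`` upstream of the
    isocenter onto the isocenter plane.  Cranial targets sit close enough to
    the isocenter that the two differ by well under a millimetre at
    SAD 1000 mm; parallel is the default.
    """
    pts = np.asarray(points_3d, dtype=float).reshape(-1, 3)
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    x_dir, y_dir, beam_dir = beam_frame(beam.gantry_deg, beam.couch_deg)
    rel = pts - iso
    u = rel @ x_dir
    v = rel @ y_dir
    if mode == "parallel":
        return np.column_stack([u, v])
    if mode == "divergent":
        depth = rel @ beam_dir  # signed distance past the isocenter plane
        denom = sad_mm + depth
        if np.any(denom <= 0):
            raise ValueError("divergent projection: point at or behind the source")
        scale = sad_mm / denom
        return np.column_stack([u * scale, v * scale])
    raise ValueError(f"unknown projection mode {mode!r}")


def _convex_hull_2d(points_2d: np.ndarray) -> np.ndarray:
    """CCW convex hull vertices (Andrew monotone chain); order/duplication
    independent.  Raises on collinear degeneracy."""
    pts = np.unique(np.asarray(points_2d, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) < 3:
        raise ValueError("degenerate projection: fewer than 3 distinct points")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise ValueError("degenerate projection: collinear points")
    return hull


def compute_pob(
    lesions,
    isocenter: np.ndarray,
    beam: BeamGeometry,
    mode: str = "parallel",
    sad_mm: float = DEFAULT_SAD_MM,
) -> ProjectedBoundary:
    """Projected outer boundary of grouped lesions: one 2-D convex hull per
    lesion in the BEV of ``beam`` about ``isocenter``.

    Each lesion must expose ``.points`` (n×3 surface points, mm) and ``.id``.
    """
    polygons = []
    for lesion in lesions:
        proj = project_points(lesion.points, isocenter, beam, mode=mode, sad_mm=sad_mm)
        try:
            hull = _convex_hull_2d(proj)
        except ValueError as exc:
            raise ValueError(f"lesion {lesion.id!r}: {exc}") from exc
        polygons.append(hull)
    return ProjectedBoundary(beam=beam, isocenter=np.asarray(isocenter, float), polygons=polygons)


def extents(pob: ProjectedBoundary) -> BevExtents:
    """Distances from the BEV origin to the outermost boundary vertex in the
    −X, +X, −Y, +Y directions (clamped at 0 when the POB is one-sided)."""
    verts = pob.all_vertices()
    return BevExtents(
        x1_mm=max(0.0, -float(verts[:, 0].min())),
        x2_mm=max(0.0, float(verts[:, 0].max())),
        y1_mm=max(0.0, -float(verts[:, 1].min())),
        y2_mm=max(0.0, float(verts[:, 1].max())),
    )


def rotate_to_mlc_frame(pob: ProjectedBoundary, collimator_deg: float) -> ProjectedBoundary:
    """Express the POB in the MLC frame for a given collimator angle.

    The MLC frame is held fixed and the projection rotated by −collimator
    about the BEV origin (equivalent to spinning the collimator by +angle).
    """
    c = math.radians(_norm_angle(collimator_deg, 180.0))
    rot = np.array([[math.cos(-c), -math.sin(-c)], [math.sin(-c), math.cos(-c)]])
    beam = BeamGeometry(pob.beam.gantry_deg, pob.beam.couch_deg, collimator_deg)
    return ProjectedBoundary(
        beam=beam,
        isocenter=pob.isocenter,
        polygons=[p @ rot.T for p in pob.polygons],
    )
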