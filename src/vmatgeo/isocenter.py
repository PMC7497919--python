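"""Isocenter placement and the projection-distance feasibility check.

An isocenter serving a group of lesions starts at the centroid of the
lesions' (equally weighted) centroids and is then shifted so the projected
outer boundary (POB) of the group is symmetric about it: left/right and
superior/inferior extents equalized in the gantry-0 BEV, anterior/posterior
extents in the gantry-270 BEV.  Under parallel projection this lands on the
3-D bounding-box center of the grouped surface points.

Feasibility then requires the POB to stay within machine-dependent distance
limits (HD120: 50 mm per X side, 40 mm per Y side, keeping the field on the
2.5 mm central leaves; Millennium 120: 50 mm both) in the BEVs at gantry
0°, 45°, 270° and 315°, couch and collimator 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BeamGeometry, BevExtents, compute_pob, extents

__all__ = [
    "DistanceCriteria",
    "FeasibilityReport",
    "DEFAULT_CHECK_ANGLES",
    "initial_isocenter",
    "symmetrize_isocenter",
    "check_projection_distance",
]

DEFAULT_CHECK_ANGLES: tuple[float, ...] = (0.0, 45.0, 270.0, 315.0)

#: boundary comparisons use <= with this slack so a lesion exactly at the
#: limit passes
_BOUNDARY_TOL_MM = 1e-6

_SYMMETRY_TOL_MM = 0.01
_MAX_SYMMETRIZE_ITER = 20


@dataclass(frozen=True)
class DistanceCriteria:
    """Per-direction limits on the BEV boundary distance from the isocenter."""

    x_max_mm: float
    y_max_mm: float

    def __post_init__(self) -> None:
        if self.x_max_mm <= 0 or self.y_max_mm <= 0:
            raise ValueError("distance criteria must be positive")


@dataclass
class FeasibilityReport:
    """Outcome of the projection-distance check at each configured gantry
    angle; ``overall_pass`` is the conjunction of the per-angle passes."""

    per_angle: dict[float, tuple[BevExtents, bool]] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(ok for _, ok in self.per_angle.values())


def initial_isocenter(lesions) -> np.ndarray:
    """Centroid of the equally weighted lesion centroids (each lesion
    contributes one point regardless of its size)."""
    if not lesions:
        raise ValueError("cannot place an isocenter for an empty lesion group")
    return np.mean([lesion.centroid for lesion in lesions], axis=0)


def symmetrize_isocenter(
    lesions,
    iso0: np.ndarray,
    mode: str = "parallel",
    sad_mm: float = 1000.0,
) -> np.ndarray:
    """Shift the isocenter until opposing POB extents balance.

    Each pass measures the POB at gantry 0 (balancing BEV X = patient
    left/right and BEV Y = superior/inferior) and gantry 270 (balancing BEV
    X = anterior/posterior) and moves the isocenter by half the imbalance
    along the corresponding BEV axes.  In parallel mode one pass is exact;
    the loop exists so the divergent mode also converges (capped at 20
    iterations).
    """
    from .geometry import beam_frame  # local import to keep module surface tidy

    iso = np.asarray(iso0, dtype=float).copy()
    for _ in range(_MAX_SYMMETRIZE_ITER):
        worst = 0.0
        for gantry in (0.0, 270.0):
            beam = BeamGeometry(gantry, 0.0, 0.0)
            ext = extents(compute_pob(lesions, iso, beam, mode=mode, sad_mm=sad_mm))
            x_dir, y_dir, _ = beam_frame(gantry, 0.0)
            dx = 0.5 * (ext.x2_mm - ext.x1_mm)
            iso = iso + dx * x_dir
            worst = max(worst, abs(ext.x2_mm - ext.x1_mm))
            if gantry == 0.0:
                dy = 0.5 * (ext.y2_mm - ext.y1_mm)
                iso = iso + dy * y_dir
                worst = max(worst, abs(ext.y2_mm - ext.y1_mm))
        if worst < _SYMMETRY_TOL_MM:
            break
    return iso


def check_projection_distance(
    lesions,
    iso: np.ndarray,
    criteria: DistanceCriteria,
    check_angles=DEFAULT_CHECK_ANGLES,
    mode: str = "parallel",
    sad_mm: float = 1000.0,
) -> FeasibilityReport:
    """Verify the POB stays within ``criteria`` in the BEV at every check
    angle (couch and collimator 0).  A boundary exactly at the limit passes."""
    report = FeasibilityReport()
    for gantry in check_angles:
        beam = BeamGeometry(gantry, 0.0, 0.0)
        ext = extents(compute_pob(lesions, iso, beam, mode=mode, sad_mm=sad_mm))
        ok = (
            ext.x1_mm <= criteria.x_max_mm + _BOUNDARY_TOL_MM
            and ext.x2_mm <= criteria.x_max_mm + _BOUNDARY_TOL_MM
            and ext.y1_mm <= criteria.y_max_mm + _BOUNDARY_TOL_MM
            and ext.y2_mm <= criteria.y_max_mm + _BOUNDARY_TOL_MM
        )
        report.per_angle[float(gantry)] = (ext, ok)
    return report
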