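"""Per-arc collimator-angle optimization.

For each treatment arc the projected outer boundary (POB) of the grouped
lesions is sampled along the gantry rotation; at every candidate collimator
angle the MLC aperture is fitted to each sampled POB and the opening areas
are summed over the arc.  The collimator angle with the smallest summed
opening area wins (ties to the smallest angle).  The scan covers 0–165° —
angles up to 180° add nothing because opposed leaf banks make apertures
180°-periodic, and the last 15° are excluded by machine rotation limits.

Defaults follow the clinically released settings (gantry sampled every 2°,
collimator every 5°); the finer research setting (4°/1°) is available via
the step arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import BeamGeometry, compute_pob, rotate_to_mlc_frame
from .mlc import JawSetting, MachineModel, fit_jaws, fit_leaves

__all__ = [
    "Arc",
    "CollimatorScan",
    "ArcGeometry",
    "PlanGeometry",
    "default_arcs",
    "sample_gantry",
    "scan_collimator",
    "optimize_plan_geometry",
    "DEFAULT_GANTRY_STEP_DEG",
    "DEFAULT_COLL_STEP_DEG",
    "DEFAULT_COLL_RANGE_DEG",
]

logger = logging.getLogger(__name__)

DEFAULT_GANTRY_STEP_DEG = 2.0
DEFAULT_COLL_STEP_DEG = 5.0
DEFAULT_COLL_RANGE_DEG = (0.0, 165.0)


@dataclass(frozen=True)
class Arc:
    """One VMAT arc: fixed couch angle, gantry sweep from start to stop.

    ``direction`` CW means increasing gantry angle (mod 360), CCW
    decreasing.  ``full`` marks a (near-)complete rotation.
    """

    id: str
    couch_deg: float
    gantry_start_deg: float
    gantry_stop_deg: float
    direction: str = "CW"
    full: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("CW", "CCW"):
            raise ValueError("arc direction must be CW or CCW")
        if not self.full and self.gantry_start_deg % 360 == self.gantry_stop_deg % 360:
            raise ValueError("degenerate arc: start == stop without full flag")

    @property
    def span_deg(self) -> float:
        start = self.gantry_start_deg % 360
        stop = self.gantry_stop_deg % 360
        if self.direction == "CW":
            span = (stop - start) % 360
        else:
            span = (start - stop) % 360
        return 360.0 if span == 0 and self.full else span


@dataclass
class CollimatorScan:
    """Result of scanning collimator angles for one arc: the sampled angles,
    the summed MLC opening area at each, and the best (minimum-area) angle.
    Ties — totals within 1e-9 relative of the minimum — break to the
    smallest angle."""

    arc_id: str
    angles_deg: list[float]
    total_areas_mm2: list[float]
    best_angle_deg: float

    def best_area_mm2(self) -> float:
        return self.total_areas_mm2[self.angles_deg.index(self.best_angle_deg)]


@dataclass
class ArcGeometry:
    """Optimized geometry for one (cluster, arc) pair."""

    arc: Arc
    scan: CollimatorScan
    collimator_deg: float
    jaws: JawSetting


@dataclass
class PlanGeometry:
    """Per-cluster plan geometry: isocenter plus the optimized arcs."""

    cluster_index: int
    lesion_ids: list
    isocenter_mm: np.ndarray
    arcs: list[ArcGeometry] = field(default_factory=list)


def default_arcs() -> list[Arc]:
    """The default four-arc set: a full arc at couch 0 plus 180°-range
    partial arcs at couch 90°, 45° and 315°, routed away from the couch."""
    return [
        Arc("arc1_c0_full", 0.0, 181.0, 179.0, "CW", full=False),
        Arc("arc2_c90", 90.0, 180.0, 0.0, "CCW"),
        Arc("arc3_c45", 45.0, 180.0, 0.0, "CCW"),
        Arc("arc4_c315", 315.0, 180.0, 0.0, "CW"),
    ]


def sample_gantry(arc: Arc, step_deg: float) -> list[float]:
    """Gantry angles sampled along the arc, inclusive of both endpoints,
    honouring direction and 0/360 wrap-around (duplicate endpoint dropped
    when start ≡ stop)."""
    if step_deg <= 0:
        raise ValueError("gantry step must be positive")
    span = arc.span_deg
    start = arc.gantry_start_deg % 360
    sign = 1.0 if arc.direction == "CW" else -1.0
    n = int(np.floor(span / step_deg + 1e-9))
    angles = [(start + sign * i * step_deg) % 360 for i in range(n + 1)]
    if abs(angles[-1] % 360 - arc.gantry_stop_deg % 360) > 1e-9:
        angles.append(arc.gantry_stop_deg % 360)
    # dedup a coincident final endpoint (full arcs where start == stop)
    if len(angles) > 1 and abs((angles[-1] - angles[0]) % 360) < 1e-9:
        angles.pop()
    return angles


def _coll_angles(coll_range, step_deg) -> list[float]:
    lo, hi = coll_range
    if not (0 <= lo <= hi < 180):
        raise ValueError("collimator range must lie within [0, 180)")
    n = int(np.floor((hi - lo) / step_deg + 1e-9))
    angles = [lo + i * step_deg for i in range(n + 1)]
    if angles[-1] < hi - 1e-9:
        angles.append(hi)
    return angles


def scan_collimator(
    lesions,
    iso: np.ndarray,
    arc: Arc,
    machine: MachineModel,
    gantry_step_deg: float = DEFAULT_GANTRY_STEP_DEG,
    coll_step_deg: float = DEFAULT_COLL_STEP_DEG,
    coll_range=DEFAULT_COLL_RANGE_DEG,
    mode: str = "parallel",
) -> CollimatorScan:
    """Scan collimator angles for one arc.

    total(c) = Σ over sampled gantry angles g of the MLC opening area fitted
    to the POB at (g, arc.couch) rotated into the MLC frame at collimator c.
    Returns every sampled angle with its summed area and the argmin (ties
    broken to the smallest angle).
    """
    gantry_angles = sample_gantry(arc, gantry_step_deg)
    coll_angles = _coll_angles(coll_range, coll_step_deg)
    pobs = []
    for g in gantry_angles:
        beam = BeamGeometry(g, arc.couch_deg, 0.0)
        pobs.append(compute_pob(lesions, iso, beam, mode=mode, sad_mm=machine.sad_mm))

    totals = []
    for c in coll_angles:
        total = 0.0
        for pob in pobs:
            rotated = rotate_to_mlc_frame(pob, c)
            try:
                total += fit_leaves(rotated, machine).total_area_mm2
            except ValueError as exc:
                raise ValueError(f"arc {arc.id!r}: {exc}") from exc
        totals.append(total)
    # smallest angle within numerical-tie distance of the minimum wins
    min_total = min(totals)
    best_idx = next(
        i for i, t in enumerate(totals) if t <= min_total * (1 + 1e-9) + 1e-9
    )
    return CollimatorScan(
        arc_id=arc.id,
        angles_deg=[float(c) for c in coll_angles],
        total_areas_mm2=totals,
        best_angle_deg=float(coll_angles[best_idx]),
    )


def optimize_plan_geometry(
    clustering,
    arcs: list[Arc] | None,
    machine: MachineModel,
    lesions_by_id: dict,
    gantry_step_deg: float = DEFAULT_GANTRY_STEP_DEG,
    coll_step_deg: float = DEFAULT_COLL_STEP_DEG,
    coll_range=DEFAULT_COLL_RANGE_DEG,
    jaw_margin_mm: float = 0.0,
    mode: str = "parallel",
) -> list[PlanGeometry]:
    """Optimize collimator angle and jaws for every (cluster, arc) pair of a
    feasible clustering; returns one PlanGeometry per cluster."""
    if arcs is None:
        arcs = default_arcs()
    plans = []
    for ci, cluster in enumerate(clustering.clusters):
        group = [lesions_by_id[lid] for lid in cluster.lesion_ids]
        plan = PlanGeometry(
            cluster_index=ci,
            lesion_ids=list(cluster.lesion_ids),
            isocenter_mm=np.asarray(cluster.isocenter, float),
        )
        for arc in arcs:
            scan = scan_collimator(
                group,
                cluster.isocenter,
                arc,
                machine,
                gantry_step_deg=gantry_step_deg,
                coll_step_deg=coll_step_deg,
                coll_range=coll_range,
                mode=mode,
            )
            best = scan.best_angle_deg
            pobs = [
                rotate_to_mlc_frame(
                    compute_pob(
                        group,
                        cluster.isocenter,
                        BeamGeometry(g, arc.couch_deg, 0.0),
                        mode=mode,
                        sad_mm=machine.sad_mm,
                    ),
                    best,
                )
                for g in sample_gantry(arc, gantry_step_deg)
            ]
            jaws = fit_jaws(pobs, best, machine, margin_mm=jaw_margin_mm)
            plan.arcs.append(
                ArcGeometry(arc=arc, scan=scan, collimator_deg=best, jaws=jaws)
            )
            logger.info(
                "cluster %d arc %s: collimator %.1f deg, area %.1f mm2",
                ci,
                arc.id,
                best,
                scan.best_area_mm2(),
            )
        plans.append(plan)
    return plans
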