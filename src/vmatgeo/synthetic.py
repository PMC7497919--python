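"""Deterministic generator of synthetic multi-metastasis cases.

Emulates the geometry of multi-lesion cranial SRS cohorts at desk scale:
a handful of quasi-spherical lesions (radii a few to ~20 mm) scattered
inside a cranial sphere, optionally with planted cluster structure whose
ground-truth labels the clustering stage should recover.  Lesion surfaces
are Fibonacci-lattice point sets, so identical specs give bit-identical
geometry and exactly repeatable convex hulls and aperture areas.

What it does **not** emulate: real contour slice structure, non-spherical
lesion shapes, organs at risk, or any dose information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Lesion, StructureSet

__all__ = ["SyntheticSpec", "GroundTruth", "sphere_surface_points", "generate_case"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic case.

    Defaults mirror a typical multi-metastasis presentation: 2–3 spatially
    distinct groups of small lesions inside a ~80 mm-radius cranial volume.
    """

    n_clusters: int = 3
    lesions_per_cluster: int = 2
    cluster_center_box_mm: float = 120.0  # cube edge for cluster-center draws
    intra_cluster_spread_mm: float = 8.0
    radius_range_mm: tuple[float, float] = (2.0, 10.0)
    points_per_lesion: int = 80
    skull_radius_mm: float = 80.0
    min_center_spacing_mm: float | None = None  # planted-separation floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_cluster_spread_mm <= 0 or self.radius_range_mm[0] <= 0:
            raise ValueError("spread and radii must be positive")
        if self.radius_range_mm[1] >= self.skull_radius_mm:
            raise ValueError("lesion radii must be smaller than the skull radius")
        if self.points_per_lesion < 4:
            raise ValueError("need at least 4 surface points per lesion")


@dataclass
class GroundTruth:
    """Planted clustering: lesion id -> cluster label, plus the planted
    cluster centers (mm)."""

    labels: dict[str, int] = field(default_factory=dict)
    cluster_centers_mm: np.ndarray | None = None


def sphere_surface_points(
    center, radius: float, n: int, seed: int | None = None
) -> np.ndarray:
    """``n`` Fibonacci-lattice points on a sphere (near-uniform coverage,
    fully deterministic).  ``seed`` only randomizes the lattice orientation."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n < 4:
        raise ValueError("need n >= 4 points")
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.clip(1 - z * z, 0.0, None))
    pts = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    if seed is not None:
        # random rotation so lattices of different lesions are not aligned
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
        if np.linalg.det(rot) < 0:
            rot[:, 0] = -rot[:, 0]
        pts = pts @ rot.T
    return np.asarray(center, dtype=float) + radius * pts


def generate_case(spec: SyntheticSpec) -> tuple[StructureSet, GroundTruth]:
    """Generate one synthetic structure set with planted cluster labels.

    Cluster centers are drawn uniformly in a cube and rejection-sampled so
    every lesion (center + spread + max radius) stays inside the skull
    sphere; lesion centers scatter isotropically about their cluster center.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.cluster_center_box_mm / 2.0
    r_max = spec.radius_range_mm[1]
    margin = r_max + 3.0 * spec.intra_cluster_spread_mm
    if margin >= spec.skull_radius_mm:
        raise ValueError(
            "infeasible spec: radius + 3*spread exceeds the skull radius"
        )
    keep_within = spec.skull_radius_mm - margin

    centers: list[np.ndarray] = []
    for _restart in range(500):
        centers = []
        for _ in range(spec.n_clusters):
            for _attempt in range(200):
                c = rng.uniform(-half, half, size=3)
                if np.linalg.norm(c) > keep_within:
                    continue
                if spec.min_center_spacing_mm is not None and any(
                    np.linalg.norm(c - prev) < spec.min_center_spacing_mm
                    for prev in centers
                ):
                    continue
                centers.append(c)
                break
            else:
                break  # this center draw failed; restart the whole set
        if len(centers) == spec.n_clusters:
            break
    else:
        raise ValueError(
            "infeasible spec: cluster centers do not fit the skull/spacing"
        )
    centers = np.array(centers)

    lesions: list[Lesion] = []
    truth = GroundTruth(cluster_centers_mm=centers)
    for ci, center in enumerate(centers):
        for li in range(spec.lesions_per_cluster):
            for _attempt in range(1000):
                lesion_center = center + rng.normal(
                    scale=spec.intra_cluster_spread_mm, size=3
                )
                radius = rng.uniform(*spec.radius_range_mm)
                if np.linalg.norm(lesion_center) + radius <= spec.skull_radius_mm:
                    break
            else:
                raise ValueError("infeasible spec: cannot fit lesion in skull")
            lesion_id = f"PTV_c{ci}_l{li}"
            pts = sphere_surface_points(
                lesion_center,
                radius,
                spec.points_per_lesion,
                seed=int(rng.integers(2**31)),
            )
            lesions.append(Lesion(id=lesion_id, name=lesion_id, points=pts))
            truth.labels[lesion_id] = ci
    return StructureSet(lesions=lesions, source=f"synthetic(seed={spec.seed})"), truth
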