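"""Independent oracles used by the test suite.

Everything here recomputes quantities by a different route than the package:
scipy rotation matrices instead of hand-built frames, surjective-assignment
enumeration instead of recursive block placement, shapely polygon clipping
instead of the edge-parametric band fit, and closed-form bounding-box
isocenters instead of iterative symmetrization.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

BOUNDARY_TOL_MM = 1e-6


# --- geometry ---------------------------------------------------------------


def frame_oracle(gantry_deg: float, couch_deg: float):
    """BEV frame via scipy Rotation composition: couch about the patient
    A-P (y) axis first, then gantry about the patient S-I (z) axis."""
    r_couch = Rotation.from_euler("y", couch_deg, degrees=True)
    g = np.radians(gantry_deg)
    beam0 = np.array([-np.sin(g), np.cos(g), 0.0])
    x0 = np.array([np.cos(g), np.sin(g), 0.0])
    y0 = np.array([0.0, 0.0, 1.0])
    return r_couch.apply(x0), r_couch.apply(y0), r_couch.apply(beam0)


def project_oracle(points, iso, gantry_deg, couch_deg=0.0):
    """Parallel BEV projection via the rotation-matrix frame."""
    x_dir, y_dir, _ = frame_oracle(gantry_deg, couch_deg)
    rel = np.asarray(points, float) - np.asarray(iso, float)
    return np.column_stack([rel @ x_dir, rel @ y_dir])


def rotate2d_oracle(points_2d, angle_deg):
    """Rotate 2-D points by ``angle_deg`` via scipy (about +z)."""
    r = Rotation.from_euler("z", angle_deg, degrees=True)
    pts3 = np.column_stack([np.asarray(points_2d, float), np.zeros(len(points_2d))])
    return r.apply(pts3)[:, :2]


def bbox_center_oracle(all_points) -> np.ndarray:
    """Closed-form symmetrized isocenter in parallel mode: per-axis midpoint
    of the 3-D bounding box of all grouped surface points."""
    pts = np.asarray(all_points, float).reshape(-1, 3)
    return 0.5 * (pts.min(axis=0) + pts.max(axis=0))


def extents_oracle(points_2d):
    pts = np.asarray(points_2d, float)
    return (
        max(0.0, -pts[:, 0].min()),
        max(0.0, pts[:, 0].max()),
        max(0.0, -pts[:, 1].min()),
        max(0.0, pts[:, 1].max()),
    )


def feasible_oracle(lesions, iso, x_max, y_max, angles=(0, 45, 270, 315)) -> bool:
    for g in angles:
        proj = np.concatenate(
            [project_oracle(lesion.points, iso, g) for lesion in lesions]
        )
        x1, x2, y1, y2 = extents_oracle(proj)
        if not (
            x1 <= x_max + BOUNDARY_TOL_MM
            and x2 <= x_max + BOUNDARY_TOL_MM
            and y1 <= y_max + BOUNDARY_TOL_MM
            and y2 <= y_max + BOUNDARY_TOL_MM
        ):
            return False
    return True


# --- clustering -------------------------------------------------------------


def partitions_oracle(items, k):
    """All set partitions of ``items`` into exactly k blocks, by filtering
    the k^n label assignments down to canonical surjective ones (labels in
    first-appearance order)."""
    items = list(items)
    n = len(items)
    seen = set()
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        # canonical relabeling by first appearance
        remap, canon = {}, []
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap)
            canon.append(remap[lab])
        canon = tuple(canon)
        if canon in seen:
            continue
        seen.add(canon)
        blocks = [[] for _ in range(k)]
        for item, lab in zip(items, canon):
            blocks[lab].append(item)
        yield blocks


def ssed_oracle(centroids, iso) -> float:
    total = 0.0
    for c in np.asarray(centroids, float).reshape(-1, 3):
        d = c - np.asarray(iso, float)
        total += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
    return total


def brute_force_clustering(lesions, x_max, y_max, max_k=3):
    """Reference minimum-isocenter clustering: enumerate partitions per k
    with the assignment oracle, isocenter = bounding-box center, feasibility
    via rotation-matrix projections, SSED by accumulation loop.  Returns
    (k, partition, total_ssed) or None; ties broken to the
    lexicographically-smallest partition by input rank."""
    lesions = list(lesions)
    rank = {l.id: i for i, l in enumerate(lesions)}
    by_id = {l.id: l for l in lesions}
    ids = [l.id for l in lesions]
    for k in range(1, min(max_k, len(ids)) + 1):
        best = None
        for partition in partitions_oracle(ids, k):
            total = 0.0
            ok = True
            for block in partition:
                group = [by_id[i] for i in block]
                iso = bbox_center_oracle(np.concatenate([l.points for l in group]))
                if not feasible_oracle(group, iso, x_max, y_max):
                    ok = False
                    break
                total += ssed_oracle([l.centroid for l in group], iso)
            if not ok:
                continue
            key = tuple(tuple(rank[i] for i in block) for block in partition)
            if best is None:
                best = (total, key, partition)
            else:
                rel = abs(total - best[0]) / max(abs(best[0]), 1e-30)
                if (rel > 1e-6 and total < best[0]) or (rel <= 1e-6 and key < best[1]):
                    best = (total, key, partition)
        if best is not None:
            return k, best[2], best[0]
    return None


# --- MLC / collimator -------------------------------------------------------


def aperture_area_oracle(polygons, leaf_edges) -> float:
    """Opening area via shapely: clip each leaf band, open a single interval
    from the clipped union's X bounds; zero-area (touching) clips stay shut."""
    polys = [Polygon(p) for p in polygons]
    total = 0.0
    for lo, hi in zip(leaf_edges[:-1], leaf_edges[1:]):
        band = box(-1e6, lo, 1e6, hi)
        clipped = unary_union([poly.intersection(band) for poly in polys])
        if clipped.is_empty or clipped.area <= 1e-12:
            continue
        minx, _, maxx, _ = clipped.bounds
        total += (hi - lo) * (maxx - minx)
    return total


def union_area_oracle(polygons) -> float:
    return unary_union([Polygon(p) for p in polygons]).area


def collimator_brute_force(lesions, iso, gantry_angles, couch_deg, leaf_edges,
                           coll_angles):
    """Best collimator angle by direct enumeration with the shapely aperture
    oracle; smallest angle within 1e-9 relative of the minimum wins."""
    hulls_per_gantry = []
    for g in gantry_angles:
        hulls = []
        for lesion in lesions:
            proj = project_oracle(lesion.points, iso, g, couch_deg)
            hulls.append(np.array(MultiPoint(proj).convex_hull.exterior.coords))
        hulls_per_gantry.append(hulls)
    totals = []
    for c in coll_angles:
        total = 0.0
        for hulls in hulls_per_gantry:
            rotated = [rotate2d_oracle(h, -c) for h in hulls]
            total += aperture_area_oracle(rotated, leaf_edges)
        totals.append(total)
    min_total = min(totals)
    best = next(i for i, t in enumerate(totals)
                if t <= min_total * (1 + 1e-9) + 1e-9)
    return coll_angles[best], totals
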