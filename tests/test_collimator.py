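import numpy as np
import pytest

from vmatgeo.collimator import (
    Arc,
    default_arcs,
    optimize_plan_geometry,
    sample_gantry,
    scan_collimator,
)
from vmatgeo.io_formats import Lesion
from vmatgeo.synthetic import sphere_surface_points

from oracles import collimator_brute_force


def box_lesion(lesion_id, x_range, y_range, z_range):
    """Axis-aligned box: its gantry-0 BEV projection is the rectangle
    x_range x z_range (BEV y = patient z)."""
    pts = np.array([[x, y, z] for x in x_range for y in y_range for z in z_range],
                   float)
    return Lesion(id=lesion_id, name=lesion_id, points=pts)


def ring_sphere(center, radius, n_rings=9, points_per_ring=72):
    """Sphere sampled as latitude rings about the patient Y (gantry-0 beam)
    axis: the gantry-0 projection is a set of concentric regular polygons,
    exactly symmetric under 5-degree BEV rotations."""
    pts = []
    for theta in np.linspace(0.15, np.pi - 0.15, n_rings):
        phi = np.radians(np.arange(points_per_ring) * (360.0 / points_per_ring))
        r = radius * np.sin(theta)
        y = radius * np.cos(theta)
        ring = np.column_stack([r * np.cos(phi), np.full_like(phi, y), r * np.sin(phi)])
        pts.append(ring)
    return Lesion("sphere", "sphere", np.asarray(center, float) + np.concatenate(pts))


@pytest.fixture
def two_square_lesions():
    """3-D boxes projecting (gantry 0) to the two-square island fixture."""
    return [
        box_lesion("left", (-25, -15), (-1, 1), (-5, 5)),
        box_lesion("right", (15, 25), (-1, 1), (-5, 5)),
    ]


def static_arc(gantry=0.0, couch=0.0):
    """Degenerate full arc sampled with a 360-degree step: exactly one
    gantry sample — a static beam."""
    return Arc("static", couch, gantry, gantry, "CW", full=True)


STATIC_STEP = 360.0


class TestDefaultArcs:
    def test_four_arcs_at_the_standard_couch_angles(self):
        arcs = default_arcs()
        assert [a.couch_deg for a in arcs] == [0.0, 90.0, 45.0, 315.0]

    def test_couch0_arc_is_effectively_full(self):
        full = default_arcs()[0]
        assert 358.0 <= full.span_deg <= 360.0

    def test_partial_arcs_span_180(self):
        for arc in default_arcs()[1:]:
            assert arc.span_deg == 180.0


class TestSampleGantry:
    def test_ccw_inclusive_endpoints(self):
        assert sample_gantry(Arc("a", 0, 180, 0, "CCW"), 90) == [180, 90, 0]

    def test_full_arc_dedups_wrap(self):
        samples = sample_gantry(default_arcs()[0], 2)
        assert len(samples) == 180
        assert samples[0] == 181.0
        assert samples[-1] == 179.0

    def test_step_larger_than_span(self):
        assert sample_gantry(Arc("a", 0, 350, 10, "CW"), 90) == [350, 10]

    def test_cw_wraps_through_zero(self):
        assert sample_gantry(Arc("a", 0, 350, 20, "CW"), 10) == [350, 0, 10, 20]

    def test_static_arc_yields_single_sample(self):
        assert sample_gantry(static_arc(gantry=42.0), STATIC_STEP) == [42.0]


class TestScanCollimator:
    def test_two_square_fixture_prefers_90(self, hd120, two_square_lesions):
        """Island blocking: 500 mm2 bridged at collimator 0, 200 mm2 once
        the separation lies along the leaf-travel direction at 90."""
        scan = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                               gantry_step_deg=STATIC_STEP, coll_step_deg=5)
        assert scan.best_angle_deg == 90.0
        areas = dict(zip(scan.angles_deg, scan.total_areas_mm2))
        assert areas[0.0] == pytest.approx(500.0)
        assert areas[90.0] == pytest.approx(200.0)

    def test_two_square_matches_one_degree_brute_force(self, hd120,
                                                        two_square_lesions):
        grid = [float(c) for c in range(0, 166)]
        scan = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                               gantry_step_deg=STATIC_STEP, coll_step_deg=1)
        best_ref, totals_ref = collimator_brute_force(
            two_square_lesions, [0, 0, 0], [0.0], 0.0,
            list(hd120.leaf_pair_edges_mm), grid)
        assert scan.best_angle_deg == best_ref == 90.0
        assert np.allclose(scan.total_areas_mm2, totals_ref, rtol=1e-9)

    def test_sphere_is_rotation_invariant_tiebreak_zero(self, hd120):
        lesion = ring_sphere([0, 0, 0], 10.0)
        scan = scan_collimator([lesion], [0, 0, 0], static_arc(), hd120,
                               gantry_step_deg=STATIC_STEP, coll_step_deg=5)
        assert scan.best_angle_deg == 0.0
        areas = np.array(scan.total_areas_mm2)
        assert np.ptp(areas) / areas.mean() < 0.01

    def test_coarse_scan_within_discretization_gap_of_fine(self, hd120,
                                                            two_square_lesions):
        fine = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                               gantry_step_deg=STATIC_STEP, coll_step_deg=1)
        coarse = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                                 gantry_step_deg=STATIC_STEP, coll_step_deg=5)
        gap = max(abs(a - b) for a, b in zip(fine.total_areas_mm2[::5],
                                             coarse.total_areas_mm2))
        assert coarse.best_area_mm2() <= fine.best_area_mm2() + gap + 1e-9

    def test_halving_step_never_worsens_best_area(self, hd120, two_square_lesions):
        a10 = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                              gantry_step_deg=STATIC_STEP,
                              coll_step_deg=10).best_area_mm2()
        a5 = scan_collimator(two_square_lesions, [0, 0, 0], static_arc(), hd120,
                             gantry_step_deg=STATIC_STEP,
                             coll_step_deg=5).best_area_mm2()
        assert a5 <= a10 + 1e-9

    def test_aperture_is_180_periodic(self, hd120, two_square_lesions):
        """Opposed leaf banks: the aperture at collimator c equals the one
        at c +/- 180, so scanning past 165 cannot improve on [0, 165]."""
        from vmatgeo.geometry import BeamGeometry, compute_pob, rotate_to_mlc_frame
        from vmatgeo.mlc import fit_leaves

        pob = compute_pob(two_square_lesions, [0, 0, 0], BeamGeometry(0, 0))
        for c in (10.0, 40.0, 120.0, 165.0):
            a1 = fit_leaves(rotate_to_mlc_frame(pob, c), hd120).total_area_mm2
            a2 = fit_leaves(rotate_to_mlc_frame(pob, c + 180), hd120).total_area_mm2
            assert a1 == pytest.approx(a2, rel=1e-9)

    def test_cw_and_ccw_full_arcs_agree(self, hd120):
        lesions = [box_lesion("a", (-12, -4), (-4, 4), (-6, 6)),
                   box_lesion("b", (8, 18), (-2, 2), (10, 20))]
        cw = Arc("cw", 0, 181, 179, "CW")
        ccw = Arc("ccw", 0, 179, 181, "CCW")
        s1 = scan_collimator(lesions, [0, 0, 5], cw, hd120, 10, 15)
        s2 = scan_collimator(lesions, [0, 0, 5], ccw, hd120, 10, 15)
        assert np.allclose(sorted(s1.total_areas_mm2), sorted(s2.total_areas_mm2),
                           rtol=1e-9)

    def test_random_fixtures_match_brute_force(self, hd120, rng):
        """Implementation vs shapely brute force on the same grid, exact
        argmin and tie-break, across random few-lesion fixtures."""
        for _ in range(10):
            lesions = []
            for i in range(int(rng.integers(2, 5))):
                center = rng.uniform(-35, 35, 3)
                center[2] = rng.uniform(-25, 25)
                radius = rng.uniform(2, 8)
                lesions.append(Lesion(f"l{i}", f"l{i}", sphere_surface_points(
                    center, radius, 40, seed=int(rng.integers(2**31)))))
            arc = static_arc(gantry=float(rng.integers(0, 180)))
            grid = [float(c) for c in range(0, 166, 5)]
            scan = scan_collimator(lesions, [0, 0, 0], arc, hd120,
                                   gantry_step_deg=STATIC_STEP, coll_step_deg=5)
            best_ref, totals_ref = collimator_brute_force(
                lesions, [0, 0, 0], sample_gantry(arc, STATIC_STEP), arc.couch_deg,
                list(hd120.leaf_pair_edges_mm), grid)
            assert scan.best_angle_deg == best_ref
            assert np.allclose(scan.total_areas_mm2, totals_ref, rtol=1e-9)


class TestOptimizePlanGeometry:
    def test_structure_one_cluster_four_arcs(self, hd120):
        from vmatgeo.clustering import optimize_isocenters

        lesions = [box_lesion("a", (-15, -5), (-5, 5), (-5, 5)),
                   box_lesion("b", (5, 15), (-5, 5), (10, 20))]
        result = optimize_isocenters(lesions, hd120.default_criteria)
        plans = optimize_plan_geometry(result, None, hd120,
                                       {l.id: l for l in lesions},
                                       gantry_step_deg=30, coll_step_deg=30)
        assert len(plans) == 1
        assert len(plans[0].arcs) == 4
        for ag in plans[0].arcs:
            assert -40 <= ag.jaws.y1_mm < ag.jaws.y2_mm <= 40
            min_area = min(ag.scan.total_areas_mm2)
            assert ag.scan.total_areas_mm2[
                ag.scan.angles_deg.index(ag.collimator_deg)
            ] <= min_area * (1 + 1e-9) + 1e-9

    def test_rerun_is_bit_identical(self, hd120):
        from vmatgeo.clustering import optimize_isocenters

        lesions = [box_lesion("a", (-15, -5), (-5, 5), (-5, 5))]
        result = optimize_isocenters(lesions, hd120.default_criteria)
        kwargs = dict(gantry_step_deg=30, coll_step_deg=30)
        p1 = optimize_plan_geometry(result, None, hd120, {"a": lesions[0]}, **kwargs)
        p2 = optimize_plan_geometry(result, None, hd120, {"a": lesions[0]}, **kwargs)
        assert p1[0].arcs[0].scan.total_areas_mm2 == p2[0].arcs[0].scan.total_areas_mm2
        assert p1[0].arcs[0].collimator_deg == p2[0].arcs[0].collimator_deg
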