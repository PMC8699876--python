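import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqueprop.errors import GeometryError, InvalidContourError, LoftError
from plaqueprop.geometry import (
    Contour,
    ContourStack,
    contour_area,
    contour_centroid,
    loft_surface,
    make_error_models,
    perturb_vessel,
    scale_contour,
)
from plaqueprop.synthetic import VesselRecipe, generate_vessel

from conftest import regular_polygon


def star_polygon(radii: list[float]) -> Contour:
    """Simple (star-shaped) polygon from per-vertex radii at sorted angles."""
    n = len(radii)
    theta = 2 * np.pi * np.arange(n) / n
    r = np.asarray(radii)
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)]))


class TestCentroid:
    def test_unit_square(self, unit_square):
        assert np.allclose(contour_centroid(unit_square), [0.5, 0.5, 0.0])

    def test_translation_linearity(self, unit_square):
        shift = np.array([3.0, -2.0, 7.0])
        moved = Contour(unit_square.points + shift)
        assert np.allclose(contour_centroid(moved), contour_centroid(unit_square) + shift)

    def test_regular_72gon_offcentre(self):
        c = regular_polygon(72, radius=2.0, center=(1.0, 1.0, 0.0))
        assert np.allclose(contour_centroid(c), [1.0, 1.0, 0.0], atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidContourError):
            Contour(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))


class TestArea:
    def test_unit_square(self, unit_square):
        assert contour_area(unit_square) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("radius", [1.0, 2.5])
    def test_regular_72gon_closed_form(self, radius):
        # enclosed area of a regular m-gon with circumradius r: (m/2) r^2 sin(2pi/m)
        expected = 36.0 * radius**2 * np.sin(2.0 * np.pi / 72.0)
        assert contour_area(regular_polygon(72, radius)) == pytest.approx(expected, rel=1e-12)
        if radius == 1.0:
            assert expected == pytest.approx(3.137607, abs=5e-6)

    def test_similarity_scaling(self, unit_square):
        scaled = Contour(unit_square.points * 3.0)
        assert contour_area(scaled) == pytest.approx(9.0 * contour_area(unit_square))

    def test_collinear_ring_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(InvalidContourError):
            contour_area(Contour(pts))


class TestScaleContour:
    @pytest.mark.parametrize("factor", [0.9, 0.95, 1.0, 1.05, 1.1])
    def test_area_contract_on_regular_ring(self, factor):
        c = regular_polygon(72, 1.3, center=(0.4, -0.2, 5.0))
        scaled = scale_contour(c, factor)
        assert contour_area(scaled) / contour_area(c) == pytest.approx(factor, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        radii=st.lists(st.floats(0.5, 2.0), min_size=5, max_size=40),
        factor=st.floats(0.5, 2.0),
    )
    def test_area_contract_and_centroid_on_star_polygons(self, radii, factor):
        c = star_polygon(radii)
        scaled = scale_contour(c, factor)
        assert contour_area(scaled) / contour_area(c) == pytest.approx(factor, rel=1e-9)
        assert np.linalg.norm(scaled.centroid - c.centroid) < 1e-9

    def test_identity_factor(self, unit_square):
        assert np.allclose(scale_contour(unit_square, 1.0).points, unit_square.points, atol=1e-12)

    def test_vertex_radii_sqrt_of_area_factor(self):
        c = regular_polygon(72, 1.0)
        scaled = scale_contour(c, 1.05)
        radii = np.linalg.norm(scaled.points[:, :2], axis=1)
        assert np.allclose(radii, 1.024695, atol=1e-6)

    @pytest.mark.parametrize("factor", [0.0, -0.5])
    def test_nonpositive_factor_rejected(self, unit_square, factor):
        with pytest.raises(GeometryError):
            scale_contour(unit_square, factor)


class TestPerturbVessel:
    def test_twenty_vessels_yield_sixty_models(self):
        models = []
        for i in range(20):
            v = generate_vessel(VesselRecipe(length=5.0, seed=i, case_id=f"v{i}"))
            models.extend(make_error_models(v, 0.05))
        assert len(models) == 60
        tags = {m.perturbation_tag for m in models}
        assert tags == {"original", "overestimated", "underestimated"}

    def test_under_then_over_is_not_identity(self):
        # (1 - e)(1 + e) = 1 - e^2 < 1: the perturbation is not involutive
        assert 0.95 * 1.05 == pytest.approx(0.9975)
        v = generate_vessel(VesselRecipe(length=5.0, seed=0))
        under = perturb_vessel(v, 0.05, "under")
        under_original = type(under)(under.case_id, under.lumen, under.outer_wall, "original")
        back = perturb_vessel(under_original, 0.05, "over")
        ratio = back.lumen.areas() / v.lumen.areas()
        assert np.allclose(ratio, 0.9975, rtol=1e-9)

    def test_per_station_area_ratio(self, triplet):
        original, over, under = triplet
        assert np.allclose(under.lumen.areas() / original.lumen.areas(), 0.95, rtol=1e-9)
        assert np.allclose(over.outer_wall.areas() / original.outer_wall.areas(), 1.05, rtol=1e-9)

    def test_structure_preserved(self, triplet):
        original, over, _ = triplet
        assert len(over.lumen) == len(original.lumen)
        assert over.lumen.points_per_contour == original.lumen.points_per_contour
        assert np.allclose(over.lumen.centroids(), original.lumen.centroids(), atol=1e-9)
        over.lumen.validate(spacing_tol=1e-6)

    @pytest.mark.parametrize("error", [0.0, 1.0, 1.5])
    def test_error_out_of_range_rejected(self, straight_vessel, error):
        with pytest.raises(GeometryError):
            perturb_vessel(straight_vessel, error, "under")


class TestLoft:
    def test_counting(self):
        stack = ContourStack(
            (regular_polygon(72, 1.0, (0, 0, 0)), regular_polygon(72, 1.0, (0, 0, 0.5)))
        )
        mesh = loft_surface(stack)
        assert len(mesh.vertices) == 144
        assert len(mesh.triangles) == 144

    def test_cylinder_surface_area(self, straight_vessel):
        mesh = loft_surface(straight_vessel.lumen)
        r = np.sqrt(straight_vessel.lumen.areas()[0] / np.pi)
        expected = 2.0 * np.pi * r * 30.0
        assert mesh.surface_area == pytest.approx(expected, rel=0.01)

    def test_perturbation_preserves_topology(self, triplet):
        original, over, _ = triplet
        m0, m1 = loft_surface(original.lumen), loft_surface(over.lumen)
        assert np.array_equal(m0.triangles, m1.triangles)

    def test_mismatched_point_counts_rejected(self):
        stack = ContourStack(
            (regular_polygon(72), regular_polygon(36, center=(0.0, 0.0, 0.5)))
        )
        with pytest.raises(LoftError):
            loft_surface(stack)
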