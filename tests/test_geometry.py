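"""Unit-cell geometry: wall profiles, descriptors, areas, degeneracies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampersim.geometry import (
    GeometrySpec,
    InvalidSpecError,
    Shape,
    build_unit_cell,
    filling_height,
    hole_radius_profile,
    hole_radius_slope,
    perforation_level,
    throat_from_alpha,
    wall_arclength,
    wall_polyline,
)

B = dict(b1=2.0, b2=4.0, b4=14.0, b5=16.0)


def spec(shape, a2=0.1, a3=0.3, b3=9.0, flip=False):
    return GeometrySpec(shape, a2, a3, B["b1"], B["b2"], b3, B["b4"], B["b5"],
                        flip_orientation=flip)


class TestDescriptors:
    def test_perforation_level_endpoints(self):
        assert perforation_level(1.0) == 0.0
        assert perforation_level(0.1) == pytest.approx(0.9)
        assert throat_from_alpha(0.5) == 0.5

    @given(st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_perforation_roundtrip(self, a2):
        assert throat_from_alpha(perforation_level(a2)) == pytest.approx(a2, rel=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            perforation_level(0.0)
        with pytest.raises(InvalidSpecError):
            throat_from_alpha(1.0)
        with pytest.raises(InvalidSpecError):
            filling_height(1.5, 4.0, 14.0)

    def test_filling_height(self):
        assert filling_height(0.0, 4.0, 14.0) == 4.0
        assert filling_height(1.0, 4.0, 14.0) == 14.0
        assert filling_height(0.5, 4.0, 14.0) == 9.0
        g = spec(Shape.CONE_UP, b3=9.0)
        assert g.gamma == pytest.approx(0.5)
        assert g.alpha == pytest.approx(0.9)


class TestWallProfile:
    """Orientation convention: upward = throat (a2) at the hole top z=b4.

    With flip_orientation=True the upward/downward roles are exchanged
    (narrow end of 'up' shapes at z=b2)."""

    def test_cone_endpoints_default_convention(self):
        g = spec(Shape.CONE_UP)
        assert hole_radius_profile(Shape.CONE_UP, B["b4"], g) == pytest.approx(0.1)
        assert hole_radius_profile(Shape.CONE_UP, B["b2"], g) == pytest.approx(0.3)

    def test_cone_endpoints_flipped_convention(self):
        g = spec(Shape.CONE_UP, flip=True)
        assert hole_radius_profile(Shape.CONE_UP, B["b2"], g) == pytest.approx(0.1)
        mid = 0.5 * (B["b2"] + B["b4"])
        assert hole_radius_profile(Shape.CONE_UP, mid, g) == pytest.approx(0.2)

    def test_cone_linear_midpoint(self):
        g = spec(Shape.CONE_DOWN)
        mid = 0.5 * (B["b2"] + B["b4"])
        assert hole_radius_profile(Shape.CONE_DOWN, mid, g) == pytest.approx(0.2)

    def test_cylinder_constant(self):
        g = spec(Shape.CYLINDER, a2=0.25, a3=0.25)
        z = np.linspace(B["b2"], B["b4"], 7)
        assert hole_radius_profile(Shape.CYLINDER, z, g) == pytest.approx(0.25)

    def test_paraboloid_down_endpoints_flipped(self):
        # flipped convention: downward narrows with increasing z
        g = spec(Shape.PARABOLOID_DOWN, flip=True)
        assert hole_radius_profile(g.shape, B["b2"], g) == pytest.approx(0.3)
        assert hole_radius_profile(g.shape, B["b4"], g) == pytest.approx(0.1)

    @pytest.mark.parametrize("shape", [s for s in Shape if s is not Shape.CYLINDER])
    def test_profile_bounded_and_continuous(self, shape):
        g = spec(shape)
        z = np.linspace(B["b2"], B["b4"], 257)
        a = hole_radius_profile(shape, z, g)
        assert np.all(a >= g.a2 - 1e-12) and np.all(a <= g.a3 + 1e-12)
        assert np.max(np.abs(np.diff(a))) < 0.01  # no jumps
        ends = sorted([a[0], a[-1]])
        assert ends == pytest.approx([g.a2, g.a3])

    @pytest.mark.parametrize(
        "up, down",
        [
            (Shape.CONE_UP, Shape.CONE_DOWN),
            (Shape.PARABOLOID_UP, Shape.PARABOLOID_DOWN),
            (Shape.CONCAVE_PARABOLOID_UP, Shape.CONCAVE_PARABOLOID_DOWN),
        ],
    )
    def test_up_down_mirror_images(self, up, down):
        gu, gd = spec(up), spec(down)
        z = np.linspace(B["b2"], B["b4"], 101)
        z_mirror = B["b2"] + B["b4"] - z
        np.testing.assert_allclose(
            hole_radius_profile(up, z, gu),
            hole_radius_profile(down, z_mirror, gd),
            rtol=1e-13,
        )

    def test_vertex_placement(self):
        # paraboloid: zero slope at the narrow end; concave: at the wide end
        gp = spec(Shape.PARABOLOID_UP)  # narrow at top
        gc = spec(Shape.CONCAVE_PARABOLOID_UP)
        assert hole_radius_slope(gp.shape, B["b4"], gp) == pytest.approx(0.0)
        assert hole_radius_slope(gc.shape, B["b2"], gc) == pytest.approx(0.0)

    def test_domain_errors(self):
        g = spec(Shape.CONE_UP)
        with pytest.raises(ValueError):
            hole_radius_profile(Shape.CONE_UP, B["b2"] - 1.0, g)
        with pytest.raises(InvalidSpecError):
            spec(Shape.CONE_UP, a2=0.4, a3=0.3)


class TestUnitCell:
    def test_study_layer_thicknesses(self):
        g = spec(Shape.CYLINDER, a2=0.1, a3=0.1)
        thick = (g.b1, g.b2 - g.b1, g.b4 - g.b2, g.b5 - g.b4)
        assert thick == (2.0, 2.0, 10.0, 2.0)

    def test_alpha0_collapses_to_slabs(self):
        cell = build_unit_cell(GeometrySpec(Shape.CYLINDER, 1.0, 1.0, 2, 4, 9, 14, 16))
        assert cell.full_width
        assert "alpha=0" in cell.degenerate
        assert cell.total_area() == pytest.approx(16.0)

    def test_gamma_degenerate_reported(self):
        lo = build_unit_cell(spec(Shape.CONE_UP, b3=4.0))
        hi = build_unit_cell(spec(Shape.CONE_UP, b3=14.0))
        assert "gamma=0" in lo.degenerate and "carrier_bottom" in lo.degenerate
        assert "gamma=1" in hi.degenerate and "carrier_top" in hi.degenerate

    @pytest.mark.parametrize("shape", list(Shape))
    def test_region_areas_match_quadrature(self, shape):
        g = spec(shape, a2=0.1, a3=0.3 if shape is not Shape.CYLINDER else 0.1)
        cell = build_unit_cell(g)
        # independent oracle: fine trapezoid quadrature of the wall profile
        z = np.linspace(g.b2, g.b3, 20001)
        hole2 = np.trapezoid(hole_radius_profile(shape, z, g), z)
        z = np.linspace(g.b3, g.b4, 20001)
        hole3 = np.trapezoid(hole_radius_profile(shape, z, g), z)
        assert cell.region_area(1) == pytest.approx(2.0)
        assert cell.region_area(2) == pytest.approx(2.0 + hole2, rel=1e-9)
        assert cell.region_area(3) == pytest.approx(2.0 + hole3, rel=1e-9)

    def test_wall_polyline_error_second_order(self):
        g = spec(Shape.CONCAVE_PARABOLOID_UP)
        exact = wall_arclength(g)

        def polyline_len(n):
            p = wall_polyline(g, n)
            return np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))

        e1 = exact - polyline_len(16)
        e2 = exact - polyline_len(32)
        assert e1 > 0 and e2 > 0
        assert e1 / e2 >= 2.0  # halving h cuts the boundary error >= 2x
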