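"""Cavalieri volumes, chord-based length/width, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnscore import (
    ContourStack,
    generate_ellipsoid_contours,
    length_width,
    measure_stack,
    polygon_area,
    volume_from_stack,
    volume_ratio,
)
from lnscore.errors import DegenerateGeometryError, InvalidInputError
from lnscore.morphometry import _densify, _hull_diameter

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def ellipse(a, b, n=512, phase=0.0):
    th = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack((a * np.cos(th), b * np.sin(th)))


def star_polygon(rng, n):
    """Random star-shaped (hence simple) polygon."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 2.0, n)
    return np.column_stack((r * np.cos(th), r * np.sin(th)))


class TestPolygonArea:
    def test_unit_square_and_orientation_invariance(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)
        assert polygon_area(UNIT_SQUARE[::-1]) == pytest.approx(1.0)

    def test_regular_256gon_approaches_circle_area(self):
        # inscribed-polygon limit, against the brute-force cross-product sum
        poly = ellipse(1.0, 1.0, n=256)
        brute = 0.5 * abs(
            sum(
                poly[i, 0] * poly[(i + 1) % 256, 1]
                - poly[(i + 1) % 256, 0] * poly[i, 1]
                for i in range(256)
            )
        )
        assert polygon_area(poly) == pytest.approx(brute, rel=1e-12)
        assert polygon_area(poly) == pytest.approx(np.pi, rel=5e-4)

    def test_too_few_vertices_raises(self):
        with pytest.raises(DegenerateGeometryError):
            polygon_area(np.array([[0.0, 0.0], [1.0, 0.0]]))

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10.0),
    )
    def test_rigid_motion_invariance_and_scaling(self, seed, angle, scale):
        poly = star_polygon(np.random.default_rng(seed), 12)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = poly @ rot.T + np.array([3.7, -1.2])
        assert polygon_area(moved) == pytest.approx(polygon_area(poly), rel=1e-9)
        assert polygon_area(scale * poly) == pytest.approx(
            scale**2 * polygon_area(poly), rel=1e-9
        )


class TestVolume:
    def test_single_slice_slab(self):
        stack = ContourStack([UNIT_SQUARE], spacing_mm=0.038)
        assert volume_from_stack(stack) == pytest.approx(0.038)

    @pytest.mark.parametrize(
        "semiaxes",
        [(1.0, 1.0, 1.0), (2.5, 1.5, 1.2), (2.0, 1.0, 0.8), (0.6, 0.5, 0.5)],
    )
    def test_ellipsoid_within_one_percent_of_analytic(self, semiaxes):
        stack = generate_ellipsoid_contours(semiaxes, 0.038, seed=3)
        analytic = 4.0 / 3.0 * np.pi * np.prod(semiaxes)
        assert volume_from_stack(stack) == pytest.approx(analytic, rel=0.01)

    def test_refinement_convergence(self):
        # halving the spacing changes the estimate by < 0.5%
        coarse = volume_from_stack(
            generate_ellipsoid_contours((2.0, 1.2, 1.0), 0.076, seed=5)
        )
        fine = volume_from_stack(
            generate_ellipsoid_contours((2.0, 1.2, 1.0), 0.038, seed=5)
        )
        assert abs(fine - coarse) / fine < 0.005

    def test_volume_scales_cubically(self):
        base = generate_ellipsoid_contours((1.5, 1.0, 0.8), 0.038, seed=9)
        v1 = volume_from_stack(base)
        scaled = ContourStack(
            [2.0 * s for s in base.slices], spacing_mm=2.0 * base.spacing_mm
        )
        assert volume_from_stack(scaled) == pytest.approx(8.0 * v1, rel=1e-9)


class TestLengthWidth:
    def test_rectangle_diameter_is_the_diagonal(self):
        rect = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 1.0], [0.0, 1.0]])
        stack = ContourStack([rect], spacing_mm=0.038)
        length, width, idx = length_width(stack)
        assert length == pytest.approx(np.sqrt(17.0), rel=1e-3)
        assert width == pytest.approx(1.94, rel=0.02)
        assert idx == 0
        m = measure_stack(stack)
        assert m.lw_ratio == pytest.approx(2.12, rel=0.02)
        assert not m.is_round

    def test_circle_is_round_with_unit_ratio(self):
        stack = ContourStack([ellipse(1.0, 1.0)], spacing_mm=0.038)
        m = measure_stack(stack)
        assert m.length_mm == pytest.approx(2.0, rel=1e-3)
        assert m.lw_ratio == pytest.approx(1.0, abs=0.01)
        assert m.is_round

    @pytest.mark.parametrize(
        "b_semi,expect_round", [(0.95, True), (0.6, False)]
    )
    def test_ellipse_roundness_classification(self, b_semi, expect_round):
        stack = ContourStack([ellipse(1.5, b_semi)], spacing_mm=0.038)
        m = measure_stack(stack)
        assert m.lw_ratio == pytest.approx(1.5 / b_semi, rel=0.01)
        assert m.is_round is expect_round

    def test_length_never_below_width(self, rng):
        for _ in range(20):
            stack = ContourStack([star_polygon(rng, 10)], spacing_mm=0.1)
            length, width, _ = length_width(stack)
            assert length >= width

    def test_lw_ratio_rigid_motion_invariant(self, rng):
        poly = star_polygon(np.random.default_rng(4), 14)
        rot = np.array(
            [[np.cos(1.1), -np.sin(1.1)], [np.sin(1.1), np.cos(1.1)]]
        )
        a = measure_stack(ContourStack([poly], spacing_mm=0.1))
        b = measure_stack(
            ContourStack([poly @ rot.T + np.array([5.0, 2.0])], spacing_mm=0.1)
        )
        assert b.lw_ratio == pytest.approx(a.lw_ratio, rel=0.02)

    def test_hull_diameter_matches_exhaustive_chord_search(self, rng):
        # oracle equivalence on small polygons: hull-pair search vs O(n^2)
        for _ in range(50):
            pts = _densify(star_polygon(rng, rng.integers(4, 13)), 64)
            length, _ = _hull_diameter(pts)
            diff = pts[:, None, :] - pts[None, :, :]
            brute = np.hypot(diff[..., 0], diff[..., 1]).max()
            assert length == pytest.approx(brute, rel=1e-12)

    def test_all_degenerate_slices_raise(self):
        stack = ContourStack(
            [np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])], spacing_mm=0.038
        )
        with pytest.raises(DegenerateGeometryError):
            length_width(stack)


class TestVolumeRatio:
    def test_group_mean_quotient(self):
        assert volume_ratio(12.076, 1.438) == pytest.approx(8.398, abs=5e-4)

    def test_equal_volumes_and_threshold_boundary(self):
        assert volume_ratio(3.3, 3.3) == pytest.approx(1.0)
        assert volume_ratio(5.0, 1.0) == pytest.approx(5.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            volume_ratio(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            volume_ratio(1.0, -2.0)
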