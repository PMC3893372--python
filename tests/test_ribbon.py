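"""Laplace solve, field-line thickness and curvature on analytic phantoms."""

import numpy as np
import pytest

from fcdmap.errors import (
    InsufficientCurveError,
    InvalidGeometryError,
)
from fcdmap.ribbon import (
    GREY,
    INNER_BOUNDARY,
    OUTER_BOUNDARY,
    ContourPair,
    curvature,
    midline_profile,
    rasterize_ribbon,
    solve_laplace,
    trace_field_line,
)
from fcdmap.synthetic import make_annulus_phantom, make_gyral_ribbon


class TestRasterize:
    def test_annulus_area_within_3pc(self, annulus_field):
        _, grid, _ = annulus_field
        assert abs(grid.ribbon_area_px / (np.pi * (70**2 - 40**2)) - 1.0) < 0.03

    def test_swapped_contours_rejected(self):
        ph = make_annulus_phantom(40, 70, 360)
        cp = ph.contour_pair
        swapped = ContourPair(cp.inner, cp.outer, cp.pixel_size, closed=True)
        with pytest.raises(InvalidGeometryError):
            rasterize_ribbon(swapped)

    def test_band_area(self, band_field):
        _, grid, _ = band_field
        # 199 px long x 20 px wide band
        assert abs(grid.ribbon_area_px - 199 * 20) < 0.06 * 199 * 20

    def test_boundary_labels_present(self, annulus_field):
        _, grid, _ = annulus_field
        assert (grid.labels == INNER_BOUNDARY).sum() > 100
        assert (grid.labels == OUTER_BOUNDARY).sum() > 100


class TestSolveLaplace:
    def test_boundary_values_and_maximum_principle(self, annulus_field):
        _, grid, fld = annulus_field
        assert np.all(fld.phi[grid.labels == INNER_BOUNDARY] == 1.0)
        assert np.all(fld.phi[grid.labels == OUTER_BOUNDARY] == -1.0)
        interior = fld.phi[grid.labels == GREY]
        assert interior.max() < 1.0 and interior.min() > -1.0

    def test_annulus_matches_log_solution(self, annulus_field):
        _, grid, fld = annulus_field
        rr, cc = np.nonzero(grid.labels == GREY)
        r = np.hypot(cc + fld.origin[0] - 75.0, rr + fld.origin[1] - 75.0)
        phi = fld.phi[rr, cc]
        A = np.column_stack([np.ones_like(r), np.log(r)])
        coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
        assert np.abs(phi - A @ coef).max() < 0.02

    def test_band_phi_linear(self, band_field):
        _, grid, fld = band_field
        rr, cc = np.nonzero(grid.labels == GREY)
        y = rr + fld.origin[1]
        A = np.column_stack([np.ones_like(y), y])
        coef, *_ = np.linalg.lstsq(A, fld.phi[rr, cc], rcond=None)
        assert np.abs(fld.phi[rr, cc] - A @ coef).max() < 0.01

    def test_all_boundary_grid_returns_boundary_values(self):
        from fcdmap.ribbon import GreyMatterGrid

        lab = np.zeros((5, 7), np.uint8)
        lab[1, 1:6] = INNER_BOUNDARY
        lab[3, 1:6] = OUTER_BOUNDARY
        fld = solve_laplace(GreyMatterGrid(lab, (0.0, 0.0), 1.0, 1.0))
        assert np.all(fld.phi[1, 1:6] == 1.0)
        assert np.all(fld.phi[3, 1:6] == -1.0)

    def test_discrete_laplacian_small_on_deep_interior(self, annulus_field):
        _, grid, fld = annulus_field
        phi = np.where(np.isfinite(fld.phi), fld.phi, 0.0)
        lap = (
            np.roll(phi, 1, 0) + np.roll(phi, -1, 0) + np.roll(phi, 1, 1) + np.roll(phi, -1, 1)
            - 4 * phi
        )
        from scipy import ndimage

        deep = ndimage.binary_erosion(grid.labels == GREY, iterations=2)
        assert np.abs(lap[deep]).max() < 1e-6


class TestFieldLines:
    def test_annulus_line_is_radial_with_correct_length(self, annulus_field):
        _, _, fld = annulus_field
        path, length = trace_field_line(fld, (75.0 + 52.9, 75.0))
        assert abs(length - 300.0) < 6.0  # 2%
        # radial: all path points near the horizontal line y = 75
        assert np.abs(path[:, 1] - 75.0).max() < 1.0

    def test_band_line_length(self, band_field):
        _, _, fld = band_field
        _, length = trace_field_line(fld, (100.0, 40.0))
        assert abs(length - 200.0) < 2.0  # 1%

    def test_field_lines_do_not_cross(self, annulus_field):
        from shapely.geometry import LineString

        _, _, fld = annulus_field
        paths = []
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            x = 75.0 + 52.9 * np.cos(ang)
            y = 75.0 + 52.9 * np.sin(ang)
            path, _ = trace_field_line(fld, (x, y))
            paths.append(LineString(path))
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                assert not paths[i].crosses(paths[j])

    def test_start_outside_grey_rejected(self, annulus_field):
        _, _, fld = annulus_field
        with pytest.raises(ValueError):
            trace_field_line(fld, (75.0, 75.0))  # annulus hole

    def test_thickness_symmetry_of_two_sided_trace(self, annulus_field):
        # summing the two one-sided traces equals the full line length
        _, _, fld = annulus_field
        from fcdmap.ribbon import _trace_batch

        rc = fld.to_rc(np.array([[75.0 + 52.9, 75.0]]))
        li, _ = _trace_batch(fld, rc, +1)
        lo, _ = _trace_batch(fld, rc, -1)
        _, full = trace_field_line(fld, (75.0 + 52.9, 75.0))
        assert abs((li[0] + lo[0]) * 10.0 - full) < 0.01 * full


class TestMidlineProfile:
    def test_annulus_thickness_within_2pc(self, annulus_profile):
        assert annulus_profile.t.min() > 294.0
        assert annulus_profile.t.max() < 306.0

    def test_annulus_midline_radius(self, annulus_profile):
        r = np.hypot(annulus_profile.points[:, 0] - 75.0, annulus_profile.points[:, 1] - 75.0)
        assert np.abs(r / np.sqrt(40.0 * 70.0) - 1.0).max() < 0.02

    def test_arc_strictly_increasing_and_t_positive(self, annulus_profile):
        assert np.all(np.diff(annulus_profile.arc_s) > 0)
        assert np.all(annulus_profile.t > 0)

    def test_focus_halves_measured_thickness(self):
        n = 500
        cl = np.column_stack([np.arange(n, dtype=float) + 5, np.full(n, 120.0)])
        ph = make_gyral_ribbon(
            cl, np.full(n, 40.0), [(1500.0, 3500.0, 0.5)], pixel_size=10.0, taper=200.0
        )
        fld = solve_laplace(rasterize_ribbon(ph.contour_pair))
        prof = midline_profile(fld, sample_step=50.0, trim=400.0)
        in_focus = ph.in_focus(prof.points)
        core = in_focus & (np.abs(prof.arc_s - 2500.0) < 600.0)  # tapered core
        assert core.sum() > 5
        assert np.abs(prof.t[core] / 200.0 - 1.0).max() < 0.05
        far = ~in_focus & (np.abs(prof.arc_s - 2500.0) > 1500.0)
        assert np.abs(prof.t[far] / 400.0 - 1.0).max() < 0.05

    def test_refinement_consistency_under_grid_halving(self):
        ph = make_annulus_phantom(40, 70, 720, pixel_size=10.0)
        t_means = []
        for spacing in (1.0, 0.5):
            fld = solve_laplace(rasterize_ribbon(ph.contour_pair, grid_spacing=spacing))
            prof = midline_profile(fld, sample_step=50.0)
            t_means.append(prof.t.mean())
        assert abs(t_means[0] / t_means[1] - 1.0) < 0.01


class TestCurvature:
    def test_circle_kappa_signed(self, annulus_profile):
        # midline radius ~52.92 px at 10 um/px -> +1.89/mm, crest-positive
        kap = annulus_profile.kappa
        assert np.abs(kap / (1000.0 / (np.sqrt(2800.0) * 10.0)) - 1.0).max() < 0.05

    def test_straight_line_zero(self):
        pts = np.column_stack([np.linspace(0, 100, 50), np.full(50, 3.0)])
        kap = curvature(pts, window=200.0, pixel_size=10.0)
        assert np.abs(kap).max() < 1e-6

    def test_sinusoid_crest_matches_analytic(self):
        # y = A sin(x / L): kappa at the crest = A / L^2 (y' = 0 there)
        A, L = 30.0, 40.0
        x = np.linspace(0, 2 * np.pi * L, 800)
        pts = np.column_stack([x, A * np.sin(x / L)])
        kap = curvature(pts, window=30.0, pixel_size=1.0)
        crest = np.argmin(np.abs(x - np.pi / 2 * L))
        expect = A / L**2 * 1000.0  # 1/mm with pixel_size=1 um
        assert abs(abs(kap[crest]) / expect - 1.0) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientCurveError):
            curvature(np.array([[0.0, 0.0], [1.0, 1.0]]), window=10.0)
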