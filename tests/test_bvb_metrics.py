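"""Wall morphometry, bifurcation angles, fractal dimension and cuffing rule."""

import numpy as np
import pytest

from bvbquant.bvb_metrics import (
    AirwayMeasurement,
    MeasurementError,
    bifurcation_angle,
    box_counting_fd,
    branch_direction,
    compute_avi,
    detect_cuffing,
    find_narrowest_section,
    measure_wall,
    peribronchial_roi,
)
from bvbquant.core_volume import Centerline, VoxelVolume
from bvbquant.reformat import CrossSection, ObliquePlane, curved_planar_reformation, resample_plane
from bvbquant.synthetic_data import (
    AirwayPhantomSpec,
    CuffSpec,
    make_airway_phantom,
    sierpinski_carpet,
)

from conftest import axial_plane, median_reference_walls, straight_z_centerline


def synthetic_annulus_section(
    inner_r=2.0, outer_r=3.0, pixel=0.25, size_mm=16.0,
    lumen=-1000.0, wall=40.0, parench=-850.0,
):
    """Analytic 2D annulus cross-section (no volume resampling involved)."""
    n = int(size_mm / pixel) + 1
    c = (n - 1) / 2
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(ii - c, jj - c) * pixel
    img = np.full((n, n), parench)
    img[r < outer_r] = wall
    img[r < inner_r] = lumen
    return CrossSection(
        image=img, pixel_size=pixel, center_world=np.zeros(3),
        normal=np.array([0, 0, 1.0]), u_axis=np.array([1.0, 0, 0]),
        v_axis=np.array([0, 1.0, 0]),
    )


class TestMeasureWall:
    def test_stage1_design_point_recovered(self, stage1_section):
        m = measure_wall(stage1_section)
        assert m.wt_d_ratio == pytest.approx(0.26, abs=0.01)
        assert m.inner_diameter_d == pytest.approx(4.0, abs=0.15)

    def test_ratio_scale_invariance(self):
        vol = make_airway_phantom(
            AirwayPhantomSpec(lumen_diameter_mm=8.0, wall_thickness_mm=2.08)
        )
        m = measure_wall(resample_plane(vol, axial_plane(extent=19.0)))
        assert m.wt_d_ratio == pytest.approx(0.26, abs=0.01)

    def test_noisy_stage3_recovery_over_seeds(self):
        vals = []
        for seed in range(20):
            vol = make_airway_phantom(
                AirwayPhantomSpec(
                    lumen_diameter_mm=4.0, wall_thickness_mm=1.40,
                    noise_sd_hu=12.4, seed=seed,
                )
            )
            vals.append(measure_wall(resample_plane(vol, axial_plane())).wt_d_ratio)
        assert np.mean(vals) == pytest.approx(0.35, abs=0.02)

    def test_in_plane_rotation_invariance(self, stage1_volume):
        ratios = []
        for k in range(10):
            th = 2 * np.pi * k / 10
            u = np.array([np.cos(th), np.sin(th), 0.0])
            v = np.array([-np.sin(th), np.cos(th), 0.0])
            plane = ObliquePlane(center=np.zeros(3), u_axis=u, v_axis=v,
                                 extent=(13.0, 13.0), pixel_size=0.2)
            ratios.append(measure_wall(resample_plane(stage1_volume, plane)).wt_d_ratio)
        assert max(ratios) - min(ratios) <= 0.01

    def test_no_wall_raises_with_diagnostics(self):
        img = np.full((61, 61), -1000.0)  # pure air: no wall anywhere
        sec = CrossSection(image=img, pixel_size=0.25, center_world=np.zeros(3),
                           normal=np.array([0, 0, 1.0]), u_axis=np.array([1.0, 0, 0]),
                           v_axis=np.array([0, 1.0, 0]))
        with pytest.raises(MeasurementError):
            measure_wall(sec)

    def test_seed_in_wall_rejected(self, stage1_section):
        ci, cj = stage1_section.center_px
        wall_px = (int(ci), int(cj + 2.5 / stage1_section.pixel_size))
        with pytest.raises(MeasurementError):
            measure_wall(stage1_section, lumen_seed=wall_px)


def stenosed_tube_sections(min_d=3.0, base_d=4.0, wall=1.0, z_min=0.0, z_max=20.0,
                           stenosis_z=10.0, pixel=0.2, step=1.0):
    """Axial sections of a tube whose lumen narrows smoothly to ``min_d``."""
    sections = []
    n = int(16.0 / pixel) + 1
    c = (n - 1) / 2
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rr = np.hypot(ii - c, jj - c) * pixel
    for z in np.arange(z_min, z_max + 1e-9, step):
        d = base_d - (base_d - min_d) * np.exp(-((z - stenosis_z) ** 2) / 8.0)
        img = np.full((n, n), -850.0)
        img[rr < d / 2 + wall] = 40.0
        img[rr < d / 2] = -1000.0
        sec = CrossSection(image=img, pixel_size=pixel, center_world=np.array([0, 0, z]),
                           normal=np.array([0, 0, 1.0]), u_axis=np.array([1.0, 0, 0]),
                           v_axis=np.array([0, 1.0, 0]), arc_position=float(z))
        sections.append(sec)
    return sections


class TestNarrowestSection:
    def test_stenosis_located_and_measured(self):
        stack = stenosed_tube_sections()
        sec, m = find_narrowest_section(stack)
        assert m.arc_position == pytest.approx(10.0, abs=1.0)
        assert m.inner_diameter_d == pytest.approx(3.0, abs=0.1)

    def test_tie_broken_by_first_section(self):
        stack = stenosed_tube_sections(min_d=4.0)  # constant diameter
        sec, m = find_narrowest_section(stack)
        assert m.arc_position == stack[0].arc_position

    def test_needs_three_sections(self):
        with pytest.raises(ValueError):
            find_narrowest_section(stenosed_tube_sections()[:2])


class TestBifurcationAngle:
    def test_orthogonal_vectors(self):
        assert bifurcation_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_constructed_rotation(self):
        th = np.radians(110.0)
        assert bifurcation_angle([0, 0, 1], [np.sin(th), 0, np.cos(th)]) == pytest.approx(110.0)

    def test_identical_vectors(self):
        assert bifurcation_angle([0.3, 0.4, 0.5], [0.3, 0.4, 0.5]) == pytest.approx(0.0, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_angle([0, 0, 0], [1, 0, 0])


class TestBranchDirection:
    def test_straight_branch_exact(self):
        cl = Centerline(np.outer(np.linspace(0.5, 9.5, 10), [0, 0, 1.0]))
        np.testing.assert_allclose(branch_direction(cl, [0, 0, 0]), [0, 0, 1.0], atol=1e-12)

    def test_jittered_branch_within_two_degrees(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.linspace(0.5, 9.5, 19)
            pts = np.outer(t, [0, 0, 1.0]) + rng.normal(0, 0.1, (19, 3))
            d = branch_direction(Centerline(pts), [0, 0, 0], length=10.0)
            errs.append(np.degrees(np.arccos(np.clip(abs(d[2]), -1, 1))))
        assert np.mean(errs) < 2.0

    def test_too_few_points_near_vertex(self):
        cl = Centerline(np.outer(np.linspace(50, 60, 10), [0, 0, 1.0]))
        with pytest.raises(ValueError):
            branch_direction(cl, [0, 0, 0], length=10.0)


class TestAvi:
    @pytest.mark.parametrize(
        "angle,expected", [(110.0, 0.0), (126.92, 16.92), (101.73, 8.27)]
    )
    def test_reference_deviation(self, angle, expected):
        assert compute_avi(angle) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("x", [0.0, 35.0, 95.5, 110.0, 147.2, 180.0])
    def test_symmetry_about_reference(self, x):
        r = 110.0
        if 0 <= 2 * r - x <= 180:
            assert compute_avi(x, r) == pytest.approx(compute_avi(2 * r - x, r))

    def test_range_check(self):
        with pytest.raises(ValueError):
            compute_avi(190.0)


class TestPeribronchialRoi:
    def _wall(self, inner_r=2.0, outer_r=3.0, center=(32.0, 32.0)):
        return AirwayMeasurement(
            inner_diameter_d=2 * inner_r, wall_thickness_wt=outer_r - inner_r,
            center_px=center,
        )

    def test_annulus_area_matches_analytic(self):
        sec = synthetic_annulus_section(pixel=0.25, size_mm=16.0)
        mask = peribronchial_roi(sec, self._wall(), band_mm=2.0)
        area = mask.sum() * 0.25**2
        assert area == pytest.approx(np.pi * (5.0**2 - 3.0**2), rel=0.1)

    def test_zero_band_is_empty(self):
        sec = synthetic_annulus_section()
        assert peribronchial_roi(sec, self._wall(), band_mm=0.0).sum() == 0

    def test_clipped_annulus_rejected(self):
        sec = synthetic_annulus_section(size_mm=8.0)
        with pytest.raises(MeasurementError):
            peribronchial_roi(sec, self._wall(center=(16.0, 16.0)), band_mm=6.0)


class TestBoxCountingFd:
    def test_filled_square(self):
        assert box_counting_fd(np.ones((81, 81), bool), 1.0).fd == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_carpet(self):
        res = box_counting_fd(sierpinski_carpet(4, 81), 1.0)
        assert res.fd == pytest.approx(np.log(8) / np.log(3), abs=0.05)
        assert res.fit_r2 > 0.99

    def test_single_pixel(self):
        img = np.zeros((81, 81), bool)
        img[40, 40] = True
        assert box_counting_fd(img, 1.0).fd == pytest.approx(0.0, abs=0.05)

    def test_monotone_on_nested_sets(self):
        n = 81
        point = np.zeros((n, n), bool); point[40, 40] = True
        line = np.zeros((n, n), bool); np.fill_diagonal(line, True)
        filled = np.ones((n, n), bool)
        fds = [box_counting_fd(m, 1.0).fd for m in (point, line, filled)]
        assert fds[0] <= fds[1] <= fds[2]

    def test_counts_non_increasing_with_box_size(self):
        res = box_counting_fd(sierpinski_carpet(3, 81), 1.0)
        assert np.all(np.diff(res.box_counts) <= 0)

    def test_empty_foreground(self):
        with pytest.raises(MeasurementError):
            box_counting_fd(np.zeros((81, 81), bool), 1.0)

    def test_scalar_input_needs_threshold(self):
        with pytest.raises(ValueError):
            box_counting_fd(np.zeros((81, 81)), 1.0)

    def test_too_few_scales(self):
        img = np.ones((29, 29), bool)
        with pytest.raises(ValueError):
            box_counting_fd(img, 1.0)


class TestCuffing:
    def test_full_ring_cuff_positive(self, cuffed_stack, cuffed_stack_walls):
        res = detect_cuffing(cuffed_stack, cuffed_stack_walls)
        assert res.positive
        assert res.consecutive_slices >= 4
        assert res.coverage_fraction > 0.9
        assert res.cuff_thickness_mm >= 2.0

    def test_partial_coverage_negative(self, cuffed_stack_walls):
        vol = make_airway_phantom(
            AirwayPhantomSpec(cuff=CuffSpec(thickness_mm=3.0, coverage_fraction=0.4, n_slices=5))
        )
        stack = curved_planar_reformation(vol, straight_z_centerline(), width=15.0,
                                          pixel_size=0.2, step=0.62)
        res = detect_cuffing(stack, median_reference_walls(stack))
        assert not res.positive
        assert res.coverage_fraction <= 0.5

    def test_thin_ring_negative(self):
        vol = make_airway_phantom(
            AirwayPhantomSpec(cuff=CuffSpec(thickness_mm=1.0, coverage_fraction=1.0, n_slices=5))
        )
        stack = curved_planar_reformation(vol, straight_z_centerline(), width=15.0,
                                          pixel_size=0.2, step=0.62)
        res = detect_cuffing(stack, median_reference_walls(stack))
        assert not res.positive

    def test_short_run_negative(self, cuffed_stack_walls):
        vol = make_airway_phantom(
            AirwayPhantomSpec(cuff=CuffSpec(thickness_mm=3.0, coverage_fraction=1.0, n_slices=2))
        )
        stack = curved_planar_reformation(vol, straight_z_centerline(), width=15.0,
                                          pixel_size=0.2, step=0.62)
        res = detect_cuffing(stack, median_reference_walls(stack))
        assert not res.positive

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hu_threshold": 45.0},
            {"min_coverage": 0.8},
            {"min_thickness_mm": 4.0},
            {"min_slices": 10},
        ],
    )
    def test_monotone_in_each_criterion(self, cuffed_stack, cuffed_stack_walls, kwargs):
        """Tightening any single criterion can only flip positive -> negative."""
        base = detect_cuffing(cuffed_stack, cuffed_stack_walls)
        strict = detect_cuffing(cuffed_stack, cuffed_stack_walls, **kwargs)
        assert not (strict.positive and not base.positive)

    def test_needs_enough_sections(self, cuffed_stack, cuffed_stack_walls):
        with pytest.raises(ValueError):
            detect_cuffing(cuffed_stack[:3], cuffed_stack_walls[:3])

    def test_missing_wall_counts_as_non_qualifying(self, cuffed_stack):
        res = detect_cuffing(cuffed_stack, [None] * len(cuffed_stack))
        assert not res.positive
        assert res.coverage_fraction == 0.0
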