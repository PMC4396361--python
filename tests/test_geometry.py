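"""Monitor/head geometry, patch Gaussian fits, retinotopy interpolation and
the concentric prediction."""

import numpy as np
import pytest

from tectomap.geometry import (
    MonitorGeometry,
    PatchFit,
    build_concentric_map,
    concentric_angle,
    concentric_from_angles,
    fit_head_angles,
    fit_patch_gaussian,
    interpolate_retinotopy,
    monitor_to_head_xyz,
    xyz_to_spherical,
)
from tectomap.maps import AxialMap, ScalarMap


class TestMonitorToHead:
    def test_centre_on_nose_axis(self):
        geom = MonitorGeometry()
        assert np.allclose(monitor_to_head_xyz([0.0, 0.0], geom), [0, 0, 29.5])

    def test_point_at_distance_to_the_right(self):
        geom = MonitorGeometry()
        x, y, z = monitor_to_head_xyz([29.5, 0.0], geom)
        assert x == pytest.approx(z)

    def test_pitch_90_maps_ahead_to_above(self):
        geom = MonitorGeometry(head_pitch_deg=90.0)
        x, y, z = monitor_to_head_xyz([0.0, 0.0], geom)
        assert np.allclose([x, z], 0, atol=1e-9)
        assert y == pytest.approx(29.5)

    def test_monitor_corners_analytic(self):
        geom = MonitorGeometry(width_cm=80.0, height_cm=40.0, distance_cm=20.0)
        for sx, sy in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
            corner = [sx * 40.0, sy * 20.0]
            x, y, z = monitor_to_head_xyz(corner, geom)
            az, el = xyz_to_spherical(x, y, z)
            assert az == pytest.approx(np.rad2deg(np.arctan(sx * 2.0)))
            assert el == pytest.approx(
                np.rad2deg(np.arctan(sy * 20.0 / np.hypot(40.0, 20.0)))
            )


class TestSpherical:
    def test_closed_forms(self):
        assert np.allclose(xyz_to_spherical(0.0, 0.0, 29.5), (0.0, 0.0))
        az, _ = xyz_to_spherical(5.0, 0.0, 5.0)
        assert az == pytest.approx(45.0)
        _, el = xyz_to_spherical(0.0, 5.0, 5.0)
        assert el == pytest.approx(45.0)

    def test_behind_animal_raises(self):
        with pytest.raises(ValueError, match="behind"):
            xyz_to_spherical(1.0, 1.0, -1.0)


class TestConcentricAngle:
    def test_worked_values(self):
        assert concentric_angle(1.0, 0.0) == pytest.approx(90.0)  # temporal axis: vertical
        assert concentric_angle(0.0, 1.0) == pytest.approx(0.0)  # above nose: horizontal
        assert concentric_angle(1.0, 1.0) == pytest.approx(45.0)

    def test_scale_and_point_symmetry(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        lam = rng.uniform(0.1, 10, size=1000)
        a = concentric_angle(x, y)
        assert np.allclose(concentric_angle(lam * x, lam * y), a, equal_nan=True)
        assert np.allclose(concentric_angle(-x, -y), a, equal_nan=True)

    def test_origin_undefined(self):
        with pytest.raises(ValueError, match="centre of vision"):
            concentric_angle(0.0, 0.0)


def gaussian_blob(shape, amp, centre, sigma):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    v = amp * np.exp(-(((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2) / (2 * sigma**2)))
    return ScalarMap(v, np.ones(shape, bool), "dF/F")


class TestPatchFit:
    def test_noiseless_centre_within_tenth_pixel(self):
        m = gaussian_blob((40, 40), 0.01, (17.3, 22.8), 4.0)
        fit = fit_patch_gaussian(m)
        assert fit.included
        assert abs(fit.centre_px[0] - 17.3) < 0.1
        assert abs(fit.centre_px[1] - 22.8) < 0.1

    def test_dim_patch_excluded_by_amplitude_rule(self):
        m = gaussian_blob((40, 40), 0.003, (20, 20), 4.0)
        fit = fit_patch_gaussian(m)
        assert not fit.included

    def test_amplitude_just_above_threshold_included(self):
        m = gaussian_blob((40, 40), 0.0045, (20, 20), 4.0)
        assert fit_patch_gaussian(m).included

    def test_noisy_recovery_median_under_one_pixel(self):
        rng = np.random.default_rng(31)
        errs = []
        for _ in range(100):
            centre = rng.uniform(12, 28, 2)
            m = gaussian_blob((40, 40), 0.01, centre, 4.0)
            noisy = ScalarMap(m.values + rng.normal(0, 0.0005, m.values.shape), m.mask)
            fit = fit_patch_gaussian(noisy)
            errs.append(np.hypot(fit.centre_px[0] - centre[0], fit.centre_px[1] - centre[1]))
        assert np.median(errs) < 1.0

    def test_too_few_pixels(self):
        m = ScalarMap(np.ones((4, 4)), np.ones((4, 4), bool))
        assert not fit_patch_gaussian(m).included


def corner_fits(shape, monitor_extent=20.0):
    """Four included patch fits at the image corners mapping to a plane."""
    H, W = shape
    fits = []
    for pid, (r, c) in enumerate([(0, 0), (0, W - 1), (H - 1, 0), (H - 1, W - 1)]):
        fits.append(PatchFit(pid, (float(r), float(c)), (3.0, 3.0), 0.01, True))
    geom = MonitorGeometry(
        patch_centres_cm=np.array(
            [[-monitor_extent, monitor_extent], [monitor_extent, monitor_extent],
             [-monitor_extent, -monitor_extent], [monitor_extent, -monitor_extent]]
        )
    )
    return fits, geom


class TestInterpolateRetinotopy:
    def test_interior_is_exactly_linear(self):
        fits, geom = corner_fits((21, 21))
        retino = interpolate_retinotopy(fits, geom, (21, 21))
        # centre pixel maps to the monitor centre
        assert retino.x_cm[10, 10] == pytest.approx(0.0, abs=1e-9)
        assert retino.y_cm[10, 10] == pytest.approx(0.0, abs=1e-9)
        # linear in the column index along the middle row
        assert retino.x_cm[10, 5] == pytest.approx(-10.0, abs=1e-9)

    def test_all_pixels_inside_hull_for_corner_patches(self):
        fits, geom = corner_fits((15, 15))
        retino = interpolate_retinotopy(fits, geom, (15, 15))
        assert retino.hull_mask.all()

    def test_outside_hull_masked(self):
        fits, geom = corner_fits((15, 15))
        retino = interpolate_retinotopy(fits, geom, (20, 20))
        assert not retino.hull_mask[19, 19]

    def test_too_few_patches(self):
        fits, geom = corner_fits((15, 15))
        for f in fits[2:]:
            f.included = False
        with pytest.raises(ValueError, match="insufficient retinotopy"):
            interpolate_retinotopy(fits, geom, (15, 15))

    def test_collinear_patches(self):
        fits, geom = corner_fits((15, 15))
        for f in fits:
            f.centre_px = (7.0, f.centre_px[1])
        with pytest.raises(ValueError, match="insufficient retinotopy"):
            interpolate_retinotopy(fits, geom, (15, 15))


class TestBuildConcentricMap:
    def make_retino(self, az_lo=10, az_hi=40, el_lo=-10, el_hi=25, shape=(20, 20)):
        az = np.linspace(az_lo, az_hi, shape[1])[None, :] * np.ones((shape[0], 1))
        el = np.linspace(el_hi, el_lo, shape[0])[:, None] * np.ones((1, shape[1]))
        mask = np.ones(shape, bool)
        from tectomap.geometry import RetinotopyMaps

        return RetinotopyMaps(
            azimuth_deg=ScalarMap(az, mask, "deg"),
            elevation_deg=ScalarMap(el, mask, "deg"),
            hull_mask=mask,
        )

    def test_sigma_zero_matches_pointwise_formula(self):
        retino = self.make_retino()
        out = build_concentric_map(retino, sigma_um=0)
        expected = concentric_from_angles(
            retino.azimuth_deg.values, retino.elevation_deg.values
        )
        assert np.allclose(out.angle_deg[out.mask], expected[out.mask])

    def test_all_ipsilateral_is_horizontal(self):
        retino = self.make_retino(az_lo=-40, az_hi=-10)
        out = build_concentric_map(retino, sigma_um=0, ipsi_azimuth_sign=-1)
        assert np.allclose(out.angle_deg[out.mask], 0.0)

    def test_smoothing_preserves_slowly_varying_angles(self):
        retino = self.make_retino(az_lo=25, az_hi=40, el_lo=15, el_hi=25)
        raw = build_concentric_map(retino, sigma_um=0)
        sm = build_concentric_map(retino, sigma_um=132.0, pixel_size_um=11.04)
        d = np.abs(
            (sm.angle_deg[sm.mask] - raw.angle_deg[sm.mask] + 90) % 180 - 90
        )
        assert np.median(d) < 5.0


class TestFitHeadAngles:
    def test_recovers_generating_angles(self):
        true_pitch, true_roll = 10.0, 5.0
        rr, cc = np.mgrid[0:24, 0:24]
        mon_x = 2.0 + cc * 1.2
        mon_y = -10.0 + rr * 1.0
        pts = np.column_stack([mon_x.ravel(), mon_y.ravel()])
        geom = MonitorGeometry()

        def predicted(pitch, roll):
            xyz = monitor_to_head_xyz(pts, geom, pitch_deg=pitch, roll_deg=roll)
            az, el = xyz_to_spherical(xyz[:, 0], xyz[:, 1], xyz[:, 2])
            ang = concentric_from_angles(az, el).reshape(24, 24)
            return AxialMap(ang, np.ones_like(ang), np.ones_like(ang, bool))

        measured = predicted(true_pitch, true_roll)
        grid = np.arange(-20.0, 21.0, 5.0)
        fit = fit_head_angles(predicted, measured, grid, grid)
        assert fit.identifiable
        assert abs(fit.pitch_deg - true_pitch) <= 5.0
        assert abs(fit.roll_deg - true_roll) <= 5.0
        # the profile peaks at the truth rather than 10 degrees off in pitch
        i_true = list(grid).index(10.0)
        j_true = list(grid).index(5.0)
        assert fit.alignment_profile[i_true, j_true] >= fit.alignment_profile[i_true - 2, j_true]

    def test_random_map_unidentifiable(self):
        rng = np.random.default_rng(17)
        rr, cc = np.mgrid[0:24, 0:24]
        mon_x = 2.0 + cc * 1.2
        mon_y = -10.0 + rr * 1.0
        pts = np.column_stack([mon_x.ravel(), mon_y.ravel()])
        geom = MonitorGeometry()

        def predicted(pitch, roll):
            xyz = monitor_to_head_xyz(pts, geom, pitch_deg=pitch, roll_deg=roll)
            az, el = xyz_to_spherical(xyz[:, 0], xyz[:, 1], xyz[:, 2])
            ang = concentric_from_angles(az, el).reshape(24, 24)
            return AxialMap(ang, np.ones_like(ang), np.ones_like(ang, bool))

        noise = rng.uniform(0, 180, (24, 24))
        measured = AxialMap(noise, np.ones_like(noise), np.ones_like(noise, bool))
        fit = fit_head_angles(predicted, measured, np.arange(-10.0, 11, 5), np.arange(-10.0, 11, 5))
        assert not fit.identifiable
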