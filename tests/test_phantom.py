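"""Phantom construction, motion blur, PSF and analytic truth."""

import numpy as np
import pytest
from scipy import ndimage

from aifmap import (ActivityVolume, BackgroundSpec, BlurSpec, DefectSpec,
                    MotionSpec, PhantomSpec, apply_motion, apply_psf,
                    build_phantom, true_infarcted_fraction)
from aifmap.arcscan import radial_window, sweep_arc_activities


def shell_volume(spec: PhantomSpec) -> float:
    return (np.pi * (spec.outer_radius ** 2 - spec.inner_radius ** 2)
            * spec.length)


class TestBuildPhantom:
    def test_total_activity_matches_analytic_shell_volume(self, spec_std):
        vol = build_phantom(spec_std, DefectSpec(0.0), BackgroundSpec(0.0))
        assert vol.total_activity == pytest.approx(shell_volume(spec_std),
                                                   rel=0.01)

    def test_defect_removes_proportional_wall_activity(self, spec_std):
        full = build_phantom(spec_std, DefectSpec(0.0), BackgroundSpec(0.0))
        cut = build_phantom(spec_std, DefectSpec(240.0, 30.0),
                            BackgroundSpec(0.0))
        assert cut.total_activity / full.total_activity == pytest.approx(
            1.0 - 240.0 / 360.0, rel=0.01)

    @pytest.mark.parametrize("extension", [40.0, 90.0, 200.0])
    def test_wall_deficit_equals_true_fraction(self, spec_small, extension):
        """Voxel-count oracle: the rasterized activity deficit tracks the
        analytic infarcted fraction."""
        defect = DefectSpec(extension, 120.0)
        full = build_phantom(spec_small, DefectSpec(0.0),
                             BackgroundSpec(0.0))
        cut = build_phantom(spec_small, defect, BackgroundSpec(0.0))
        deficit = 1.0 - cut.total_activity / full.total_activity
        assert deficit == pytest.approx(
            true_infarcted_fraction(spec_small, defect), abs=0.01)

    def test_residual_activity_scales_defect(self, spec_small):
        half = build_phantom(spec_small,
                             DefectSpec(180.0, 0.0,
                                        residual_activity_fraction=0.5),
                             BackgroundSpec(0.0))
        full = build_phantom(spec_small, DefectSpec(0.0),
                             BackgroundSpec(0.0))
        # half the wall at half activity -> 75% of the full total
        assert half.total_activity / full.total_activity == pytest.approx(
            0.75, rel=0.01)

    def test_background_fills_cavity_and_exterior(self, spec_small):
        vol = build_phantom(spec_small, DefectSpec(0.0),
                            BackgroundSpec(0.3))
        x, y = vol.xy_grids()
        r = np.broadcast_to(np.hypot(x, y)[:, :, None], vol.values.shape)
        outside = r < spec_small.inner_radius - 0.3
        assert np.allclose(vol.values[outside], 0.3)

    def test_full_circle_defect_rejected(self):
        with pytest.raises(ValueError):
            DefectSpec(polar_extension=360.0)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            PhantomSpec(grid_spacing=0.3)


class TestTrueInfarctedFraction:
    @pytest.mark.parametrize("extension,residual,expected", [
        (240.0, 0.0, 2.0 / 3.0),
        (0.0, 0.0, 0.0),
        (90.0, 0.0, 0.25),
        (120.0, 0.5, 1.0 / 6.0),
    ])
    def test_analytic_values(self, extension, residual, expected):
        frac = true_infarcted_fraction(
            PhantomSpec(), DefectSpec(extension, 0.0, residual))
        assert frac == pytest.approx(expected, abs=1e-12)


class TestApplyMotion:
    def test_zero_amplitudes_identity(self, spec_small):
        vol = build_phantom(spec_small, DefectSpec(0.0), BackgroundSpec(0.1))
        still = MotionSpec(beat_radial_amplitude=0.0, beat_twist=0.0,
                           breath_amplitude=0.0)
        out = apply_motion(vol, still)
        assert np.array_equal(out.values, vol.values)

    def test_breathing_matches_shifted_copy_average(self, spec_small):
        """Direct oracle at n_phases=4: phase-averaged translation equals
        the mean of explicitly shifted volumes."""
        vol = build_phantom(spec_small, DefectSpec(0.0), BackgroundSpec(0.0),
                            xy_margin=2.0)
        motion = MotionSpec(beat_radial_amplitude=0.0, beat_twist=0.0,
                            breath_amplitude=2.0, n_phases=4,
                            breath_direction="perpendicular")
        out = apply_motion(vol, motion, defect_center_deg=0.0)
        disp = 1.0  # peak-to-peak 2 mm -> +-1 mm along +x
        shifts_mm = disp * np.sin(2 * np.pi * np.arange(4) / 4)
        expected = np.mean([
            ndimage.shift(vol.values, (s / vol.spacing, 0.0, 0.0), order=1,
                          mode="nearest")
            for s in shifts_mm], axis=0)
        assert np.allclose(out.values, expected, atol=1e-10)

    def test_breathing_preserves_center_of_mass(self, spec_small):
        vol = build_phantom(spec_small, DefectSpec(0.0), BackgroundSpec(0.0),
                            xy_margin=2.0)
        motion = MotionSpec(beat_radial_amplitude=0.0, beat_twist=0.0,
                            breath_amplitude=2.0)
        out = apply_motion(vol, motion, defect_center_deg=0.0)
        com_in = ndimage.center_of_mass(vol.values)
        com_out = ndimage.center_of_mass(out.values)
        assert np.allclose(com_in, com_out, atol=0.05)

    def test_beating_spreads_midwall_activity(self, spec_small):
        """Radial beat moves wall activity off the mid-wall radius into a
        band of the beat amplitude on either side."""
        vol = build_phantom(spec_small, DefectSpec(0.0), BackgroundSpec(0.0))
        motion = MotionSpec(breath_amplitude=0.0, beat_twist=0.0,
                            beat_radial_amplitude=0.35)
        out = apply_motion(vol, motion)
        x, y = vol.xy_grids()
        r = np.broadcast_to(np.hypot(x, y)[:, :, None], vol.values.shape)
        midwall = np.abs(r - spec_small.midwall_radius) < 0.1
        outer_band = ((r >= spec_small.outer_radius)
                      & (r < spec_small.outer_radius + 0.35))
        assert out.values[midwall].sum() < vol.values[midwall].sum()
        assert out.values[outer_band].sum() > vol.values[outer_band].sum()

    def test_motion_conserves_activity(self, spec_std):
        vol = build_phantom(spec_std, DefectSpec(60.0, 30.0),
                            BackgroundSpec(0.2), xy_margin=2.0)
        out = apply_motion(vol, MotionSpec(), defect_center_deg=30.0)
        assert out.total_activity == pytest.approx(vol.total_activity,
                                                   rel=1e-3)

    def test_torsion_mode_runs_and_conserves(self, spec_small):
        vol = build_phantom(spec_small, DefectSpec(90.0, 0.0),
                            BackgroundSpec(0.0), xy_margin=1.0)
        motion = MotionSpec(breath_amplitude=0.0, twist_mode="torsion",
                            n_phases=4)
        out = apply_motion(vol, motion)
        assert out.total_activity == pytest.approx(vol.total_activity,
                                                   rel=1e-3)


class TestApplyPsf:
    def test_zero_fwhm_identity(self, spec_small):
        vol = build_phantom(spec_small, DefectSpec(0.0), BackgroundSpec(0.0))
        out = apply_psf(vol, BlurSpec(0.0))
        assert np.array_equal(out.values, vol.values)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            BlurSpec(-1.0)

    def test_point_source_fwhm(self):
        h = 0.1
        values = np.zeros((61, 61, 61))
        values[30, 30, 30] = 1.0
        vol = ActivityVolume(values, h, np.array([-3.0, -3.0, -3.0]))
        out = apply_psf(vol, BlurSpec(1.3))
        profile = out.values[:, 30, 30]
        half = profile.max() / 2.0
        above = np.where(profile >= half)[0]
        fwhm = (above[-1] - above[0] + 1) * h
        assert fwhm == pytest.approx(1.3, abs=h)

    def test_psf_conserves_activity(self, spec_std):
        vol = build_phantom(spec_std, DefectSpec(0.0), BackgroundSpec(0.0),
                            xy_margin=3.0, z_margin=3.0)
        out = apply_psf(vol, BlurSpec(1.3))
        assert out.total_activity == pytest.approx(vol.total_activity,
                                                   rel=1e-3)


class TestRotationalEquivariance:
    def test_rotated_defect_rotates_sweep(self, spec_std):
        """Rotating the defect (with its co-rotating breathing axis) by a
        multiple of the sweep step circularly shifts the arc activities."""
        from aifmap.phantom import default_margins

        motion, blur = MotionSpec(), BlurSpec()
        xy_m, z_m = default_margins(motion, blur)
        window = radial_window(spec_std)
        sweeps = []
        for center in (30.0, 70.0):
            vol = build_phantom(spec_std, DefectSpec(60.0, center),
                                BackgroundSpec(0.2), xy_margin=xy_m,
                                z_margin=z_m)
            vol = apply_motion(vol, motion, defect_center_deg=center)
            vol = apply_psf(vol, blur)
            _, acts = sweep_arc_activities(vol, 60.0, 1.0, window)
            sweeps.append(acts / acts.max())
        shifted = np.roll(sweeps[0], 40)
        assert np.max(np.abs(shifted - sweeps[1])) < 0.01
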