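"""Shared fixtures: phantom level curves are expensive (seconds each), so
the standard configurations are computed once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from aifmap import (BackgroundSpec, BlurSpec, DefectSpec, MotionSpec,
                    PhantomSpec)
from aifmap.arcscan import level_curve

STD_DEFECT_60 = DefectSpec(polar_extension=60.0, polar_center=30.0)


@pytest.fixture(scope="session")
def spec_std() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def spec_small() -> PhantomSpec:
    """A short, coarser phantom for cheap volume-level tests."""
    return PhantomSpec(length=4.0, grid_spacing=0.2)


@pytest.fixture(scope="session")
def curve_ideal_60(spec_std):
    """Ideal tomography: no motion, no PSF, no background."""
    return level_curve(spec_std, STD_DEFECT_60, None, None,
                       BackgroundSpec(0.0))


@pytest.fixture(scope="session")
def curve_ideal_240(spec_std):
    """240° defect with edges on segment boundaries (centre at 60°)."""
    return level_curve(spec_std, DefectSpec(240.0, 60.0), None, None,
                       BackgroundSpec(0.0))


@pytest.fixture(scope="session")
def curve_blur_bg20_tan(spec_std):
    """The standard full-blur configuration: beating, tangential breathing,
    1.3 mm PSF, 20% background, 60° defect."""
    return level_curve(spec_std, STD_DEFECT_60, MotionSpec(), BlurSpec(),
                       BackgroundSpec(0.2))


@pytest.fixture(scope="session")
def curve_blur_bg10_tan(spec_std):
    return level_curve(spec_std, STD_DEFECT_60, MotionSpec(), BlurSpec(),
                       BackgroundSpec(0.1))


@pytest.fixture(scope="session")
def curve_blur_bg30_tan(spec_std):
    return level_curve(spec_std, STD_DEFECT_60, MotionSpec(), BlurSpec(),
                       BackgroundSpec(0.3))


@pytest.fixture(scope="session")
def curve_blur_bg20_perp(spec_std):
    return level_curve(
        spec_std, STD_DEFECT_60,
        MotionSpec(breath_direction="perpendicular"), BlurSpec(),
        BackgroundSpec(0.2))


@pytest.fixture(scope="session")
def curve_psf_only(spec_std):
    return level_curve(spec_std, STD_DEFECT_60, None, BlurSpec(),
                       BackgroundSpec(0.0))


@pytest.fixture(scope="session")
def curve_breath_only(spec_std):
    motion = MotionSpec(beat_radial_amplitude=0.0, beat_twist=0.0)
    return level_curve(spec_std, STD_DEFECT_60, motion, None,
                       BackgroundSpec(0.0))


@pytest.fixture(scope="session")
def curve_beat_only(spec_std):
    motion = MotionSpec(breath_amplitude=0.0)
    return level_curve(spec_std, STD_DEFECT_60, motion, None,
                       BackgroundSpec(0.0))


@pytest.fixture(scope="session")
def curve_normal_breathing(spec_std):
    """Defect-free phantom with breathing blur: the artifactual
    hypoperfusion configuration."""
    motion = MotionSpec(beat_radial_amplitude=0.0, beat_twist=0.0)
    return level_curve(spec_std, DefectSpec(0.0, 30.0), motion, BlurSpec(),
                       BackgroundSpec(0.2))


def min_defect_level(curve) -> float:
    """Minimum relative level over arcs fully inside the defect."""
    inside = curve.fractions >= 1.0 - 1e-12
    assert inside.any(), "no arc fully inside the defect"
    return float(curve.levels[inside].min())
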