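"""Numerical cylindrical left-ventricle phantom.

The mouse left ventricle is modelled as a thin-walled cylinder of uniform
tracer activity: a 10 mm long cylinder whose active wall is 1 mm thick with a
5.4 mm mid-wall diameter (the mean diameter resolved on SPECT).  A transmural
perfusion defect is an angular sector of the wall, spanning the full length,
in which activity is reduced to a residual fraction (0 for a complete
defect).  Everything outside the wall — the ventricular cavity and the
exterior — carries a uniform background activity expressed as a fraction of
the healthy wall activity.

Physiological motion is modelled as a phase-averaged blur: a sinusoidal
radial oscillation of the wall plus a rigid twist about the long axis
(beating), and a transverse translation of the whole ventricle (breathing),
either tangential or perpendicular to the defect centre.  System resolution
is an isotropic 3D Gaussian convolution.  No attenuation, scatter, Poisson
noise or reconstruction modelling is included: resolution enters as a single
convolution.

Coordinate convention: the long axis is z; the polar angle is measured
counter-clockwise from +x in the short-axis (x, y) plane, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from ._util import FWHM_TO_SIGMA, circ_diff

__all__ = [
    "PhantomSpec",
    "DefectSpec",
    "MotionSpec",
    "BlurSpec",
    "BackgroundSpec",
    "ActivityVolume",
    "build_phantom",
    "apply_motion",
    "apply_psf",
    "true_infarcted_fraction",
    "default_margins",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of the healthy cylindrical ventricle.

    ``midwall_diameter`` is the diameter of the wall centreline: the active
    wall occupies radii ``[midwall_radius - wall_thickness/2,
    midwall_radius + wall_thickness/2]``.
    """

    length: float = 10.0            # mm, full cylinder length
    midwall_diameter: float = 5.4   # mm, wall-centreline diameter
    wall_thickness: float = 1.0     # mm
    wall_activity: float = 1.0      # arbitrary units per unit volume
    grid_spacing: float = 0.1       # mm, isotropic voxel pitch

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not self.midwall_diameter > self.wall_thickness > 0:
            raise ValueError("require midwall_diameter > wall_thickness > 0")
        if self.wall_activity < 0:
            raise ValueError("wall_activity must be non-negative")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.grid_spacing > self.wall_thickness / 4.0:
            raise ValueError(
                f"grid_spacing {self.grid_spacing} mm too coarse: must be "
                f"<= wall_thickness/4 = {self.wall_thickness / 4.0} mm"
            )

    @property
    def midwall_radius(self) -> float:
        return self.midwall_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.midwall_radius - self.wall_thickness / 2.0

    @property
    def outer_radius(self) -> float:
        return self.midwall_radius + self.wall_thickness / 2.0


@dataclass(frozen=True)
class DefectSpec:
    """Transmural, full-length angular defect of the wall.

    ``residual_activity_fraction`` is the activity remaining inside the
    defect relative to healthy wall: 0 is a 100%-activity defect.
    """

    polar_extension: float = 0.0          # degrees, in [0, 360)
    polar_center: float = 90.0            # degrees
    residual_activity_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.polar_extension < 360.0:
            raise ValueError("polar_extension must be in [0, 360)")
        if not 0.0 <= self.residual_activity_fraction <= 1.0:
            raise ValueError("residual_activity_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MotionSpec:
    """Beating and breathing blur parameters.

    ``breath_amplitude`` is the total peak-to-peak transverse excursion of
    the ventricle (displacement oscillates by ±breath_amplitude/2).  Set
    ``breath_peak_to_peak=False`` to interpret it as the one-sided amplitude
    instead.  ``breath_direction`` is defined relative to the defect centre:
    "perpendicular" is along the radius through the defect centre,
    "tangential" is at right angles to it.

    ``twist_mode`` selects a rigid rotation of the whole cylinder ("rigid",
    default) or a base-to-apex torsion linear in z ("torsion").
    """

    beat_radial_amplitude: float = 0.35   # mm
    beat_twist: float = 3.0               # degrees
    breath_amplitude: float = 2.0         # mm (peak-to-peak by default)
    breath_direction: str = "tangential"
    breath_peak_to_peak: bool = True
    twist_mode: str = "rigid"
    n_phases: int = 16

    def __post_init__(self) -> None:
        if min(self.beat_radial_amplitude, self.beat_twist,
               self.breath_amplitude) < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if self.breath_direction not in ("tangential", "perpendicular"):
            raise ValueError("breath_direction must be 'tangential' or "
                             "'perpendicular'")
        if self.twist_mode not in ("rigid", "torsion"):
            raise ValueError("twist_mode must be 'rigid' or 'torsion'")
        if self.n_phases < 4:
            raise ValueError("n_phases must be at least 4")

    @property
    def breath_displacement(self) -> float:
        """One-sided breathing displacement in mm."""
        if self.breath_peak_to_peak:
            return self.breath_amplitude / 2.0
        return self.breath_amplitude

    @property
    def is_static(self) -> bool:
        return (self.beat_radial_amplitude == 0.0 and self.beat_twist == 0.0
                and self.breath_amplitude == 0.0)


@dataclass(frozen=True)
class BlurSpec:
    """Tomographic system resolution as an isotropic Gaussian PSF."""

    psf_fwhm: float = 1.3  # mm

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")

    @property
    def sigma(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class BackgroundSpec:
    """Uniform surrounding background, as a fraction of wall activity."""

    background_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")


@dataclass
class ActivityVolume:
    """A 3D scalar activity grid with uniform isotropic spacing.

    ``values`` is indexed [ix, iy, iz]; ``origin`` holds the physical (x, y,
    z) coordinates of the centre of voxel (0, 0, 0), in mm.
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.origin.shape != (3,):
            raise ValueError("origin must have 3 components")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def xy_grids(self) -> Tuple[np.ndarray, np.ndarray]:
        """Physical x and y coordinates broadcast to the in-plane shape."""
        x = self.axis_coords(0)
        y = self.axis_coords(1)
        return x[:, None], y[None, :]

    @property
    def total_activity(self) -> float:
        """Activity integral (value sum × voxel volume)."""
        return float(self.values.sum()) * self.spacing ** 3

    def copy(self) -> "ActivityVolume":
        return ActivityVolume(self.values.copy(), self.spacing,
                              self.origin.copy())


def _symmetric_axis(half_extent: float, spacing: float) -> np.ndarray:
    """Voxel-centre coordinates covering [-half_extent, half_extent],
    symmetric about 0 with centres at half-integer positions (even count),
    so planes like z = 0 or z = ±length/2 on a commensurate grid fall on
    voxel boundaries rather than voxel centres."""
    n = int(np.ceil(2.0 * half_extent / spacing))
    if n % 2 == 1:
        n += 1
    return (np.arange(n) - n / 2.0 + 0.5) * spacing


def default_margins(motion: MotionSpec | None,
                    blur: BlurSpec | None) -> Tuple[float, float]:
    """Field-of-view margins (transverse, axial) in mm that keep the full
    motion excursion plus 4 PSF sigmas inside the grid."""
    breath = motion.breath_displacement if motion is not None else 0.0
    beat = motion.beat_radial_amplitude if motion is not None else 0.0
    sigma = blur.sigma if blur is not None else 0.0
    return breath + beat + 4.0 * sigma + 0.2, 4.0 * sigma + 0.2


def build_phantom(spec: PhantomSpec,
                  defect: DefectSpec = DefectSpec(),
                  bg: BackgroundSpec = BackgroundSpec(0.0),
                  xy_margin: float = 3.5,
                  z_margin: float = 2.5) -> ActivityVolume:
    """Rasterize the cylindrical ventricle with an optional defect.

    Voxels whose centre lies in the wall shell (and, axially, within the
    cylinder length) receive ``wall_activity`` — or the residual fraction of
    it inside the defect arc.  Every other voxel, cavity included, receives
    ``background_fraction × wall_activity``.  Defect edges are sharp at the
    voxel level; the fine default grid (0.1 mm) provides implicit
    anti-aliasing.
    """
    h = spec.grid_spacing
    xs = _symmetric_axis(spec.outer_radius + xy_margin, h)
    zs = _symmetric_axis(spec.length / 2.0 + z_margin, h)
    x = xs[:, None]
    y = xs[None, :]
    r = np.hypot(x, y)
    wall2d = (r >= spec.inner_radius) & (r < spec.outer_radius)

    bg_value = bg.background_fraction * spec.wall_activity
    plane = np.full((xs.size, xs.size), bg_value)
    plane[wall2d] = spec.wall_activity
    if defect.polar_extension > 0.0:
        ang = np.degrees(np.arctan2(y, x))
        in_defect = np.abs(circ_diff(ang, defect.polar_center)) \
            < defect.polar_extension / 2.0
        plane[wall2d & in_defect] = (defect.residual_activity_fraction
                                     * spec.wall_activity)

    z_in = np.abs(zs) < spec.length / 2.0
    values = np.empty((xs.size, xs.size, zs.size))
    values[:, :, z_in] = plane[:, :, None]
    values[:, :, ~z_in] = bg_value
    origin = np.array([xs[0], xs[0], zs[0]])
    return ActivityVolume(values, h, origin)


def true_infarcted_fraction(spec: PhantomSpec, defect: DefectSpec) -> float:
    """Analytic infarcted fraction of the wall for a full-length transmural
    defect: angular extent fraction times depth of the activity deficit."""
    return (defect.polar_extension / 360.0
            * (1.0 - defect.residual_activity_fraction))


def _breath_unit_vector(direction: str, defect_center_deg: float
                        ) -> Tuple[float, float]:
    theta = np.radians(defect_center_deg)
    if direction == "perpendicular":
        return float(np.cos(theta)), float(np.sin(theta))
    return float(-np.sin(theta)), float(np.cos(theta))


def _inverse_plane_coords(vol: ActivityVolume, dr: float, twist_deg: float,
                          tx: float, ty: float
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Source index coordinates for one phase's in-plane motion (pull-back
    of translation -> rigid twist -> radial displacement of the wall)."""
    x, y = vol.xy_grids()
    px = x - tx
    py = np.broadcast_to(y - ty, (x.shape[0], y.shape[1])).copy()
    px = np.broadcast_to(px, py.shape).copy()
    if twist_deg != 0.0:
        th = np.radians(twist_deg)
        c, s = np.cos(th), np.sin(th)
        px, py = c * px + s * py, -s * px + c * py
    if dr != 0.0:
        rad = np.hypot(px, py)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rad > 0, np.maximum(rad - dr, 0.0) / rad, 0.0)
        px = px * scale
        py = py * scale
    ix = (px - vol.origin[0]) / vol.spacing
    iy = (py - vol.origin[1]) / vol.spacing
    return ix, iy


def apply_motion(vol: ActivityVolume, motion: MotionSpec,
                 defect_center_deg: float = 90.0) -> ActivityVolume:
    """Blur a volume by phase-averaged beating and breathing.

    The output is the average of the activity over ``n_phases`` equispaced
    phases φ of one sinusoidal cycle: the wall radius is displaced by
    ``beat_radial_amplitude·sin φ``, the cylinder twists by
    ``beat_twist·sin φ`` about z, and the whole volume translates by the
    breathing displacement ``·sin φ`` along the breathing axis (resolved
    relative to ``defect_center_deg``).  Total activity is conserved up to
    interpolation loss provided the field of view covers the excursion.
    """
    if motion.is_static:
        return vol.copy()

    bx, by = _breath_unit_vector(motion.breath_direction, defect_center_deg)
    breath = motion.breath_displacement
    phases = 2.0 * np.pi * np.arange(motion.n_phases) / motion.n_phases
    sines = np.sin(phases)

    nz = vol.values.shape[2]
    if motion.twist_mode == "torsion" and motion.beat_twist != 0.0:
        # Base-to-apex torsion: twist angle grows linearly along z, so each
        # slice needs its own warp.
        zfrac = (np.arange(nz) + 0.5) / nz
        out = np.zeros_like(vol.values)
        for s in sines:
            for k in range(nz):
                ix, iy = _inverse_plane_coords(
                    vol, motion.beat_radial_amplitude * s,
                    motion.beat_twist * s * zfrac[k],
                    breath * s * bx, breath * s * by)
                out[:, :, k] += ndimage.map_coordinates(
                    vol.values[:, :, k], [ix, iy], order=1, mode="nearest")
        out /= motion.n_phases
        return ActivityVolume(np.clip(out, 0.0, None), vol.spacing,
                              vol.origin.copy())

    # Rigid in-plane motion: one 2D warp per phase, shared by all z slices.
    # Freshly built phantoms have only two distinct slices (inside/outside
    # the cylinder length), so warp each unique slice once.
    flat = np.ascontiguousarray(vol.values.reshape(-1, nz).T)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    shape2d = vol.values.shape[:2]
    uniq_slices = uniq.reshape(uniq.shape[0], *shape2d)

    acc = np.zeros_like(uniq_slices)
    for s in sines:
        ix, iy = _inverse_plane_coords(
            vol, motion.beat_radial_amplitude * s, motion.beat_twist * s,
            breath * s * bx, breath * s * by)
        for u in range(uniq_slices.shape[0]):
            acc[u] += ndimage.map_coordinates(uniq_slices[u], [ix, iy],
                                              order=1, mode="nearest")
    acc /= motion.n_phases

    out = np.empty_like(vol.values)
    for k in range(nz):
        out[:, :, k] = acc[inverse[k]]
    return ActivityVolume(np.clip(out, 0.0, None), vol.spacing,
                          vol.origin.copy())


def apply_psf(vol: ActivityVolume, blur: BlurSpec) -> ActivityVolume:
    """Convolve with the isotropic Gaussian system PSF.

    sigma = fwhm / (2·sqrt(2·ln 2)).  Conserves total activity when the
    field of view leaves adequate margins around the activity.
    """
    if blur.psf_fwhm == 0.0:
        return vol.copy()
    sigma_vox = blur.sigma / vol.spacing
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma_vox,
                                       mode="nearest")
    return ActivityVolume(smoothed, vol.spacing, vol.origin.copy())
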