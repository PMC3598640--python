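# Methods

## The problem

Sizing a myocardial infarct from a perfusion SPECT study is usually done by
comparing the patient's (or animal's) polar map against a normal-perfusion
database. For mice such databases are expensive to build and fragile across
strains and ages. The Absolute Infarcted Fraction (AIF) statistic sidesteps
the database: it converts each polar-map segment's *relative* uptake level
directly into an infarcted-fraction estimate through a fixed s-shaped
weighting, then averages the weights over the wall with per-segment volume
weights measured from the long-axis slices.

This package implements the statistic together with the numerical
left-ventricle phantom used to derive and validate it, so the entire
simulation-side validation runs from first principles with no acquired data.

## The AIF statistic

A 20-segment polar map (6 basal + 6 middle + 6 apical + 2 apex segments)
provides uptake values `v_s`. Relative levels are `U_s = v_s / max_s v_s`,
so the hottest segment defines the normal reference (level 1). Each level is
converted to an infarcted-fraction weight by the s-curve

```
P(U) = 1 / (1 + (U / U_c)^(2n))
```

with inflection level `U_c` (P = 1/2 there) and slope parameter `n`. The
statistic is the volume-weighted mean

```
AIF = Σ_s P(U_s) V_s / Σ_s V_s ,     V_s = π D_s L_s T_s / N_s
```

where, per ring, `N_s` is the segment count (6/6/6/2), `D_s` the mean ring
diameter, `L_s` the long-axis length and `T_s` the transverse wall
thickness, all measured in any consistent unit — AIF is unit-free (verified
by a scale-invariance test). The reference calibration against
triphenyltetrazolium-chloride histology is `U_c = 0.55`, `n = 9`; both are
plain floats in code, grid-fitted as 0.01 steps in `U_c` and integers in
`n` by default.

Why an s-curve and not the ideal line `f = 1 − U`? Finite system resolution
and respiratory motion mix activity across the defect border, so a segment
fully inside a defect no longer reads level 0 and a normal segment next to a
defect reads below 1: the ideal line pivots into a steep sigmoid over a
narrow level band. The phantom below quantifies that band.

## The digital ventricle phantom

The mouse left ventricle is modelled as a cylinder:

| parameter | default | meaning |
|---|---|---|
| length | 10 mm | full wall length along z |
| mid-wall diameter | 5.4 mm | diameter of the wall centreline |
| wall thickness | 1 mm | active shell, radii 2.2–3.2 mm |
| wall activity | 1 (a.u.) | uniform healthy uptake per unit volume |
| background | 0.2 (fraction, swept 0.1/0.2/0.3) | uniform activity everywhere outside the wall, cavity included |
| defect | 0–240°, transmural, full length | activity set to a residual fraction (default 0) inside the arc |
| beat | 0.35 mm radial + 3° twist | sinusoidal, phase-averaged |
| breathing | 2 mm transverse (peak-to-peak, ±1 mm) | along or across the defect radius |
| PSF | 1.3 mm FWHM | isotropic 3D Gaussian |
| grid | 0.1 mm isotropic | ≈ 13× finer than the PSF FWHM |

The 5.4 mm figure is taken as the *mid-wall* diameter, since a SPECT-derived
mean diameter resolves the wall centreline. Voxel centres sit at
half-integer grid positions, so the cylinder end planes and the z = 0 plane
fall on voxel boundaries: with the default grid the rasterized cylinder
length is exactly 10 mm (centre-aligned grids clip a full voxel layer, a 1%
volume bias).

Motion is applied as a time average over 16 equispaced phases of one
sinusoidal cycle shared by all three motions: the wall radius is displaced
by `0.35·sin φ` mm, the cylinder twists rigidly by `3°·sin φ` about its
axis, and the whole ventricle translates by `±1 mm·sin φ` along the
breathing axis. Cardiac and respiratory cycles are physically independent;
a shared phase is a deliberate simplification of a pure blur model in which
only the phase-averaged distributions matter and the excursions are small.
A base-to-apex torsion variant of the twist (angle linear in z) is
available via `MotionSpec(twist_mode="torsion")`. Breathing amplitude is
read as the total peak-to-peak excursion; the one-sided alternative is a
flag (`breath_peak_to_peak=False`). All motions are in-plane, so the warp
is a single 2D inverse map per phase (pull-back, trilinear interpolation);
the radial term's Jacobian error is exactly linear in the displacement and
cancels over the symmetric phase set, which is why phase-averaged motion
conserves activity to interpolation precision (< 0.01% in practice, 0.1%
budgeted).

The PSF stage is `scipy.ndimage.gaussian_filter` with
`σ = FWHM / (2√(2 ln 2))` and nearest-edge padding; field-of-view margins
of 4σ plus the motion excursion keep both stages conservative.

## Arc sampling and the level curve

A 60° arc segment sweeps the short-axis plane in 1° steps. Per arc the
activity is summed over the full axial extent of the grid and over a fixed
radial window hugging the anatomical wall — the shell dilated by a quarter
wall thickness, [1.95, 3.45] mm by default. Two numerical choices here
deserve explanation:

- **Fixed (not motion-dilated) radial window.** Activity that motion and
  resolution push beyond the wall neighbourhood is genuinely lost from a
  segment sum, which is part of the sensitivity loss the s-curve corrects.
  A window dilated by the full motion excursion re-captures that activity
  and also floods every arc with background; under the default blur it
  raises the minimum observable level of a 60° defect from ≈ 0.47 to
  ≈ 0.63 and fails to reproduce the known (0.5, 0.8) level-range mapping
  of the reference model, whereas the wall-hugging window reproduces it.
- **Subpixel angular membership.** Arc membership is evaluated on 4×4
  subpixel centres of the axially projected plane (piecewise-constant
  subdivision, exactly activity-conserving). Pure voxel-centre membership
  at 0.1 mm leaves ≈ 3.5% aliasing jitter in arc sums as boundary voxels
  jump in or out; subdivision reduces it to ≈ 0.2%, restoring the exact
  ideal-tomography limit `f = 1 − U` to better than 1%.

Relative levels divide by the hottest arc; the analytic true fraction of an
arc is its circular-interval overlap with the defect (wrap-around handled
exactly). The model-side AIF uses one ring of six equal-volume 60°
segments — the only segmentation consistent with a cylinder, which has no
apex — and renormalizes the six picked activities to their own maximum,
mirroring polar-map normalization. A defect displaced by Δ versus the
segmentation is evaluated by reading segment centres shifted by −Δ from
the same sweep; this is exact by rotational symmetry because the breathing
axis is defined relative to the defect.

## Calibration

`fit_scurve_params` grid-searches `(U_c, n)` minimizing the sum of squared
differences between case AIFs and reference fractions (`U_c` ∈ [0.30,
0.90] step 0.01, `n` ∈ {1 … 20}), with ties broken toward smaller `n` then
smaller `U_c` — deterministic and derivative-free, matching the small
parameter space. The original calibration objective is stated only as
"best agreement"; a correlation-maximizing objective is available as a
flag. `curve_fit_scurve` fits the s-curve directly to (level, fraction)
samples, grid search plus optional local least-squares refinement; the
refinement is skipped for the headline calibration number so the stated
grid defines the result. Degenerate inputs (fewer than 3 cases, equal
references, constant fractions) raise errors rather than returning
garbage.

## Validation ensemble

The default ensemble crosses defect extensions 0–240° (step 20°),
backgrounds 10/20/30%, tangential and perpendicular breathing, and defect
offsets 0–50° (step 10°) against the segmentation: 468 simulated
infarctions with true fractions 0–66%. The exact point set of the
reference validation is not recoverable, so the grid is chosen to span the
same axes and is fully configurable. On this default the OLS of AIF
(U_c = 0.55, n = 9) on truth gives slope ≈ 0.94, intercept ≈ −0.03,
R² ≈ 0.91 (reference simulation: 0.97 / −0.01 / 0.94). Bland-Altman limits
use mean ± 2 SD (sample SD), and the paired t test is the standard
two-tailed statistic with df = n − 1.

At 0.1 mm grid spacing the full ensemble runs in ≈ 80 s on one CPU core
(one blurred sweep per extension × background × direction; offsets reused
from the sweep). The test suite uses coarser 0.15–0.2 mm grids for
volume-level unit tests and the full grid for the validation checks.

## What the synthetic data do and do not show

The fixture generator derives polar-map segment values from the phantom
pipeline (optionally with seeded multiplicative log-normal noise), with a
manifest of analytic true fractions. It emulates the *geometry* of
perfusion defects and the deterministic blur chain. It does not emulate
Poisson counting noise, attenuation, scatter, reconstruction artifacts,
tracer kinetics (e.g. viable-but-hypoperfused tissue), partial apex
involvement, or operator variability in segment-geometry measurement.
Passing tests therefore demonstrate the statistic's behaviour under the
modelled blur physics, not clinical accuracy on acquired data.

## Known limitations

- The cylinder has no apex; apex segments in synthetic 20-segment fixtures
  are taken as normal, so model-side results exercise one ring.
- The defect is axially uniform and transmural; partial-thickness or
  patchy infarcts are representable only through the residual-activity
  fraction.
- The s-curve collapses the level→fraction relation of *all* blur
  configurations into one curve; per-configuration level curves (different
  backgrounds, breathing directions) retain a residual spread, which is
  what limits the ensemble R² to ≈ 0.91.
- No projector/reconstruction model: resolution enters as a single
  stationary 3D convolution.
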