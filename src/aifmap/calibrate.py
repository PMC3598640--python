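"""Fitting the s-curve parameters (U_c, n).

Two routes are provided.  ``fit_scurve_params`` mirrors the reference
calibration: given cases with known reference infarcted fractions (histology
in the original study, known phantom truth in simulation), it grid-searches
(U_c, n) minimizing the sum of squared differences between each case's AIF
and its reference.  ``curve_fit_scurve`` fits the s-curve directly to
sampled (relative level, infarcted fraction) pairs of a model level curve by
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aifcore import SCurveParams, relative_levels, s_curve_weight

__all__ = [
    "CalibrationCase",
    "CalibrationSet",
    "FitReport",
    "fit_scurve_params",
    "curve_fit_scurve",
]

DEFAULT_UC_GRID = np.round(np.arange(0.30, 0.9001, 0.01), 10)
DEFAULT_N_GRID = np.arange(1.0, 20.001, 1.0)


@dataclass(frozen=True)
class CalibrationCase:
    """One calibration case: segment uptake values, segment wall volumes
    and the reference infarcted fraction the AIF should reproduce."""

    values: np.ndarray
    volumes: np.ndarray
    reference_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        object.__setattr__(self, "volumes",
                           np.asarray(self.volumes, dtype=float))
        if self.values.shape != self.volumes.shape:
            raise ValueError("values and volumes must have the same length")
        if np.any(self.volumes <= 0):
            raise ValueError("segment volumes must be positive")
        if not 0.0 <= self.reference_fraction <= 1.0:
            raise ValueError("reference_fraction must be in [0, 1]")


@dataclass
class CalibrationSet:
    """A collection of calibration cases; a fit needs at least three cases
    with non-identical reference fractions."""

    cases: list[CalibrationCase] = field(default_factory=list)

    def validate_for_fit(self) -> None:
        if len(self.cases) < 3:
            raise ValueError("calibration needs at least 3 cases")
        refs = [c.reference_fraction for c in self.cases]
        if np.ptp(refs) == 0.0:
            raise ValueError("degenerate calibration set: all reference "
                             "fractions are equal")


@dataclass
class FitReport:
    """Fitted parameters with the attained objective value."""

    params: SCurveParams
    objective: float
    objective_kind: str
    n_cases: int


def _case_aif(case: CalibrationCase, u_c: np.ndarray, n: np.ndarray
              ) -> np.ndarray:
    """AIF of one case on a broadcast (U_c, n) parameter grid."""
    levels = relative_levels(case.values)
    with np.errstate(divide="ignore"):
        log_u = np.log(levels)  # -inf at exactly 0 is fine under expit
    t = 2.0 * n[..., None] * (log_u - np.log(u_c[..., None]))
    from scipy.special import expit
    p = expit(-t)
    w = case.volumes / case.volumes.sum()
    return (p * w).sum(axis=-1)


def fit_scurve_params(cal: CalibrationSet,
                      uc_grid: Sequence[float] = DEFAULT_UC_GRID,
                      n_grid: Sequence[float] = DEFAULT_N_GRID,
                      objective: str = "sse") -> FitReport:
    """Grid-search (U_c, n) for the best agreement of AIF with reference
    fractions.

    ``objective='sse'`` minimizes Σ(AIF_i − ref_i)²; ``objective='corr'``
    maximizes the Pearson correlation (reported as 1 − r).  Ties break
    toward smaller n, then smaller U_c, so the result is deterministic for
    a given grid.
    """
    cal.validate_for_fit()
    if objective not in ("sse", "corr"):
        raise ValueError("objective must be 'sse' or 'corr'")
    uc = np.asarray(uc_grid, dtype=float)
    nn = np.asarray(n_grid, dtype=float)
    if np.any((uc <= 0) | (uc > 1)) or np.any(nn <= 0):
        raise ValueError("invalid parameter grid")
    UC, NN = np.meshgrid(uc, nn, indexing="ij")
    aifs = np.stack([_case_aif(c, UC, NN) for c in cal.cases], axis=-1)
    refs = np.array([c.reference_fraction for c in cal.cases])
    if objective == "sse":
        obj = ((aifs - refs) ** 2).sum(axis=-1)
    else:
        am = aifs - aifs.mean(axis=-1, keepdims=True)
        rm = refs - refs.mean()
        denom = np.sqrt((am ** 2).sum(axis=-1) * (rm ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (am * rm).sum(axis=-1) / denom, -1.0)
        obj = 1.0 - r
    # Tie-break toward smaller n (outer scan), then smaller U_c.
    best = None
    for j in range(nn.size):          # n ascending
        for i in range(uc.size):      # u_c ascending
            v = obj[i, j]
            if best is None or v < best[0] - 1e-15:
                best = (v, i, j)
    assert best is not None
    value, i, j = best
    return FitReport(params=SCurveParams(u_c=float(uc[i]), n=float(nn[j])),
                     objective=float(value), objective_kind=objective,
                     n_cases=len(cal.cases))


def curve_fit_scurve(levels: Sequence[float], fractions: Sequence[float],
                     uc_grid: Sequence[float] = DEFAULT_UC_GRID,
                     n_grid: Sequence[float] = DEFAULT_N_GRID,
                     refine: bool = True) -> tuple[SCurveParams, float]:
    """Least-squares fit of P(U) to sampled (U, f) pairs of a level curve.

    A deterministic grid search seeds an optional local refinement
    (``scipy.optimize.least_squares``); returns the parameters and the
    residual sum of squares.
    """
    u = np.asarray(levels, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if u.shape != f.shape or u.ndim != 1:
        raise ValueError("levels and fractions must be 1D of equal length")
    if u.size < 5:
        raise ValueError("need at least 5 (level, fraction) pairs")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("levels must be in [0, 1]")
    if np.ptp(f) == 0.0:
        raise ValueError("constant fractions: s-curve parameters are "
                         "unidentifiable")

    uc = np.asarray(uc_grid, dtype=float)
    nn = np.asarray(n_grid, dtype=float)
    UC, NN = np.meshgrid(uc, nn, indexing="ij")
    with np.errstate(divide="ignore"):
        log_u = np.log(u)
    from scipy.special import expit
    t = 2.0 * NN[..., None] * (log_u - np.log(UC[..., None]))
    resid = expit(-t) - f
    sse = (resid ** 2).sum(axis=-1)
    # ties toward smaller n, then smaller u_c
    best = None
    for j in range(nn.size):
        for i in range(uc.size):
            v = sse[i, j]
            if best is None or v < best[0] - 1e-15:
                best = (v, i, j)
    assert best is not None
    value, i, j = best
    params = SCurveParams(u_c=float(uc[i]), n=float(nn[j]))

    if refine:
        from scipy.optimize import least_squares

        def residual(theta):
            p = SCurveParams(u_c=float(np.clip(theta[0], 1e-6, 1.0)),
                             n=float(max(theta[1], 1e-6)))
            return s_curve_weight(u, p) - f

        sol = least_squares(residual, x0=[params.u_c, params.n],
                            bounds=([1e-6, 1e-6], [1.0, 100.0]))
        refined = SCurveParams(u_c=float(sol.x[0]), n=float(sol.x[1]))
        refined_sse = float((residual(sol.x) ** 2).sum())
        if refined_sse <= value:
            return refined, refined_sse
    return params, float(value)
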