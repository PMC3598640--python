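"""The Absolute Infarcted Fraction (AIF) statistic.

AIF estimates the infarcted fraction of the myocardial wall from a
20-segment perfusion polar map without a normal-perfusion database.  Each
segment's relative level U_s (uptake divided by the hottest segment's
uptake) is converted to an infarcted-fraction weight by an s-shaped curve

    P(U) = 1 / (1 + (U / U_c)^(2n)),

where U_c is the level at the inflection point and n sets the slope there
(fitted values U_c = 0.55, n = 9).  The weights are then averaged with the
segment wall volumes

    AIF = Σ_s P(U_s) V_s / Σ_s V_s,

where V_s = π·D_s·L_s·T_s / N_s comes from per-ring measurements on the
long-axis slices: N_s segments per ring, ring mean diameter D_s, long-axis
length L_s and transverse thickness T_s (arbitrary but consistent units —
AIF is unit-free).

For the cylindrical phantom the map reduces to a single ring of six equal
60° segments, so the model-side AIF is the plain mean of P over six arcs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "RING_LAYOUT",
    "RING_ORDER",
    "SCurveParams",
    "SegmentGeometryTable",
    "PolarMap",
    "AIFResult",
    "segment_volume",
    "relative_levels",
    "s_curve_weight",
    "compute_aif",
    "segment_levels_from_sweep",
    "model_aif",
    "segment_true_fraction_table",
]

#: Segments per ring of the 20-segment polar map.
RING_LAYOUT = {"basal": 6, "middle": 6, "apical": 6, "apex": 2}
RING_ORDER = ("basal", "middle", "apical", "apex")
N_SEGMENTS = 20

GEOMETRY_COLUMNS = ["segment_id", "ring", "N_s", "D_s", "L_s", "T_s"]


@dataclass(frozen=True)
class SCurveParams:
    """Parameters of the s-shaped severity curve: inflection level ``u_c``
    and slope parameter ``n`` (a positive real; the reference fit gave the
    integer 9)."""

    u_c: float = 0.55
    n: float = 9.0

    def __post_init__(self) -> None:
        if not 0.0 < self.u_c <= 1.0:
            raise ValueError("u_c must be in (0, 1]")
        if self.n <= 0:
            raise ValueError("n must be positive")


def segment_volume(n_s: float, d_s: float, l_s: float, t_s: float) -> float:
    """Wall volume of one segment: the circular ring volume π·D·L·T shared
    equally by the N_s segments of the ring."""
    if min(n_s, d_s, l_s, t_s) <= 0:
        raise ValueError("segment dimensions must be positive")
    return np.pi * d_s * l_s * t_s / n_s


class SegmentGeometryTable:
    """Per-segment geometry measurements for the 20-segment polar map."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in GEOMETRY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"geometry table missing columns: {missing}")
        frame["segment_id"] = frame["segment_id"].astype(int)
        frame["N_s"] = frame["N_s"].astype(int)
        for col in ("D_s", "L_s", "T_s"):
            frame[col] = frame[col].astype(float)
        ids = sorted(frame["segment_id"])
        if len(frame) != N_SEGMENTS or ids != list(range(1, N_SEGMENTS + 1)):
            expected = set(range(1, N_SEGMENTS + 1))
            missing_ids = sorted(expected - set(ids))
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"geometry table must have segments 1-{N_SEGMENTS} exactly "
                f"once (missing: {missing_ids}, duplicated: {dupes})")
        counts = frame["ring"].value_counts().to_dict()
        if counts != RING_LAYOUT:
            raise ValueError(
                f"ring layout must be {RING_LAYOUT}, got {counts}")
        for ring, n in RING_LAYOUT.items():
            bad = frame.loc[(frame["ring"] == ring) & (frame["N_s"] != n)]
            if len(bad):
                raise ValueError(
                    f"N_s must be {n} for ring '{ring}' "
                    f"(segments {sorted(bad['segment_id'])})")
        dims = frame[["D_s", "L_s", "T_s"]].to_numpy(dtype=float)
        if np.any(dims <= 0):
            raise ValueError("all segment dimensions must be positive")
        self.frame = frame.sort_values("segment_id").reset_index(drop=True)

    @property
    def segment_ids(self) -> np.ndarray:
        return self.frame["segment_id"].to_numpy()

    @property
    def volumes(self) -> np.ndarray:
        f = self.frame
        return (np.pi * f["D_s"] * f["L_s"] * f["T_s"]
                / f["N_s"]).to_numpy(dtype=float)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def scaled(self, factor: float) -> "SegmentGeometryTable":
        f = self.frame.copy()
        for col in ("D_s", "L_s", "T_s"):
            f[col] = f[col] * factor
        return SegmentGeometryTable(f)


class PolarMap:
    """20 segment uptake values (arbitrary units) and their relative
    levels."""

    def __init__(self, values: Sequence[float],
                 segment_ids: Sequence[int] | None = None):
        values = np.asarray(values, dtype=float)
        if values.shape != (N_SEGMENTS,):
            raise ValueError(f"polar map needs {N_SEGMENTS} segment values")
        if np.any(values < 0):
            raise ValueError("uptake values must be non-negative")
        if values.max() <= 0:
            raise ValueError("polar map must have a positive segment")
        if segment_ids is None:
            segment_ids = np.arange(1, N_SEGMENTS + 1)
        segment_ids = np.asarray(segment_ids, dtype=int)
        if sorted(segment_ids) != list(range(1, N_SEGMENTS + 1)):
            raise ValueError("segment ids must be 1-20 exactly once")
        order = np.argsort(segment_ids)
        self.segment_ids = segment_ids[order]
        self.values = values[order]

    @property
    def relative_levels(self) -> np.ndarray:
        return relative_levels(self.values)


def relative_levels(values: Sequence[float]) -> np.ndarray:
    """Uptake values divided by the hottest value; the maximum is exactly
    1."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("uptake values must be non-negative")
    peak = values.max()
    if peak <= 0:
        raise ValueError("all-zero uptake: relative levels undefined")
    return values / peak


def s_curve_weight(u, params: SCurveParams = SCurveParams()):
    """Infarcted-fraction weight P(U) = 1 / (1 + (U/U_c)^(2n)).

    Strictly decreasing in U with P(U_c) = 1/2 and P(0) = 1.  Evaluated in
    log space so large exponents cannot overflow.  Accepts scalars or
    arrays; U must lie in [0, 1].
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("relative level must be in [0, 1]")
    with np.errstate(divide="ignore"):
        t = 2.0 * params.n * (np.log(u_arr) - np.log(params.u_c))
    p = expit(-t)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(p)
    return p


@dataclass
class AIFResult:
    """AIF with its per-segment breakdown (levels, weights, volumes)."""

    aif: float
    per_segment: pd.DataFrame
    total_volume: float

    def to_dict(self) -> dict:
        return {
            "aif": self.aif,
            "total_volume": self.total_volume,
            "segments": self.per_segment.to_dict(orient="records"),
        }


def compute_aif(pmap: PolarMap, geom: SegmentGeometryTable,
                params: SCurveParams = SCurveParams()) -> AIFResult:
    """Volume-weighted AIF of a 20-segment polar map:
    AIF = Σ P(U_s)·V_s / Σ V_s."""
    if not np.array_equal(pmap.segment_ids, geom.segment_ids):
        raise ValueError("polar map and geometry segment ids do not match")
    levels = pmap.relative_levels
    weights = s_curve_weight(levels, params)
    volumes = geom.volumes
    total = volumes.sum()
    aif = float((weights * volumes).sum() / total)
    per_segment = pd.DataFrame({
        "segment_id": pmap.segment_ids,
        "ring": geom.frame["ring"].to_numpy(),
        "value": pmap.values,
        "relative_level": levels,
        "weight": weights,
        "volume": volumes,
    })
    return AIFResult(aif=aif, per_segment=per_segment,
                     total_volume=float(total))


def segment_levels_from_sweep(centers: np.ndarray, activities: np.ndarray,
                              offset_deg: float = 0.0,
                              n_segments: int = 6) -> np.ndarray:
    """Relative levels of an aligned ring of equal segments read off a
    circumferential sweep.

    Segment centres sit at ``offset + width/2 + k·width`` (boundaries at
    multiples of the segment width, shifted by ``offset_deg``); the nearest
    sampled sweep positions are used and the picked activities are
    renormalized to their own maximum, mirroring how a real polar map is
    normalized to its hottest segment.
    """
    centers = np.asarray(centers, dtype=float)
    activities = np.asarray(activities, dtype=float)
    width = 360.0 / n_segments
    wanted = (offset_deg + width / 2.0 + width * np.arange(n_segments)) % 360.0
    idx = [int(np.argmin(np.abs(((centers - w + 180.0) % 360.0) - 180.0)))
           for w in wanted]
    picked = activities[idx]
    peak = picked.max()
    if peak <= 0:
        raise ValueError("all segment activities are zero")
    return picked / peak


def model_aif(segment_levels: Sequence[float],
              params: SCurveParams = SCurveParams()) -> float:
    """AIF of the cylindrical model: the plain mean of P over the ring of
    equal-volume segments (equal V_s makes Eq. 5 an unweighted mean)."""
    levels = relative_levels(segment_levels)
    return float(np.mean(s_curve_weight(levels, params)))


def segment_true_fraction_table(defect, geom: SegmentGeometryTable,
                                segment_width: float = 60.0) -> np.ndarray:
    """Analytic per-segment true infarcted fraction for a full-length
    transmural defect mapped onto the 20-segment layout.

    The six segments of each ring span [k·width, (k+1)·width); the apex cap
    lies beyond the full-length cylindrical defect and is taken as normal.
    """
    from ._util import circ_interval_overlap

    ring_fracs = []
    for k in range(int(round(360.0 / segment_width))):
        center = segment_width / 2.0 + k * segment_width
        overlap = circ_interval_overlap(center, segment_width,
                                        defect.polar_center,
                                        defect.polar_extension)
        ring_fracs.append(overlap / segment_width
                          * (1.0 - defect.residual_activity_fraction))
    out = np.zeros(N_SEGMENTS)
    rings = geom.frame["ring"].to_numpy()
    per_ring_idx = {r: 0 for r in RING_ORDER}
    for i, ring in enumerate(rings):
        if ring == "apex":
            out[i] = 0.0
        else:
            out[i] = ring_fracs[per_ring_idx[ring]]
            per_ring_idx[ring] += 1
    return out
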