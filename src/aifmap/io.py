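"""File formats, run configuration and synthetic fixture generation.

CSV dialect everywhere: comma-separated, dot decimal, UTF-8, mandatory
header row.  Polar maps are ``segment_id,ring,value``; geometry tables are
``segment_id,ring,N_s,D_s,L_s,T_s``; level curves are
``center_angle_deg,relative_level,true_fraction``.  Volumes are exported as
flat binary float32 with a JSON sidecar (shape, spacing, origin) and,
optionally, as per-slice PGM images for quick inspection.

``generate_fixture`` stands in for an acquired dataset: it derives polar-map
segment values from the phantom pipeline (optionally with seeded
multiplicative noise) together with a manifest of known true fractions, so
every downstream module is testable without any acquired SPECT data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .aifcore import (GEOMETRY_COLUMNS, N_SEGMENTS, RING_LAYOUT, RING_ORDER,
                      PolarMap, SCurveParams, SegmentGeometryTable,
                      segment_true_fraction_table)
from .arcscan import LevelCurve
from .phantom import (ActivityVolume, BackgroundSpec, BlurSpec, DefectSpec,
                      MotionSpec, PhantomSpec)

__all__ = [
    "read_polar_map_csv",
    "write_polar_map_csv",
    "read_geometry_csv",
    "write_geometry_csv",
    "default_mouse_geometry",
    "write_level_curve_csv",
    "read_level_curve_csv",
    "save_volume",
    "load_volume",
    "write_pgm_stack",
    "RunConfig",
    "generate_fixture",
]

_FLOAT_FMT = "{:.9g}"


# ---------------------------------------------------------------------------
# Polar map and geometry CSV

def _ring_of_segment(segment_id: int) -> str:
    if 1 <= segment_id <= 6:
        return "basal"
    if 7 <= segment_id <= 12:
        return "middle"
    if 13 <= segment_id <= 18:
        return "apical"
    return "apex"


def read_polar_map_csv(path) -> PolarMap:
    """Read a 20-row polar map CSV (segment_id, ring, value)."""
    frame = pd.read_csv(path)
    for col in ("segment_id", "value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    ids = frame["segment_id"].astype(int).tolist()
    expected = set(range(1, N_SEGMENTS + 1))
    if sorted(ids) != sorted(expected):
        missing = sorted(expected - set(ids))
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        lines = [str(frame.index[frame["segment_id"] == d][0] + 2)
                 for d in dupes]
        raise ValueError(
            f"{path}: polar map must contain segments 1-20 exactly once "
            f"(missing ids: {missing}; duplicated ids: {dupes}"
            f"{' at lines ' + ','.join(lines) if lines else ''})")
    values = frame["value"].to_numpy(dtype=float)
    if np.any(values < 0):
        bad = int(frame.index[frame["value"] < 0][0]) + 2
        raise ValueError(f"{path}: negative uptake at line {bad}")
    return PolarMap(values, segment_ids=ids)


def write_polar_map_csv(path, pmap: PolarMap) -> None:
    lines = ["segment_id,ring,value"]
    for sid, val in zip(pmap.segment_ids, pmap.values):
        lines.append(f"{sid},{_ring_of_segment(int(sid))},"
                     + _FLOAT_FMT.format(val))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_geometry_csv(path) -> SegmentGeometryTable:
    """Read and validate a 20-row geometry CSV
    (segment_id, ring, N_s, D_s, L_s, T_s)."""
    frame = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dims = frame[["D_s", "L_s", "T_s"]].to_numpy(dtype=float)
    if np.any(dims <= 0):
        row = int(np.argwhere(dims <= 0)[0][0]) + 2
        raise ValueError(f"{path}: non-positive dimension at line {row}")
    try:
        return SegmentGeometryTable(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_geometry_csv(path, geom: SegmentGeometryTable) -> None:
    f = geom.frame
    lines = [",".join(GEOMETRY_COLUMNS)]
    for _, row in f.iterrows():
        lines.append(
            f"{int(row['segment_id'])},{row['ring']},{int(row['N_s'])},"
            + ",".join(_FLOAT_FMT.format(row[c])
                       for c in ("D_s", "L_s", "T_s")))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_mouse_geometry() -> SegmentGeometryTable:
    """A plausible mouse-sized geometry table (units: mm as measured on
    long-axis slices): three six-segment rings tapering toward the apex
    plus a small two-segment apex cap."""
    rows = []
    ring_dims = {
        "basal": (5.4, 2.5, 1.0),
        "middle": (5.4, 2.5, 1.0),
        "apical": (4.4, 2.5, 1.0),
        "apex": (1.6, 1.0, 1.0),
    }
    sid = 1
    for ring in RING_ORDER:
        d, l, t = ring_dims[ring]
        for _ in range(RING_LAYOUT[ring]):
            rows.append({"segment_id": sid, "ring": ring,
                         "N_s": RING_LAYOUT[ring], "D_s": d, "L_s": l,
                         "T_s": t})
            sid += 1
    return SegmentGeometryTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Level curve CSV

def write_level_curve_csv(path, curve: LevelCurve) -> None:
    lines = ["center_angle_deg,relative_level,true_fraction"]
    for c, u, f in zip(curve.center_angles, curve.levels, curve.fractions):
        lines.append(",".join(_FLOAT_FMT.format(v) for v in (c, u, f)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_level_curve_csv(path) -> LevelCurve:
    frame = pd.read_csv(path)
    return LevelCurve(frame["center_angle_deg"].to_numpy(),
                      frame["relative_level"].to_numpy(),
                      frame["true_fraction"].to_numpy())


# ---------------------------------------------------------------------------
# Volume export

def save_volume(path_stem, vol: ActivityVolume) -> None:
    """Write a volume as float32 raw binary plus a JSON metadata sidecar."""
    stem = Path(path_stem)
    raw = stem.with_suffix(".raw")
    vol.values.astype(np.float32).tofile(raw)
    meta = {
        "shape": list(vol.values.shape),
        "spacing_mm": vol.spacing,
        "origin_mm": [float(v) for v in vol.origin],
        "dtype": "float32",
        "order": "C (x, y, z)",
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n",
                                         encoding="utf-8")


def load_volume(path_stem) -> ActivityVolume:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text(encoding="utf-8"))
    values = np.fromfile(stem.with_suffix(".raw"),
                         dtype=np.float32).reshape(meta["shape"])
    return ActivityVolume(values.astype(float), float(meta["spacing_mm"]),
                          np.asarray(meta["origin_mm"]))


def write_pgm_stack(directory, vol: ActivityVolume,
                    axis: int = 2) -> list[Path]:
    """Export per-slice 8-bit PGM images (plain text, P2) for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = vol.values.max()
    scale = 255.0 / peak if peak > 0 else 0.0
    paths = []
    for k in range(vol.values.shape[axis]):
        sl = np.take(vol.values, k, axis=axis)
        img = np.round(sl * scale).astype(int)
        lines = ["P2", f"{img.shape[1]} {img.shape[0]}", "255"]
        lines += [" ".join(str(v) for v in row) for row in img]
        p = directory / f"slice_{k:04d}.pgm"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run, assembled from YAML
    blocks and/or CLI flags; the seed governs fixture noise only (the
    phantom pipeline itself is deterministic)."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    defect: DefectSpec = field(default_factory=DefectSpec)
    motion: MotionSpec = field(default_factory=MotionSpec)
    blur: BlurSpec = field(default_factory=BlurSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    scurve: SCurveParams = field(default_factory=SCurveParams)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        blocks = {
            "phantom": PhantomSpec, "defect": DefectSpec,
            "motion": MotionSpec, "blur": BlurSpec,
            "background": BackgroundSpec, "scurve": SCurveParams,
        }
        kwargs = {}
        for name, typ in blocks.items():
            if name in raw:
                kwargs[name] = typ(**raw[name])
        for scalar in ("seed", "output_dir"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(
                v) else v
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Fixture generation

def _pipeline_segment_values(config: RunConfig, ideal: bool) -> np.ndarray:
    """Six ring-segment activities from the phantom pipeline, aligned to
    the segmentation (defect centre on a segment centre)."""
    from .arcscan import radial_window, sweep_arc_activities
    from .phantom import (apply_motion, apply_psf, build_phantom,
                          default_margins)

    motion = None if ideal else config.motion
    blur = None if ideal else config.blur
    bg = BackgroundSpec(0.0) if ideal else config.background
    xy_margin, z_margin = default_margins(motion, blur)
    vol = build_phantom(config.phantom, config.defect, bg,
                        xy_margin=xy_margin, z_margin=z_margin)
    if motion is not None and not motion.is_static:
        vol = apply_motion(vol, motion,
                           defect_center_deg=config.defect.polar_center)
    if blur is not None and blur.psf_fwhm > 0:
        vol = apply_psf(vol, blur)
    centers, acts = sweep_arc_activities(
        vol, width=60.0, step=1.0, window=radial_window(config.phantom))
    wanted = (30.0 + 60.0 * np.arange(6)) % 360.0
    idx = [int(np.argmin(np.abs(((centers - w + 180) % 360) - 180)))
           for w in wanted]
    return acts[idx]


def _reference_fraction(config: RunConfig,
                        geom: SegmentGeometryTable) -> float:
    """Volume-weighted true infarcted fraction of the 20-segment map (apex
    segments are outside the full-length cylindrical defect)."""
    fractions = segment_true_fraction_table(config.defect, geom)
    vols = geom.volumes
    return float((fractions * vols).sum() / vols.sum())


def generate_fixture(kind: str, out_dir, config: RunConfig,
                     seed: Optional[int] = None,
                     noise_sd: float = 0.0,
                     n_cases: int = 6,
                     extensions: Optional[Sequence[float]] = None,
                     ideal: bool = False) -> dict:
    """Write synthetic polar-map + geometry CSVs derived from the phantom
    pipeline, plus a manifest with the known true fraction per case.

    kind: "normal" (no defect), "defect" (single case with the configured
    defect) or "calibration_set" (n_cases spanning ``extensions``).
    Multiplicative log-normal noise of width ``noise_sd`` is applied to the
    segment values when requested; the same seed regenerates byte-identical
    files.
    """
    if kind not in ("normal", "defect", "calibration_set"):
        raise ValueError("kind must be 'normal', 'defect' or "
                         "'calibration_set'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = default_mouse_geometry()
    write_geometry_csv(out_dir / "geometry.csv", geom)

    if kind == "calibration_set":
        if extensions is None:
            extensions = np.linspace(0.0, 240.0, n_cases)
        configs = [dataclasses.replace(
            config, defect=dataclasses.replace(config.defect,
                                               polar_extension=float(e)))
            for e in extensions]
        names = [f"case_{i:02d}" for i in range(len(configs))]
    else:
        if kind == "normal":
            config = dataclasses.replace(
                config, defect=dataclasses.replace(config.defect,
                                                   polar_extension=0.0))
        configs = [config]
        names = [kind]

    manifest_rows = []
    for name, cfg in zip(names, configs):
        ring_acts = _pipeline_segment_values(cfg, ideal=ideal)
        # basal/middle/apical rings replicate the six swept activities;
        # the apex cap sits outside the full-length defect and is normal.
        values = np.concatenate([np.tile(ring_acts, 3),
                                 np.full(2, ring_acts.max())])
        if noise_sd > 0:
            values = values * np.exp(rng.normal(0.0, noise_sd,
                                                size=values.size))
        pmap = PolarMap(values)
        write_polar_map_csv(out_dir / f"{name}.csv", pmap)
        manifest_rows.append(
            (name, _reference_fraction(cfg, geom)))

    lines = ["case_id,reference_fraction"]
    lines += [f"{n},{_FLOAT_FMT.format(r)}" for n, r in manifest_rows]
    (out_dir / "manifest.csv").write_text("\n".join(lines) + "\n",
                                          encoding="utf-8")
    meta = {
        "kind": kind,
        "seed": config.seed if seed is None else seed,
        "noise_sd": noise_sd,
        "ideal": ideal,
        "config_hash": config.config_hash(),
    }
    (out_dir / "fixture.json").write_text(json.dumps(meta, indent=2,
                                                     sort_keys=True) + "\n",
                                          encoding="utf-8")
    return meta
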