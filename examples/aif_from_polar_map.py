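"""Compute the AIF of a measured 20-segment polar map.

Generates a synthetic dataset (polar map + segment geometry CSVs) from the
phantom pipeline with a 240° defect, then sizes the infarct with the
s-curve calibration U_c = 0.55, n = 9.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aifmap import (DefectSpec, PhantomSpec, RunConfig, compute_aif,
                    generate_fixture, read_geometry_csv, read_polar_map_csv)

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(phantom=PhantomSpec(length=4.0, grid_spacing=0.2),
                    defect=DefectSpec(240.0, 60.0))
    generate_fixture("defect", tmp, cfg, ideal=True)
    pmap = read_polar_map_csv(Path(tmp) / "defect.csv")
    geom = read_geometry_csv(Path(tmp) / "geometry.csv")
    manifest = pd.read_csv(Path(tmp) / "manifest.csv")

result = compute_aif(pmap, geom)
print(result.per_segment.to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}"))
print(f"\nAIF = {result.aif:.4f}")
print(f"known true fraction of this synthetic case: "
      f"{manifest['reference_fraction'].iloc[0]:.4f}")
print("AIF is the volume-weighted mean of the s-curve weights P(U_s): "
      "segments at level 0 count as fully infarcted, normal segments "
      "contribute ~0.")
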