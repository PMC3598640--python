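"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

#: Conversion factor between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def circ_diff(a, b):
    """Signed circular difference a - b in degrees, mapped to (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circ_interval_overlap(center_a: float, width_a: float,
                          center_b: float, width_b: float) -> float:
    """Angular overlap (degrees) of two arcs on the circle.

    Arcs are [center - width/2, center + width/2]; wrap-around is handled by
    testing the relative offset at -360, 0 and +360 degrees.
    """
    if width_a <= 0.0 or width_b <= 0.0:
        return 0.0
    delta = float(circ_diff(center_b, center_a))
    total = 0.0
    for k in (-360.0, 0.0, 360.0):
        lo = max(-width_a / 2.0, delta + k - width_b / 2.0)
        hi = min(width_a / 2.0, delta + k + width_b / 2.0)
        if hi > lo:
            total += hi - lo
    return min(total, min(width_a, width_b, 360.0))
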