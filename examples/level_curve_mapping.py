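"""Compute the infarcted-fraction-vs-relative-level curve of a 60° defect
under the standard blur, and report the reduced level range.

Resolution and breathing compress the full infarcted-fraction range (0, 1)
of a segment into a narrow band of observable relative levels — the reason
a steep s-curve, rather than the ideal line f = 1 − U, converts levels to
infarct fractions.
"""

from aifmap import (BackgroundSpec, BlurSpec, DefectSpec, MotionSpec,
                    PhantomSpec)
from aifmap.arcscan import level_curve, mapped_level_range

ideal = level_curve(PhantomSpec(), DefectSpec(60.0, 30.0), None, None,
                    BackgroundSpec(0.0))
blurred = level_curve(PhantomSpec(), DefectSpec(60.0, 30.0), MotionSpec(),
                      BlurSpec(), BackgroundSpec(0.2))

err = abs(ideal.fractions + ideal.levels - 1.0).max()
print(f"ideal tomography: max |f + U - 1| = {err:.4f} (exact line)")
lo, hi = mapped_level_range(blurred)
print(f"full blur: fraction range (0, 1) mapped into levels "
      f"({lo:.3f}, {hi:.3f})")
print("A segment fully inside the defect no longer reads level 0 — it "
      f"bottoms out near {lo:.2f}; a segment just outside the defect "
      f"already reads ~{hi:.2f} rather than 1.")
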