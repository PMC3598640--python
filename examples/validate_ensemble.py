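"""Run a reduced simulated-infarction ensemble and summarize agreement of
AIF with the known true infarcted fraction.

The full validation grid (13 extensions × 3 backgrounds × 2 breathing
directions × 6 offsets at 0.1 mm) takes a couple of minutes; this example
uses a coarser phantom and a smaller grid for a quick look.  Use
``aifmap validate --preset paper`` (or the EnsembleSpec defaults) for the
full run.
"""

from aifmap import (EnsembleSpec, PhantomSpec, SCurveParams, bland_altman,
                    linear_regression, paired_t_test, simulate_ensemble)

spec = EnsembleSpec(defect_extensions=(0, 60, 120, 180, 240),
                    backgrounds=(0.1, 0.3),
                    breath_directions=("tangential", "perpendicular"),
                    defect_offsets=(0, 20, 40),
                    phantom=PhantomSpec(grid_spacing=0.15))
pairs, frame = simulate_ensemble(spec, SCurveParams(0.55, 9))

reg = linear_regression(pairs)
ba = bland_altman(pairs)
tt = paired_t_test(pairs)
print(f"{pairs.n} simulated infarctions")
print(f"OLS: AIF = {reg['slope']:.3f} x truth + {reg['intercept']:+.3f}, "
      f"R² = {reg['r_squared']:.3f}")
print(f"Bland-Altman: bias {ba['bias']:+.3f}, limits of agreement "
      f"[{ba['lower_loa']:+.3f}, {ba['upper_loa']:+.3f}] (±2 SD)")
print(f"paired t test: t = {tt['t']:.2f}, df = {tt['df']}, "
      f"p = {tt['p_value']:.3g}")
print("A slope near 1 with a small intercept means AIF tracks the true "
      "infarcted fraction across defect sizes, backgrounds, breathing "
      "directions and defect positions.")
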