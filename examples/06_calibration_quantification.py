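"""Calibration curves, LOD/LOQ and equivalent-based semi-quantification.

A linear external-standard curve converts XIC areas into standard
equivalents; LOD and LOQ follow the 3.3*SD/slope and 10*SD/slope rules,
so LOQ/LOD is always 10/3.3.  Colorimetric assay curves (total phenolics
with gallic acid, total flavonoids with rutin) are inverted the same way.
"""

import numpy as np

import chemometab as cm

rng = np.random.default_rng(6)
conc = np.repeat([5.0, 50.0, 200.0, 500.0, 750.0], 3)  # ug/mL, triplicate injections
area = 37.0 * conc + 12.0 + rng.standard_normal(conc.size) * 8.0
curve = cm.fit_calibration(conc, area, analyte="chlorogenic acid")
print(f"{curve.analyte}: slope {curve.slope:.3f}, intercept {curve.intercept:.2f}, "
      f"R2 {curve.r_squared:.5f}")
print(f"LOD {curve.lod:.3f} ug/mL, LOQ {curve.loq:.3f} ug/mL "
      f"(ratio {curve.loq / curve.lod:.3f} = 10/3.3)")

value = cm.quantify_equivalents(area.mean(), curve, extract_mass_g=0.010, volume_ml=1.0)
print(f"sample at the mean calibration response: {value:.2f} mg equivalents / g extract")
tiny = cm.quantify_equivalents(curve.predict_response(curve.loq / 2), curve, 0.010, 1.0)
print(f"response below the quantification limit reports: {tiny!r}")

tpc = cm.assay_curve(0.0015, -0.149, "gallic acid")
print(f"total phenolics: absorbance 0.601 -> {cm.invert_assay_curve(0.601, tpc):.0f} ug/mL "
      f"gallic acid equivalents")
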