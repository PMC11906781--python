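"""Annotation mass arithmetic: formula -> monoisotopic mass -> adduct m/z -> ppm.

Recomputes the bundled ten-metabolite table (printed formulas, adducts and
observed m/z from a published cell-metabolomics annotation table) and
checks every record against the < 5 ppm identification tolerance.
"""

import chemometab as cm
from chemometab.annotate import annotate_records

taurine = cm.parse_formula("C2H7NO3S")
mass = cm.monoisotopic_mass(taurine)
print(f"taurine composition {taurine}, monoisotopic mass {mass:.6f} Da")
print(f"[M+H]+ m/z {cm.adduct_mz(mass, '[M+H]+'):.6f}, "
      f"ppm error vs observed 126.0217: {cm.ppm_error(126.0217, 'C2H7NO3S', '[M+H]+'):+.2f}")

ann = annotate_records(cm.bundled_annotations())
cols = ["metabolite", "observed_mz", "theoretical_mz", "calc_neutral_mass", "ppm_error"]
print(ann[cols].round(5).to_string(index=False))
print(f"max |ppm error| = {ann['ppm_error'].abs().max():.2f} "
      f"(identification tolerance: < 5 ppm)")
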