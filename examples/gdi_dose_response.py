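"""Dose response to a GDI-type G-alpha(q/11) inhibitor (FR900359/YM-254890 class).

The drug reversibly sequesters GDP-bound G-alpha.  Counterintuitively this
suppresses even "constitutively active" mutants, because every G-alpha still
visits the GDP state — just more rarely for hydrolysis-dead mutants, which is
exactly why Q209L needs ~an order of magnitude more drug than the partially
GAP-sensitive R183C (the published log-shift).  IC50s are in the model's
concentration unit (total G-alpha = 1).
"""

from gqcycle import load_preset, parse_genotype
from gqcycle.gdi import DrugParameters, dose_response

params = load_preset("revised")
drug = DrugParameters()  # Kd = 1e-4 in units of total G-alpha
print(f"drug Kd = {drug.kd:g}\n")
ic50s = {}
for g in ("WT", "GNAQ:R183C:het", "GNAQ:Q209L:het"):
    curve = dose_response(params, parse_genotype(g), drug)
    ic50s[g] = curve.ic50_trio
    print(f"{g:18s} IC50(TRIO) = {curve.ic50_trio:.3e}   "
          f"IC50(PLC) = {curve.ic50_plc:.3e}")
shift = ic50s["GNAQ:Q209L:het"] / ic50s["GNAQ:R183C:het"]
print(f"\nQ209L / R183C IC50 shift: {shift:.1f}x  (the published log-shift)")
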