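"""Steady-state activation of TRIO and PLC-beta across disease genotypes.

Solves the G-protein cycle to its dynamic equilibrium for each uveal-melanoma
genotype under both shipped parameter presets and prints active-effector
levels and fold changes over the all-WT baseline.  Fold > 1 means the mutant
constitutively activates that pathway arm; under the initial preset the
CYSLTR2 L129Q row shows the near-complete loss of PLC-beta activation
(relative to GNAQ Q209L) that motivated the parameter revision.
"""

import pandas as pd

from gqcycle import WT, fold_changes, load_preset, parse_genotype, solve_steady_state

GENOTYPES = ["GNAQ:Q209L:het", "GNAQ:Q209L:hom", "GNAQ:Q209P:het",
             "GNAQ:R183C:het", "GNAQ:R183C:hom", "CYSLTR2:L129Q:het"]

for preset in ("initial", "revised"):
    params = load_preset(preset)
    base = solve_steady_state(params, WT)
    rows = [{"genotype": "WT", "active_TRIO": base.active_trio,
             "active_PLC": base.active_plc, "fold_TRIO": 1.0, "fold_PLC": 1.0}]
    for g in GENOTYPES:
        r = solve_steady_state(params, parse_genotype(g))
        ft, fp = fold_changes(r, base)
        rows.append({"genotype": g, "active_TRIO": r.active_trio,
                     "active_PLC": r.active_plc, "fold_TRIO": ft,
                     "fold_PLC": fp})
    print(f"\n=== preset: {preset} ===")
    print(pd.DataFrame(rows).to_string(index=False, float_format="%.4g"))
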