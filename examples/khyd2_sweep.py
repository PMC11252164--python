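"""Sweep of PLC-beta's GAP strength (k_hyd2 as fold over basal hydrolysis).

With the revised 4x TRIO-over-PLC mutant bias fixed, active TRIO and
PLC-beta are tracked for WT, het GNAQ Q209L and het CYSLTR2 L129Q while
k_hyd2/k_hyd sweeps from 0.5 to 1000.  Because the L129Q network signals
through fully GAP-sensitive WT G-alpha, strong PLC-beta GAP activity
extinguishes its own PLC-beta signal — the "match" column marks the
GAP-strength region reproducing the experimental activation pattern.
"""

import numpy as np

from gqcycle import load_preset
from gqcycle.explore import khyd2_sweep

params = load_preset("revised")
ratios = np.logspace(np.log10(0.5), 3, 16)
df = khyd2_sweep(params, ratios)
wide = df.pivot_table(index=["ratio", "match"], columns="genotype",
                      values="active_plc").reset_index()
print("active PLC-beta vs k_hyd2/k_hyd:")
print(wide.to_string(index=False, float_format="%.4f"))
lo = df[df["match"]]["ratio"].min()
hi = df[df["match"]]["ratio"].max()
print(f"\nmatch region on this grid: k_hyd2/k_hyd in [{lo:.1f}, {hi:.1f}]")
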