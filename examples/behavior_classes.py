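"""Diverging-behavior classes and experiment-matching parameter sets.

Over wide parameter ranges the model allows qualitatively different
relationships between the CYSLTR2 L129Q and GNAQ Q209L networks.  Each
sampled set is classified by whether L129Q activates each pathway arm
strongly or weakly relative to Q209L, and flagged as "matching" the
experimental observation (L129Q: PLC-beta >= Q209L's, TRIO < Q209L's).
The effector bias and k_hyd2 are the parameters that best separate matching
from non-matching sets.  (n = 400 here for speed; shipped analyses use 2000.)
"""

from gqcycle import load_preset
from gqcycle.explore import (behavior_fractions, default_ranges,
                             evaluate_batch, ks_discriminate, roc_classifier,
                             sample_parameter_sets)

params = load_preset("initial")
batch = sample_parameter_sets(default_ranges(params), "lhs", n=400, seed=11)
print(f"evaluating {batch.n} parameter sets...")
evaluate_batch(batch, params)

print("\nbehavior-class fractions (rows) by weak/strong threshold theta:")
print((100 * behavior_fractions(batch)).round(1))
print(f"\nexperiment-match rate: {batch.ok_rows()['match'].mean():.1%}")

print("\nKS discrimination of match vs non-match, per parameter:")
print(ks_discriminate(batch).to_string(index=False))
for par, direction in (("effector_bias", "ge"), ("k_hyd2", "lt")):
    auc = roc_classifier(batch, par, direction).auc
    print(f"AUC({par}, {direction}) = {auc:.3f}")
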