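# gqcycle

Mechanistic steady-state modeling of oncogenic CysLT₂R / Gα(q/11) signaling in
uveal melanoma (UM).

Nearly every UM carries one of a set of mutually exclusive activating mutations
in the *CYSLTR2*/*GNAQ*/*GNA11*/*PLCB4* axis: the GPCR CysLT₂R (L129Q), or the
Gα subunits it activates (Q209L/P, R183C).  `gqcycle` implements a mass-action
kinetic model of the heterotrimeric G-protein cycle behind these mutations —
receptor-catalyzed nucleotide exchange, hydrolysis (intrinsic, RGS-catalyzed,
and by the effector PLCβ acting as its own GAP), effector binding to TRIO and
PLCβ, and Gβγ re-association — with **wild-type and mutant Gα carried as
distinct species**.  The model's readouts are the steady-state concentrations
of the GαGTP·TRIO and GαGTP·PLCβ complexes ("active TRIO", proxying FAK/YAP
signaling, and "active PLCβ", proxying PKC/ERK signaling).

For a heterozygous *GNAQ* mutation, mutant protein takes 25% of the total Gα
pool (GNAQ and GNA11 are treated as biochemically identical, each holding half
the pool); homozygous takes 50%.  *CYSLTR2* L129Q is modeled as 50% of the
receptor population locked in the active (GEF-competent) conformation.
Mutants differ from WT by scalings of their hydrolysis rates (r_hyd, r_gap ≈ 0
for Q209L/P; intermediate for R183C) and effector association rates
(`effector_bias` = mutant TRIO-over-PLCβ association scaling).

On top of the core model the package provides:

* **GDI drug targeting** — an FR900359/YM-254890-type inhibitor that
  reversibly sequesters GDP-bound Gα; dose-response curves and IC50s
  reproduce the log-shift in sensitivity between partially GAP-sensitive
  (R183C) and GAP-dead (Q209L) mutants.
* **Global parameter exploration** — Saltelli/Sobol total-order sensitivity of
  the Q209L-vs-L129Q activation differences; classification of parameter sets
  into diverging-behavior classes (strong/weak ERK × YAP); the
  experiment-match predicate (L129Q: PLCβ ≥ Q209L's AND TRIO < Q209L's) with
  Kolmogorov–Smirnov discrimination and ROC/AUC classifier comparison; a sweep
  of PLCβ GAP strength (k_hyd2/k_hyd).
* **Co-mutation enrichment** — the exact probability that two mutation-carrier
  sets of sizes x and y among N patients overlap in exactly k patients,

      P(K = k) = (N−k)! / [(x−k)!(y−k)!(N+k−x−y)!] · C(N,k) / [C(N,x)·C(N,y)]

  (identically the hypergeometric point mass), evaluated in log-gamma space
  and cross-checked against scipy, exact integer arithmetic and Monte Carlo;
  applied to cohort mutation tables with a packaged semaphorin/plexin gene
  list.
* **Synthetic data** — seeded generators for parameter sets, toy networks with
  closed-form steady states, and patient cohorts with planted co-mutation
  structure.

Two parameter presets ship with the package: `initial` (PLCβ GAP rate 770×
basal hydrolysis, no mutant effector bias) and `revised` (GAP rate 20× basal,
4× TRIO-over-PLCβ mutant bias), the second being the
experimentally-consistent update.  See `docs/methods.md` for the model
equations, parameter rationale and limitations.

## Worked example

```python
from gqcycle import load_preset, parse_genotype, solve_steady_state, fold_changes, WT

params = load_preset("revised")
base = solve_steady_state(params, WT)
for g in ("GNAQ:Q209L:het", "CYSLTR2:L129Q:het"):
    r = solve_steady_state(params, parse_genotype(g))
    ft, fp = fold_changes(r, base)
    print(f"{g:18s} active_TRIO={r.active_trio:.4f} active_PLC={r.active_plc:.4f} "
          f"fold_TRIO={ft:.1f} fold_PLC={fp:.1f}")
```

prints

```
GNAQ:Q209L:het     active_TRIO=0.1233 active_PLC=0.1160 fold_TRIO=8.7 fold_PLC=4.2
CYSLTR2:L129Q:het  active_TRIO=0.1067 active_PLC=0.1759 fold_TRIO=7.5 fold_PLC=6.4
```

Both mutants constitutively activate both effector arms (folds ≫ 1 over the
WT baseline), but under the revised parameters the receptor mutant L129Q
produces *more* active PLCβ and *less* active TRIO than Q209L — the
experimentally observed pattern (strong ERK, weak YAP for L129Q).
Concentrations are in units of total Gα; fold changes are scale-invariant.

The `examples/` directory holds one short script per capability
(`simulate_genotypes.py`, `gdi_dose_response.py`, `sensitivity_analysis.py`,
`behavior_classes.py`, `khyd2_sweep.py`, `comutation_enrichment.py`).  A thin
CLI mirrors the library:

```bash
gqcycle simulate --preset revised --genotype GNAQ:Q209L:het
gqcycle enrichment --N 80 --x 3 --y 4 --k 2 --mc-draws 1000000
gqcycle --seed 7 synth cohort --N 80 --x 3 --y 4 --k 2
```

Every CLI run writes a JSON manifest (resolved config, seeds, file digests)
alongside its outputs.

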