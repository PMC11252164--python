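# Methods

## Model

The package models the heterotrimeric G-protein activation cycle downstream of
the GPCR CysLT₂R with mass-action kinetics.  For each Gα pool p ∈ {WT, mutant}
the species are the heterotrimer (GαGDP·Gβγ), free GαGDP, free GαGTP,
nucleotide-free Gα, the effector complexes GαGTP·TRIO and GαGTP·PLCβ, and the
GAP intermediate RGS·GαGTP; Gβγ, TRIO, PLCβ and RGS are shared pools.  The
reactions, per pool (mutant scalings s in parentheses):

1. heterotrimer → GαGTP + Gβγ, at `k_gef · R_active` — the receptor is a
   catalytic GEF, not consumed; `R_active = R_tot·[(1−m)·f_act_wt + m·f_act_mut]`
   with m the mutant receptor fraction.  β-arrestin desensitization is folded
   into the active fractions.
2. GαGTP → GαGDP at `k_hyd` (× r_hyd) — intrinsic hydrolysis.
3. RGS + GαGTP ⇌ RGS·GαGTP (`k_rgs_on`/`k_rgs_off`); RGS·GαGTP → RGS + GαGDP
   at `k_rgs_cat` (× r_gap) — an explicit GAP enzyme cycle.
4. GαGTP + TRIO ⇌ GαGTP·TRIO (`k_on_trio` × r_trio / `k_off_trio`).
5. GαGTP + PLCβ ⇌ GαGTP·PLCβ (`k_on_plc` × r_plc / `k_off_plc`).
6. GαGTP·PLCβ → GαGDP + PLCβ at `k_hyd2` (× r_gap) — PLCβ acting
   unimolecularly as a GAP on its own complex.
7. GαGTP → nucleotide-free Gα (`k_gtp_off`); reload at `k_nt_load` (GTP only;
   cellular GTP excess is folded into the pseudo-first-order constant.  A
   GDP-loading branch would be unidentifiable at steady state, since
   hydrolysis already regenerates GαGDP).
8. GαGDP + Gβγ → heterotrimer (`k_trimer`); both pools compete for one Gβγ
   pool.

Ligand binding kinetics, receptor trafficking, and everything downstream of
the effector complexes are outside the model; active TRIO and active PLCβ are
read as monotone proxies for FAK/YAP and PKC/ERK signaling.  The readouts of
interest are steady-state (dynamic-equilibrium) values; fold changes are
taken against an all-WT baseline solved under identical parameters.

Genotypes map to pool allocations: heterozygous Gα variants put 25% of Gα_tot
in the mutant pool (GNAQ and GNA11 are interchangeable, each half the pool),
homozygous 50%; CYSLTR2 L129Q het sets the mutant receptor fraction to 0.5
with f_act_mut = 1 (the mutation acts by enlarging the active receptor
population); hom (1.0) is supported but experimental — tumor genomics only
documents the het case.  Totals never change with genotype.  Compound
genotypes (a Gα lesion plus a receptor lesion) are not representable; the
mutations are mutually exclusive in patients.

## Units and parameter presets

Concentrations are nondimensionalized to Gα_tot = 1 and time is in seconds;
all downstream comparisons are fold changes or ratios, which are invariant to
the scale choice.  The exact source parameterization is not published at this
granularity, so the presets are constructed from the stated constraints plus
literature-scale round values:

| symbol | value | note |
|---|---|---|
| k_gef | 1.0 conc⁻¹s⁻¹ | receptor-catalyzed exchange |
| k_hyd | 0.01 s⁻¹ | basal Gαq hydrolysis (order 1/min) |
| k_hyd2 | 7.7 (initial) / 0.2 (revised) s⁻¹ | 770× / 20× basal; the defining difference between presets |
| k_rgs_on, k_rgs_off, k_rgs_cat | 10, 1, 2 | RGS GAP cycle, Km = 0.3 |
| k_on_trio / k_off_trio | 10 / 1.0 | effector Kd = 0.1 |
| k_on_plc / k_off_plc | 10 / 0.3 | tighter PLCβ binding (Kd 0.03): Gαq–PLCβ affinity is anomalously high relative to other effectors |
| k_gtp_off, k_nt_load | 0.001, 10 | nucleotide-free branch is a minor flux |
| k_trimer | 10 | re-trimerization fast |
| f_act_wt | 0.05 | a few percent constitutive receptor activity |
| R_tot, Gβγ_tot, RGS_tot, TRIO_tot, PLCβ_tot | 0.2, 1, 0.2, 0.5, 0.5 | relative to Gα_tot |

Variant scalings: Q209L/P r_hyd = 0.001 with r_gap chosen so the mutant's
*absolute* GAP-stimulated rate r_gap·k_hyd2 ≈ 7.7×10⁻⁴ s⁻¹ is the same under
both presets (1×10⁻⁴ initial, 4×10⁻³ revised) — the revision re-estimates the
WT PLCβ GAP strength, not the mutant's broken catalytic machinery.  The rates
are small but nonzero: a GDI can only trap Gα that still reaches the GDP
state.  R183C is partially GAP-sensitive (r_hyd = 0.05, r_gap = 0.2).  The
`effector_bias` (r_trio/r_plc for the Q209 mutants) is 1 in the initial
preset and 4 in the revised one, applied to the association rate with the
dissociation rate held fixed; Q209P shares Q209L's scalings for lack of
separately quantified values.

Two behaviors of the presets worth knowing: f_act_wt = 0.05 keeps basal
exchange fast enough that a GAP-insensitive mutant pool stays GTP-loaded at
steady state (at much smaller basal activity, slow leak through the mutant's
residual hydrolysis outpaces reloading and mutant signaling is understated),
and the tight PLCβ binding makes the initial preset's 770× GAP rate crush the
WT-pool PLCβ complex — which is what produces the near-complete loss of PLCβ
activation for L129Q (whose Gα is all WT) while leaving the
hydrolysis-protected Q209L·PLCβ complexes intact.  One known divergence from
the source description: under the initial preset the modeled L129Q activates
TRIO somewhat *more* than het Q209L (the source reports slightly less); the
orderings that downstream analyses rely on are unaffected.

## Steady-state solver

The full network (22 species, ~30 reactions) is assembled symbolically into a
stoichiometry matrix with vectorized mass-action rate laws and an analytic
Jacobian.  Steady states are found by stiff integration (LSODA) from the
all-heterotrimer initial condition over expanding time windows (10⁴ → 10¹⁰ s;
the slowest mode is the cycling of a hydrolysis-dead mutant pool, ~10⁵ s),
followed by a Newton polish in which one species equation per conserved
protein group is replaced by that group's conservation constraint — pinning
the root to the conservation manifold chosen by the initial condition.
Convergence demands max|dc/dt| ≤ 10⁻¹⁰ × the largest abundance; components
within solver precision below zero are clipped and re-validated against the
residual, anything more negative is an error, and non-convergence raises
rather than returning silently.  A pure-integration route and a
(warm-started) pure-Newton route are exposed separately and agree to 10⁻⁶
relative on the readouts across randomized parameter sets; the solver is also
validated to 10⁻⁸ against a hand-derived one-dimensional reduction of the
RGS-free, PLCβ-free cycle and to machine precision against a fully linear toy
cycle with a closed-form solution.

Multistability handling: solving from all-heterotrimer and all-dissociated
initial conditions and comparing readouts (>10⁻⁴ relative disagreement flags
the set) is available per-set and as `evaluate_batch(check_multistable=True)`.
Batch analyses run with the screen off — it doubles cost, and screening
randomized subsamples of the default ranges found no multistable sets; the
test suite asserts two-IC agreement on such a subsample.

## GDI extension

The inhibitor reversibly binds GDP-bound Gα — both free GαGDP and the
heterotrimer by default (an FR-type ligand stabilizes the GDP state
generically; either target can be disabled to probe mechanism) — with equal
affinity for WT and mutant pools and default Kd = 10⁻⁴·Gα_tot.  The drug pool
is buffered (dose is clamped, not depleted), matching cell-bath conditions;
drug-bound species enter the Gα conservation sums.  Dose-response curves use
25 log-spaced doses over 6 decades centered on the Kd, warm-starting each
solve from the previous dose (continuation); IC50s are log-interpolated at
50% of the drug-free readout, with a failure status when 50% is never
reached, and non-converged doses leave gaps rather than aborting the curve.

## Parameter exploration

Two frozen designs, both log-uniform and centered on the *initial* preset
(the exploration stage belongs to the pre-revision state of knowledge — the
revised values are its conclusion), varying k_hyd2, effector_bias, TRIO_tot,
PLC_tot, RGS_tot and k_gef:

* **classification design** (`default_ranges`): ±1.5 decades on all six; used
  for the behavior-class fractions, the match predicate, KS and ROC analyses
  (Latin-hypercube, n = 2000 in the shipped analyses).
* **sensitivity design** (`sensitivity_ranges`): ±1.5 decades on the kinetic
  unknowns (k_hyd2, effector_bias), ±1.0 on the protein abundances, ±0.75 on
  k_gef; used for the Sobol analysis (Saltelli, n_base = 128 → 1792 runs).
  The narrower widths encode that abundances are better constrained than the
  essentially unmeasured kinetic scalings; a pure throughput knob (k_gef) at
  full width would dominate the variance of the raw output differences and
  mask every mechanistically meaningful ranking.

The Saltelli design (n_base·(2D+2) rows from a scrambled Sobol' sequence:
A, B, ABᵢ, BAᵢ blocks) and the Saltelli-2010 first-order / Jansen total-order
estimators with row-bootstrap CIs are implemented in `gqcycle.sobol` and
validated against the closed-form Ishigami indices (within 0.05 at
n_base = 1024) and a dummy-factor null.  Sensitivity outputs are the raw
differences Δ_TRIO = activeTRIO(Q209L) − activeTRIO(L129Q), Δ_PLC likewise;
base-sample indices with any failed member row are dropped blockwise so the
estimator's pairing is preserved.

Behavior classification: pathway P of L129Q is *weak* iff
(fold_P(L129Q) − 1) < θ·(fold_P(Q209L) − 1), θ = 0.5 by default, with the ERK
arm read from PLCβ and the YAP arm from TRIO; class fractions are reported
with θ ∈ {0.25, 0.5, 0.75} because θ is a modeling choice, not a measured
quantity.  Rows where Q209L itself fails to activate a pathway (fold ≤ 1) are
"undefined" and excluded from fractions.  The match predicate is exactly
activePLC(L129Q) ≥ activePLC(Q209L) AND activeTRIO(L129Q) < activeTRIO(Q209L).
KS scans report Benjamini–Hochberg-adjusted p-values (ranking, not
significance, is the scientific claim).  ROC curves sweep thresholds over the
sampled range in the stated direction (≥ for the bias, < for k_hyd2); the
threshold sweep is jointly monotone in TPR and FPR, so the AUC is the plain
trapezoid along the sweep.

## Co-mutation enrichment

The point probability is evaluated in log-gamma space (stable to N ~ 10⁵) and
is exactly the hypergeometric point mass — an identity the tests verify
exhaustively for all valid quadruples with N ≤ 30 and by exact rational
arithmetic for larger N.  The Monte-Carlo confirmation draws both carrier
sets independently (each as the k-smallest of N iid uniforms) and counts
exact-overlap draws.  The right tail P(K ≥ k) is reported alongside the point
mass, clearly labeled, because "at least k" is the conventional enrichment
question; the point mass remains the primary quantity.  The packaged
semaphorin/plexin list (29 genes, SEMA3–7 + PLXNA/B/C/D families) is a
curated stand-in — the exact membership used in the source analyses is not
enumerated there — and is user-replaceable.

## Synthetic data

`make_cohort` plants an exact (N, x, y, k) co-mutation structure, then
mutates 170 background genes iid at the background rate (default 0.01) and
clamps each patient's coding burden into [5, 19] — the low-burden regime of
uveal melanoma — by adding/removing background (never planted) mutations.
The gene universe defaults to 200 genes so enrichment tests run in
milliseconds.  What it does not emulate: mutation-rate heterogeneity across
patients and genes, subclonality, or any linkage between background genes —
so passing recovery tests validates bookkeeping and the enrichment pipeline,
not robustness to real cohort artifacts.  Parameter-set generation delegates
to the exploration samplers; every generator is seed-deterministic and
returns a manifest (spec + seed + package version).

## Numerical choices and limitations

* Scaled-down problem sizes in the shipped analyses: classification n = 2000,
  Sobol n_base = 128, MC enrichment 10⁶ draws — sizes at which every ranking
  and fraction reported here is stable across seeds on a single CPU.
* IC50s depend on the dose grid only through log-interpolation error (≤ one
  grid step); non-monotone segments at the crossing use the first crossing
  with a warning.
* The model has a single physical steady state across all tested parameter
  ranges, but this is verified empirically, not proven; the two-IC screen is
  the guard.
* Behavior-class fractions depend on the sampled ranges, which stand in for
  unpublished supplementary values; they are faithful to the stated
  constraints but are the least pinned-down quantities in the package.
* Q209P is biochemically distinct from Q209L in reality (different effector
  and GAP affinities); the presets treat them identically for lack of
  separate values.
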