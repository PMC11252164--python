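"""Synthetic inputs with known ground truth.

Three generators stand in for the study's external inputs so the whole
pipeline runs offline and is testable against planted truth:

* :func:`make_cohort` — patient-by-gene mutation tables with an exactly
  planted (N, x, y, k) co-mutation structure and a low, uveal-melanoma-like
  per-patient coding-mutation burden;
* :func:`make_parameter_sets` — seeded parameter-set draws (delegates to the
  exploration sampler, adds a manifest);
* :func:`make_toy_fixture` — a reduced, fully linear single-pool G-protein
  cycle whose steady state is attached in closed form (the oracle used to
  validate the full solver), plus :func:`reduced_cycle_steady_state`, a
  hand-derived one-dimensional reduction of the full model without RGS,
  PLC-beta and the nucleotide-free branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import __version__
from .enrichment import CohortMutationTable, EnrichmentInputs
from .explore import ParameterRangeSpec, ParameterSetBatch, sample_parameter_sets
from .parameters import ModelParameters

__all__ = [
    "SyntheticCohortSpec",
    "make_cohort",
    "make_parameter_sets",
    "ToyNetworkFixture",
    "make_toy_fixture",
    "reduced_cycle_steady_state",
]

INDEX_GENE = "CYSLTR2"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Planted cohort structure: the (N, x, y, k) quadruple, a background
    mutation rate, and the per-patient coding-burden band (UM tumors carry
    on the order of 5-19 coding mutations)."""

    N: int = 80
    x: int = 3
    y: int = 4
    k: int = 2
    background_rate: float = 0.01
    burden_band: tuple[int, int] = (5, 19)
    n_background_genes: int = 170
    seed: int = 0

    def __post_init__(self):
        EnrichmentInputs(self.N, self.x, self.y, self.k)  # validates
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        lo, hi = self.burden_band
        if not 0 <= lo <= hi:
            raise ValueError("burden band must satisfy 0 <= lo <= hi")


def make_cohort(spec: SyntheticCohortSpec,
                family_genes: list[str] | None = None
                ) -> tuple[CohortMutationTable, dict]:
    """Generate a cohort table with exactly the planted (N, x, y, k).

    Index carriers get the index gene; family carriers get one random family
    gene; the overlap patients get both.  All other genes mutate i.i.d. at
    the background rate, after which per-patient background mutations are
    added or removed at random so every patient's total coding burden falls
    inside the band (planted mutations are never removed).

    Returns the table and a reproducibility manifest.
    """
    if family_genes is None:
        from .enrichment import load_gene_family
        family_genes = load_gene_family()
    rng = np.random.default_rng(spec.seed)
    bg_genes = [f"GENE{i + 1:03d}" for i in range(spec.n_background_genes)]
    genes = [INDEX_GENE] + list(family_genes) + bg_genes
    flags = pd.DataFrame(
        False, columns=pd.Index(genes, name="gene"),
        index=pd.Index([f"P{i + 1:04d}" for i in range(spec.N)],
                       name="patient_id"),
    )

    order = rng.permutation(spec.N)
    both = order[:spec.k]
    index_only = order[spec.k:spec.x]
    family_only = order[spec.x:spec.x + spec.y - spec.k]
    for i in np.concatenate([both, index_only]).astype(int):
        flags.iloc[i, flags.columns.get_loc(INDEX_GENE)] = True
    for i in np.concatenate([both, family_only]).astype(int):
        gene = family_genes[rng.integers(len(family_genes))]
        flags.iloc[i, flags.columns.get_loc(gene)] = True

    # i.i.d. background, then clamp each patient's burden into the band
    bg_cols = [flags.columns.get_loc(g) for g in bg_genes]
    bg_draw = rng.random((spec.N, len(bg_genes))) < spec.background_rate
    flags.iloc[:, bg_cols] = bg_draw
    lo, hi = spec.burden_band
    for i in range(spec.N):
        row = flags.iloc[i]
        total = int(row.sum())
        if total < lo:
            off = [c for c in bg_cols if not flags.iloc[i, c]]
            add = rng.choice(len(off), size=lo - total, replace=False)
            for j in add:
                flags.iloc[i, off[j]] = True
        elif total > hi:
            on = [c for c in bg_cols if flags.iloc[i, c]]
            drop = rng.choice(len(on), size=total - hi, replace=False)
            for j in drop:
                flags.iloc[i, on[j]] = False

    manifest = {
        "generator": "make_cohort",
        "version": __version__,
        "seed": spec.seed,
        "spec": {"N": spec.N, "x": spec.x, "y": spec.y, "k": spec.k,
                 "background_rate": spec.background_rate,
                 "burden_band": list(spec.burden_band),
                 "n_background_genes": spec.n_background_genes},
        "n_family_genes": len(family_genes),
    }
    return CohortMutationTable(flags), manifest


def make_parameter_sets(spec: ParameterRangeSpec, n: int, seed: int,
                        scheme: str = "lhs") -> tuple[ParameterSetBatch, dict]:
    """Seeded parameter-set draws plus a manifest (sampler metadata)."""
    if scheme == "saltelli":
        batch = sample_parameter_sets(spec, scheme, n_base=n, seed=seed)
    else:
        batch = sample_parameter_sets(spec, scheme, n=n, seed=seed)
    manifest = {"generator": "make_parameter_sets", "version": __version__,
                **batch.manifest()}
    return batch, manifest


# -- toy fixture ------------------------------------------------------------

@dataclass
class ToyNetworkFixture:
    """Fully linear single-pool activation cycle with buffered partners.

    Species: heterotrimer HT, free GaGTP g, free GaGDP d, effector complex C.
    Reactions (all pseudo-first-order; G-beta-gamma and the effector are
    buffered, RGS / PLC-beta GAP / nucleotide-free branches absent):

        HT -> g        a        (receptor-driven exchange)
        g  -> d        k_hyd    (intrinsic hydrolysis)
        d  -> HT       k_re     (re-trimerization, buffered Gbg folded in)
        g <-> C        k_b / k_off   (effector binding, buffered effector)

    The closed-form steady state follows from the flux balance a*HT =
    k_hyd*g = k_re*d with the side branch at binding equilibrium
    C = k_b*g/k_off, under HT + g + d + C = Ga_tot.
    """

    a: float = 0.05
    k_hyd: float = 0.01
    k_re: float = 5.0
    k_b: float = 2.0
    k_off: float = 1.0
    ga_tot: float = 1.0
    species: tuple[str, ...] = ("HT", "GaGTP", "GaGDP", "complex")

    def rhs(self, c: np.ndarray) -> np.ndarray:
        ht, g, d, cx = c
        return np.array([
            self.k_re * d - self.a * ht,
            self.a * ht - self.k_hyd * g - self.k_b * g + self.k_off * cx,
            self.k_hyd * g - self.k_re * d,
            self.k_b * g - self.k_off * cx,
        ])

    def steady_state(self) -> np.ndarray:
        ht = self.ga_tot / (1.0 + self.a / self.k_hyd + self.a / self.k_re
                            + self.a * self.k_b / (self.k_hyd * self.k_off))
        g = self.a * ht / self.k_hyd
        d = self.a * ht / self.k_re
        cx = self.k_b * g / self.k_off
        return np.array([ht, g, d, cx])


def make_toy_fixture(**kwargs) -> ToyNetworkFixture:
    """Build the linear toy cycle (rates overridable by keyword)."""
    fx = ToyNetworkFixture(**kwargs)
    for name in ("a", "k_hyd", "k_re", "k_b", "k_off", "ga_tot"):
        if getattr(fx, name) <= 0:
            raise ValueError(f"toy fixture rate {name} must be positive")
    return fx


def reduced_cycle_steady_state(params: ModelParameters,
                               f_act: float | None = None) -> dict[str, float]:
    """Hand-derived steady state of the full model restricted to the
    single-pool cycle (requires RGS_tot = PLC_tot = 0 and k_gtp_off = 0).

    At steady state the cycle flux phi = k_gef*R_act*HT passes through
    hydrolysis (phi = k_hyd * g) and re-trimerization
    (phi = k_trimer * d * (Gbg_tot - HT)), while the TRIO branch is a pure
    binding equilibrium, C = K*g*TRIO_tot/(1 + K*g) with K =
    k_on_trio/k_off_trio.  Substituting into G-alpha conservation leaves one
    monotone scalar equation in HT, bracketed and solved to machine accuracy.
    """
    if params.RGS_tot != 0 or params.PLC_tot != 0 or params.k_gtp_off != 0:
        raise ValueError("reduction valid only for RGS_tot = PLC_tot = 0 "
                         "and k_gtp_off = 0")
    a = params.k_gef * params.R_tot * (params.f_act_wt if f_act is None else f_act)
    K = params.k_on_trio / params.k_off_trio
    ga, gbg, trio = params.Ga_tot, params.Gbg_tot, params.TRIO_tot

    def excess(ht):
        g = a * ht / params.k_hyd
        d = a * ht / (params.k_trimer * (gbg - ht))
        c = K * g * trio / (1.0 + K * g)
        return ht + g + d + c - ga

    hi = min(ga, gbg) * (1 - 1e-12)
    ht = brentq(excess, 0.0, hi, xtol=1e-16, rtol=1e-15)
    g = a * ht / params.k_hyd
    return {
        "heterotrimer": ht,
        "GaGTP": g,
        "GaGDP": a * ht / (params.k_trimer * (gbg - ht)),
        "GaGTP_TRIO": K * g * trio / (1.0 + K * g),
    }
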