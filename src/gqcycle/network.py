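"""Mass-action reaction network of the CysLT2R -> Gaq/11 -> {TRIO, PLC-beta} cycle.

The network carries two parallel G-alpha pools (WT and mutant) through an
identical reaction scheme; mutant reactions are scaled by the variant's
``r_*`` factors.  The receptor is catalytic and not consumed: its active
concentration is folded into the exchange rate constant.  A guanine-nucleotide
dissociation inhibitor (GDI) can be attached to the network; the drug pool is
treated as buffered (clamped dose), so drug binding appears as
pseudo-first-order capture of GDP-bound G-alpha species.

Reactions, per G-alpha pool p (scalings s_* = 1 for WT):

1.  heterotrimer_p -> GaGTP_p + Gbg           k_gef * R_active   (receptor GEF)
2.  GaGTP_p -> GaGDP_p                        k_hyd * s_hyd      (intrinsic)
3.  RGS + GaGTP_p <-> RGS_GaGTP_p             k_rgs_on / k_rgs_off
    RGS_GaGTP_p -> RGS + GaGDP_p              k_rgs_cat * s_gap  (RGS GAP)
4.  GaGTP_p + TRIO <-> GaGTP_TRIO_p           k_on_trio * s_trio / k_off_trio
5.  GaGTP_p + PLC <-> GaGTP_PLC_p             k_on_plc * s_plc / k_off_plc
6.  GaGTP_PLC_p -> GaGDP_p + PLC              k_hyd2 * s_gap     (PLC-beta GAP)
7.  GaGTP_p -> GaEmpty_p                      k_gtp_off
    GaEmpty_p -> GaGTP_p                      k_nt_load
8.  GaGDP_p + Gbg -> heterotrimer_p           k_trimer
9.  GaGDP_p <-> GDI.GaGDP_p                   k_on_drug * dose / k_off_drug
    heterotrimer_p <-> GDI.heterotrimer_p     k_on_drug * dose / k_off_drug
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeSpec, PoolAllocation, allocate
from .parameters import ModelParameters

__all__ = ["Reaction", "ReactionNetwork", "build_network", "SPECIES", "N_SPECIES"]

_POOL_SPECIES = (
    "heterotrimer",
    "GaGDP",
    "GaGTP",
    "GaEmpty",
    "GaGTP_TRIO",
    "GaGTP_PLC",
    "RGS_GaGTP",
    "GDI_GaGDP",
    "GDI_heterotrimer",
)
_N_POOL = len(_POOL_SPECIES)

#: Full ordered species list (WT pool, mutant pool, shared free proteins).
SPECIES = tuple(
    [f"{s}_wt" for s in _POOL_SPECIES]
    + [f"{s}_mut" for s in _POOL_SPECIES]
    + ["Gbg", "TRIO", "PLC", "RGS"]
)
N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}
_GBG, _TRIO, _PLC, _RGS = (_IDX[s] for s in ("Gbg", "TRIO", "PLC", "RGS"))


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction: flux = k * prod(reactant concs)."""

    name: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    k: float

    def flux(self, c: np.ndarray) -> float:
        f = self.k
        for i in self.reactants:
            f *= c[i]
        return f


@dataclass
class ReactionNetwork:
    """Stoichiometry and rate laws of the full (two-pool) G-protein cycle."""

    params: ModelParameters
    genotype: GenotypeSpec
    alloc: PoolAllocation
    reactions: list[Reaction]
    r_active: float
    dose: float = 0.0
    species: tuple[str, ...] = SPECIES

    # derived arrays, built in __post_init__
    S: np.ndarray = field(init=False, repr=False)
    _k: np.ndarray = field(init=False, repr=False)
    _r1: np.ndarray = field(init=False, repr=False)
    _r2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        n_rx = len(self.reactions)
        S = np.zeros((N_SPECIES, n_rx))
        k = np.empty(n_rx)
        r1 = np.empty(n_rx, dtype=np.intp)
        r2 = np.full(n_rx, -1, dtype=np.intp)
        for j, rx in enumerate(self.reactions):
            if not 1 <= len(rx.reactants) <= 2:
                raise ValueError(f"reaction {rx.name}: only uni/bimolecular supported")
            for i in rx.reactants:
                S[i, j] -= 1
            for i in rx.products:
                S[i, j] += 1
            k[j] = rx.k
            r1[j] = rx.reactants[0]
            if len(rx.reactants) == 2:
                r2[j] = rx.reactants[1]
        self.S = S
        self._k = k
        self._r1 = r1
        self._r2 = r2

    # -- dynamics -----------------------------------------------------------

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if c.shape != (N_SPECIES,):
            raise ValueError(
                f"state has {c.shape} entries, network has {N_SPECIES} species"
            )
        f = self._k * c[self._r1]
        bi = self._r2 >= 0
        f[bi] *= c[self._r2[bi]]
        return f

    def rhs(self, c: np.ndarray) -> np.ndarray:
        """Mass-action time derivative dc/dt = S @ flux(c)."""
        return self.S @ self.fluxes(c)

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        n_rx = len(self._k)
        D = np.zeros((n_rx, N_SPECIES))
        rows = np.arange(n_rx)
        bi = self._r2 >= 0
        # d flux / d c_r1
        other = np.ones(n_rx)
        other[bi] = c[self._r2[bi]]
        D[rows, self._r1] += self._k * other
        # d flux / d c_r2 (bimolecular only)
        D[rows[bi], self._r2[bi]] += self._k[bi] * c[self._r1[bi]]
        return self.S @ D

    # -- conservation -------------------------------------------------------

    def conservation_groups(self) -> dict[str, tuple[np.ndarray, float]]:
        """Map group name -> (member species indices, conserved total)."""
        p = self.params
        mf = self.alloc.galpha_mut_frac
        wt = np.arange(_N_POOL)
        mut = wt + _N_POOL
        ht = [_IDX["heterotrimer_wt"], _IDX["heterotrimer_mut"],
              _IDX["GDI_heterotrimer_wt"], _IDX["GDI_heterotrimer_mut"]]
        return {
            "Ga_wt": (wt, p.Ga_tot * (1.0 - mf)),
            "Ga_mut": (mut, p.Ga_tot * mf),
            "Gbg": (np.array([_GBG] + ht), p.Gbg_tot),
            "TRIO": (np.array([_TRIO, _IDX["GaGTP_TRIO_wt"], _IDX["GaGTP_TRIO_mut"]]),
                     p.TRIO_tot),
            "PLC": (np.array([_PLC, _IDX["GaGTP_PLC_wt"], _IDX["GaGTP_PLC_mut"]]),
                    p.PLC_tot),
            "RGS": (np.array([_RGS, _IDX["RGS_GaGTP_wt"], _IDX["RGS_GaGTP_mut"]]),
                    p.RGS_tot),
        }

    def conservation_error(self, c: np.ndarray) -> float:
        """Largest relative violation of the protein conservation laws."""
        worst = 0.0
        scale = max(self.params.Ga_tot, self.params.Gbg_tot, self.params.TRIO_tot,
                    self.params.PLC_tot, self.params.RGS_tot)
        for idx, total in self.conservation_groups().values():
            err = abs(float(np.sum(np.asarray(c)[idx])) - total)
            worst = max(worst, err / max(total, 1e-12 * scale))
        return worst

    # -- initial conditions -------------------------------------------------

    def initial_state(self, kind: str = "heterotrimer") -> np.ndarray:
        """Build an initial state: ``heterotrimer`` puts as much G-alpha as
        G-beta-gamma allows into heterotrimers (remainder as free GaGDP);
        ``dissociated`` starts from free GaGDP and free G-beta-gamma."""
        p = self.params
        mf = self.alloc.galpha_mut_frac
        c = np.zeros(N_SPECIES)
        totals = {"wt": p.Ga_tot * (1 - mf), "mut": p.Ga_tot * mf}
        if kind == "heterotrimer":
            ht_total = min(p.Ga_tot, p.Gbg_tot)
            for pool, tot in totals.items():
                share = ht_total * (tot / p.Ga_tot) if p.Ga_tot > 0 else 0.0
                c[_IDX[f"heterotrimer_{pool}"]] = share
                c[_IDX[f"GaGDP_{pool}"]] = tot - share
            c[_GBG] = p.Gbg_tot - ht_total
        elif kind == "dissociated":
            for pool, tot in totals.items():
                c[_IDX[f"GaGDP_{pool}"]] = tot
            c[_GBG] = p.Gbg_tot
        else:
            raise ValueError(f"unknown initial-state kind {kind!r}")
        c[_TRIO] = p.TRIO_tot
        c[_PLC] = p.PLC_tot
        c[_RGS] = p.RGS_tot
        return c

    def species_dict(self, c: np.ndarray) -> dict[str, float]:
        return {name: float(c[i]) for name, i in _IDX.items()}

    @property
    def active_trio_idx(self) -> tuple[int, int]:
        return (_IDX["GaGTP_TRIO_wt"], _IDX["GaGTP_TRIO_mut"])

    @property
    def active_plc_idx(self) -> tuple[int, int]:
        return (_IDX["GaGTP_PLC_wt"], _IDX["GaGTP_PLC_mut"])


def build_network(
    params: ModelParameters,
    genotype: GenotypeSpec,
    *,
    drug=None,
    dose: float = 0.0,
    stimulated: bool = False,
) -> ReactionNetwork:
    """Assemble the full reaction list for a genotype.

    ``drug`` is a :class:`gqcycle.gdi.DrugParameters` (or None) and ``dose`` the
    clamped drug concentration.  ``stimulated`` replaces the basal WT active
    receptor fraction with ``params.stimulated_f_act`` (ligand-driven
    activation).
    """
    params.validate()
    if dose < 0:
        raise ValueError(f"drug dose must be nonnegative, got {dose}")
    al = allocate(genotype, params)
    f_wt = params.stimulated_f_act if stimulated else params.f_act_wt
    rmf = al.receptor_mut_frac
    r_active = params.R_tot * ((1.0 - rmf) * f_wt + rmf * al.scalings.f_act_mut)

    p = params
    reactions: list[Reaction] = []

    def add(name, reactants, products, k):
        if k < 0:
            raise ValueError(f"negative rate for reaction {name}: {k}")
        reactions.append(
            Reaction(name, tuple(_IDX[r] for r in reactants),
                     tuple(_IDX[q] for q in products), k)
        )

    for pool in ("wt", "mut"):
        is_mut = pool == "mut"
        # G-alpha variant scalings apply to the mutant G-alpha pool only; for a
        # receptor genotype the (single) G-alpha pool is fully WT.
        s = al.scalings if (is_mut and al.galpha_mut_frac > 0) else None
        s_hyd = s.r_hyd if s else 1.0
        s_gap = s.r_gap if s else 1.0
        s_trio = s.r_trio if s else 1.0
        s_plc = s.r_plc if s else 1.0

        ht, gdp, gtp = f"heterotrimer_{pool}", f"GaGDP_{pool}", f"GaGTP_{pool}"
        empty, ctrio, cplc = f"GaEmpty_{pool}", f"GaGTP_TRIO_{pool}", f"GaGTP_PLC_{pool}"
        rgs_c = f"RGS_GaGTP_{pool}"

        add(f"exchange_{pool}", [ht], [gtp, "Gbg"], p.k_gef * r_active)
        add(f"hydrolysis_{pool}", [gtp], [gdp], p.k_hyd * s_hyd)
        add(f"rgs_bind_{pool}", ["RGS", gtp], [rgs_c], p.k_rgs_on)
        add(f"rgs_release_{pool}", [rgs_c], ["RGS", gtp], p.k_rgs_off)
        add(f"rgs_cat_{pool}", [rgs_c], ["RGS", gdp], p.k_rgs_cat * s_gap)
        add(f"trio_bind_{pool}", [gtp, "TRIO"], [ctrio], p.k_on_trio * s_trio)
        add(f"trio_release_{pool}", [ctrio], [gtp, "TRIO"], p.k_off_trio)
        add(f"plc_bind_{pool}", [gtp, "PLC"], [cplc], p.k_on_plc * s_plc)
        add(f"plc_release_{pool}", [cplc], [gtp, "PLC"], p.k_off_plc)
        add(f"plc_gap_{pool}", [cplc], [gdp, "PLC"], p.k_hyd2 * s_gap)
        add(f"gtp_off_{pool}", [gtp], [empty], p.k_gtp_off)
        add(f"nt_load_{pool}", [empty], [gtp], p.k_nt_load)
        add(f"trimer_{pool}", [gdp, "Gbg"], [ht], p.k_trimer)

        if drug is not None:
            kon = drug.k_on_drug * dose
            if "gdp" in drug.target_states:
                add(f"drug_bind_gdp_{pool}", [gdp], [f"GDI_GaGDP_{pool}"], kon)
                add(f"drug_release_gdp_{pool}", [f"GDI_GaGDP_{pool}"], [gdp],
                    drug.k_off_drug)
            if "heterotrimer" in drug.target_states:
                add(f"drug_bind_ht_{pool}", [ht], [f"GDI_heterotrimer_{pool}"], kon)
                add(f"drug_release_ht_{pool}", [f"GDI_heterotrimer_{pool}"], [ht],
                    drug.k_off_drug)

    return ReactionNetwork(
        params=params, genotype=genotype, alloc=al,
        reactions=reactions, r_active=r_active, dose=dose,
    )
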