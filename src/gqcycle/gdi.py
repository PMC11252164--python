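"""Guanine-nucleotide dissociation inhibitor (GDI) extension and dose response.

Models an FR900359 / YM-254890-type inhibitor that reversibly binds and
sequesters GDP-bound G-alpha, either free or within the heterotrimer
(configurable).  The drug pool is buffered (cell-bath conditions), so dose is
a clamped parameter rather than a conserved species; drug-bound G-alpha
species still enter the G-alpha conservation sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeSpec
from .parameters import ModelParameters
from .steady import SteadyStateError, solve_network, solve_steady_state
from .network import build_network

__all__ = ["DrugParameters", "DoseResponseCurve", "dose_response", "estimate_ic50",
           "default_dose_grid"]

logger = logging.getLogger(__name__)

_VALID_TARGETS = frozenset({"gdp", "heterotrimer"})


@dataclass(frozen=True)
class DrugParameters:
    """Reversible GDI binding kinetics.

    ``target_states`` selects which GDP-bound forms the drug can sequester:
    ``"gdp"`` (free GaGDP) and/or ``"heterotrimer"``.  By default the drug
    binds both with equal affinity for WT and mutant pools.
    """

    k_on_drug: float = 100.0
    k_off_drug: float = 0.01
    target_states: frozenset[str] = frozenset({"gdp", "heterotrimer"})
    equal_affinity: bool = True

    def __post_init__(self):
        if self.k_on_drug < 0 or self.k_off_drug < 0:
            raise ValueError("drug rate constants must be nonnegative")
        bad = set(self.target_states) - _VALID_TARGETS
        if bad:
            raise ValueError(f"unknown drug target states {sorted(bad)}")
        if not self.target_states:
            raise ValueError("drug must bind at least one target state")

    @property
    def kd(self) -> float:
        return self.k_off_drug / self.k_on_drug


def default_dose_grid(drug: DrugParameters, decades: float = 6.0,
                      n_points: int = 25) -> np.ndarray:
    """Log-spaced dose grid centered on the drug's dissociation constant."""
    half = decades / 2.0
    return np.logspace(np.log10(drug.kd) - half, np.log10(drug.kd) + half, n_points)


@dataclass
class DoseResponseCurve:
    """Steady-state readouts over an ascending dose grid.

    Non-converged doses carry NaN readouts (the curve is returned with gaps
    rather than failing wholesale).
    """

    genotype: GenotypeSpec
    drug: DrugParameters
    doses: np.ndarray
    active_trio: np.ndarray
    active_plc: np.ndarray
    baseline_trio: float
    baseline_plc: float
    failed_doses: list[float] = field(default_factory=list)

    ic50_trio: float | None = None
    ic50_plc: float | None = None

    def inhibition(self, readout: str = "trio") -> np.ndarray:
        vals = self.active_trio if readout == "trio" else self.active_plc
        base = self.baseline_trio if readout == "trio" else self.baseline_plc
        return 1.0 - vals / base


def dose_response(
    params: ModelParameters,
    genotype: GenotypeSpec,
    drug: DrugParameters,
    doses: np.ndarray | None = None,
    *,
    decades: float = 6.0,
    n_points: int = 25,
    stimulated: bool = False,
) -> DoseResponseCurve:
    """Solve the drugged network to steady state at every dose.

    Doses must be strictly increasing; each solve warm-starts from the previous
    dose's steady state (a continuation that is both faster and more robust
    than cold starts).  IC50s for both readouts are attached when the curve
    crosses 50% inhibition.
    """
    if doses is None:
        doses = default_dose_grid(drug, decades, n_points)
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or len(doses) < 2 or np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be a strictly increasing 1-D array")

    baseline = solve_steady_state(params, genotype, stimulated=stimulated)
    a_trio = np.full(len(doses), np.nan)
    a_plc = np.full(len(doses), np.nan)
    failed: list[float] = []
    c_prev = baseline.state
    for i, dose in enumerate(doses):
        net = build_network(params, genotype, drug=drug, dose=dose,
                            stimulated=stimulated)
        try:
            res = solve_network(net, c0=c_prev)
        except SteadyStateError:
            try:
                res = solve_network(net)  # cold restart
            except SteadyStateError:
                failed.append(float(dose))
                logger.warning("dose %.3g did not converge; leaving a gap", dose)
                continue
        a_trio[i] = res.active_trio
        a_plc[i] = res.active_plc
        c_prev = res.state

    curve = DoseResponseCurve(
        genotype=genotype, drug=drug, doses=doses,
        active_trio=a_trio, active_plc=a_plc,
        baseline_trio=baseline.active_trio, baseline_plc=baseline.active_plc,
        failed_doses=failed,
    )
    curve.ic50_trio = estimate_ic50(curve, "trio")
    curve.ic50_plc = estimate_ic50(curve, "plc")
    return curve


def estimate_ic50(curve: DoseResponseCurve, readout: str = "trio") -> float | None:
    """Dose halving the drug-free readout, by log-linear interpolation.

    Returns None when the curve never reaches 50% inhibition.  If the curve
    is locally non-monotone at the crossing, the first crossing is used and a
    warning logged.
    """
    vals = curve.active_trio if readout == "trio" else curve.active_plc
    base = curve.baseline_trio if readout == "trio" else curve.baseline_plc
    if base <= 0:
        return None
    ok = ~np.isnan(vals)
    doses, vals = curve.doses[ok], vals[ok]
    if len(doses) < 2:
        return None
    half = 0.5 * base
    below = vals <= half
    if not np.any(below):
        return None
    j = int(np.argmax(below))  # first grid point at/below half-max
    if j == 0:
        return float(doses[0])
    if np.any(vals[j:] > half):
        logger.warning("non-monotone dose response near the IC50 crossing; "
                       "using the first crossing")
    d0, d1 = np.log10(doses[j - 1]), np.log10(doses[j])
    v0, v1 = vals[j - 1], vals[j]
    frac = (v0 - half) / (v0 - v1)
    return float(10.0 ** (d0 + frac * (d1 - d0)))
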