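"""Dynamic-equilibrium (steady-state) solution of the G-protein cycle.

The steady state is found by stiff long-time integration (LSODA) followed by a
Newton polish (``scipy.optimize.root``) on a modified system in which one
species equation per conserved protein group is replaced by that group's
conservation constraint — this pins the root to the conservation manifold
selected by the initial condition.  Integration alone and root-finding alone
are also exposed so the two routes can be cross-checked.

The slowest timescale in the network is the cycling of a nearly
hydrolysis-dead mutant G-alpha (rates ~1e-5/s), so the integrator runs in
expanding time windows up to 1e10 s before declaring non-convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import ODEintWarning, odeint
from scipy.optimize import root

from .genotype import GenotypeSpec, WT
from .network import ReactionNetwork, build_network
from .parameters import ModelParameters

__all__ = [
    "SteadyStateResult",
    "SteadyStateError",
    "solve_steady_state",
    "solve_network",
    "fold_changes",
    "check_multistability",
]

# designated rows whose ODEs are replaced by conservation constraints
_CONS_ROWS = {
    "Ga_wt": "heterotrimer_wt",
    "Ga_mut": "heterotrimer_mut",
    "Gbg": "Gbg",
    "TRIO": "TRIO",
    "PLC": "PLC",
    "RGS": "RGS",
}


class SteadyStateError(RuntimeError):
    """Raised when the solver cannot reach a converged, nonnegative steady state."""


@dataclass
class SteadyStateResult:
    """Converged state plus the model's two readouts.

    ``active_trio`` and ``active_plc`` are the summed WT+mutant
    GaGTP-effector complex concentrations; ``fold_trio``/``fold_plc`` are
    filled by :func:`fold_changes` against an all-WT baseline.
    """

    network: ReactionNetwork
    state: np.ndarray
    residual_norm: float
    method: str
    active_trio: float = 0.0
    active_plc: float = 0.0
    fold_trio: float | None = None
    fold_plc: float | None = None

    def __post_init__(self):
        it, ip = self.network.active_trio_idx, self.network.active_plc_idx
        self.active_trio = float(self.state[it[0]] + self.state[it[1]])
        self.active_plc = float(self.state[ip[0]] + self.state[ip[1]])

    @property
    def species(self) -> dict[str, float]:
        return self.network.species_dict(self.state)

    def conservation_error(self) -> float:
        return self.network.conservation_error(self.state)


def _atol(net: ReactionNetwork, atol_scale: float) -> float:
    p = net.params
    biggest = max(p.Ga_tot, p.Gbg_tot, p.RGS_tot, p.TRIO_tot, p.PLC_tot, p.R_tot)
    return atol_scale * biggest


def _residual(net: ReactionNetwork, c: np.ndarray) -> float:
    return float(np.max(np.abs(net.rhs(c))))


def _integrate(net: ReactionNetwork, c0: np.ndarray, tol: float,
               t_windows=(1e4, 1e6, 1e8, 1e10)) -> np.ndarray:
    c = c0
    f = lambda y, t: net.rhs(y)
    jac = lambda y, t: net.jacobian(y)
    t_prev = 0.0
    for t_end in t_windows:
        span = t_end - t_prev
        ts = np.array([0.0, span])
        with warnings.catch_warnings():
            # mxstep exhaustion in an early window is handled by the residual
            # check and the following (longer) windows
            warnings.simplefilter("ignore", ODEintWarning)
            out = odeint(f, c, ts, Dfun=jac, rtol=1e-10, atol=tol * 1e-4,
                         mxstep=20000, printmessg=False)
        c = out[-1]
        t_prev = t_end
        if _residual(net, c) < tol:
            break
    return c


def _polish(net: ReactionNetwork, c0: np.ndarray) -> np.ndarray | None:
    groups = net.conservation_groups()
    rows = np.array([_CONS_ROWS[g] for g in groups], dtype=object)
    row_idx = np.array([net.species.index(r) for r in rows])
    members = [idx for idx, _ in groups.values()]
    totals = np.array([tot for _, tot in groups.values()])

    def fun(c):
        r = net.rhs(c)
        J = net.jacobian(c)
        for i, (ri, idx) in enumerate(zip(row_idx, members)):
            r[ri] = np.sum(c[idx]) - totals[i]
            J[ri, :] = 0.0
            J[ri, idx] = 1.0
        return r, J

    sol = root(fun, c0, jac=True, method="hybr")
    # hybr's own success flag is unreliable at tight tolerances (it reports
    # "xtol too small" when started at the solution); the caller judges the
    # candidate by residual, conservation and nonnegativity instead
    if not np.all(np.isfinite(sol.x)):
        return None
    return sol.x


def solve_network(
    net: ReactionNetwork,
    *,
    method: str = "hybrid",
    init: str = "heterotrimer",
    c0: np.ndarray | None = None,
    atol_scale: float = 1e-10,
) -> SteadyStateResult:
    """Solve an already-built network to steady state.

    ``method``: ``hybrid`` (integrate, then Newton polish; default),
    ``integrate`` (stiff integration only), or ``root`` (Newton from the
    initial condition, refined from a short integration if the cold start
    fails).
    """
    tol = _atol(net, atol_scale)
    # Newton may land a hair below zero on species whose true value is ~0;
    # such states are accepted if clipping them to zero leaves the residual
    # within tolerance, while larger negatives are a genuine failure
    neg_tol = 1e-8 * _atol(net, 1.0)
    if c0 is None:
        c0 = net.initial_state(init)

    c = None
    if method in ("hybrid", "integrate"):
        c = _integrate(net, c0, tol)
        if method == "hybrid":
            polished = _polish(net, c)
            if (polished is not None and np.min(polished) > -neg_tol
                    and _residual(net, polished) <= max(_residual(net, c), tol)):
                c = polished
    elif method == "root":
        # Newton does the converging, but from a short warm-up integration:
        # cold starts far from the physical branch can land on spurious
        # boundary roots of the mass-action system
        warm = _integrate(net, c0, tol, t_windows=(1e2, 1e4))
        c = _polish(net, warm)
        if c is None or np.min(c) < -neg_tol or _residual(net, c) > tol:
            warm = _integrate(net, c0, tol, t_windows=(1e6, 1e8))
            c = _polish(net, warm)
    else:
        raise ValueError(f"unknown method {method!r}")

    if c is None:
        raise SteadyStateError(f"steady-state solve failed (method={method})")
    if np.min(c) < -neg_tol:
        raise SteadyStateError(
            f"negative concentration at steady state: min={np.min(c):.3e}"
        )
    c = np.clip(c, 0.0, None)
    res = _residual(net, c)
    if res > tol:
        raise SteadyStateError(
            f"not converged: residual {res:.3e} > tolerance {tol:.3e} "
            f"(method={method})"
        )
    return SteadyStateResult(network=net, state=c, residual_norm=res, method=method)


def solve_steady_state(
    params: ModelParameters,
    genotype: GenotypeSpec = WT,
    *,
    method: str = "hybrid",
    init: str = "heterotrimer",
    drug=None,
    dose: float = 0.0,
    stimulated: bool = False,
    atol_scale: float = 1e-10,
) -> SteadyStateResult:
    """Build the network for ``genotype`` and solve it to steady state."""
    net = build_network(params, genotype, drug=drug, dose=dose, stimulated=stimulated)
    return solve_network(net, method=method, init=init, atol_scale=atol_scale)


def fold_changes(result: SteadyStateResult,
                 baseline: SteadyStateResult) -> tuple[float, float]:
    """Readouts divided by the all-WT baseline readouts (same parameters).

    Also stores the fold changes on ``result``.
    """
    if baseline.active_trio <= 0 or baseline.active_plc <= 0:
        raise ValueError(
            "baseline readouts must be positive to define fold changes "
            f"(got active_trio={baseline.active_trio}, "
            f"active_plc={baseline.active_plc})"
        )
    result.fold_trio = result.active_trio / baseline.active_trio
    result.fold_plc = result.active_plc / baseline.active_plc
    return result.fold_trio, result.fold_plc


def check_multistability(
    params: ModelParameters,
    genotype: GenotypeSpec,
    *,
    rel_tol: float = 1e-4,
    **kwargs,
) -> tuple[bool, SteadyStateResult, SteadyStateResult]:
    """Solve from the all-heterotrimer and all-dissociated initial conditions
    and flag the parameter set as multistable if the readouts disagree by more
    than ``rel_tol`` relative."""
    a = solve_steady_state(params, genotype, init="heterotrimer", **kwargs)
    b = solve_steady_state(params, genotype, init="dissociated", **kwargs)

    def rel(x, y):
        scale = max(abs(x), abs(y), 1e-12)
        return abs(x - y) / scale

    flag = (rel(a.active_trio, b.active_trio) > rel_tol
            or rel(a.active_plc, b.active_plc) > rel_tol)
    return flag, a, b
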