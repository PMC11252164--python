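"""Saltelli sampling and Sobol sensitivity estimators.

Implements the standard variance-based global sensitivity workflow: a Saltelli
design of ``n_base * (2D + 2)`` model evaluations built from a scrambled
Sobol' low-discrepancy sequence (two base matrices A and B plus the
cross-matrices AB_i and BA_i), and the Saltelli-2010 first-order and Jansen
total-order estimators with bootstrap confidence intervals.

The design matrices are laid out row-blockwise as

    [A; B; AB_1 ... AB_D; BA_1 ... BA_D]

where AB_i is A with column i taken from B (and vice versa for BA_i), so a
model evaluated on the full sample can be unstacked by block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

__all__ = ["SaltelliDesign", "saltelli_sample", "sobol_indices", "SobolIndices"]


@dataclass
class SaltelliDesign:
    """A Saltelli design in the unit hypercube plus its metadata."""

    unit_sample: np.ndarray  # (n_base * (2D + 2), D)
    n_base: int
    d: int
    seed: int

    @property
    def n_total(self) -> int:
        return self.n_base * (2 * self.d + 2)

    def blocks(self, y: np.ndarray):
        """Unstack model outputs evaluated on ``unit_sample`` row order into
        (yA, yB, yAB (n_base x D), yBA (n_base x D))."""
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n_total:
            raise ValueError(
                f"expected {self.n_total} outputs for this design, got {y.shape[0]}"
            )
        n, d = self.n_base, self.d
        ya = y[:n]
        yb = y[n:2 * n]
        yab = y[2 * n:(2 + d) * n].reshape(d, n).T
        yba = y[(2 + d) * n:].reshape(d, n).T
        return ya, yb, yab, yba


def saltelli_sample(d: int, n_base: int, seed: int) -> SaltelliDesign:
    """Build the Saltelli cross-sampling design for ``d`` factors.

    ``n_base`` should be a power of two for the balance properties of the
    Sobol' sequence; other values are accepted (a matter of estimator
    convergence, not correctness).
    """
    if d < 1:
        raise ValueError("need at least one factor")
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    sampler = qmc.Sobol(d=2 * d, scramble=True, rng=np.random.default_rng(seed))
    if n_base & (n_base - 1) == 0:
        base = sampler.random_base2(int(np.log2(n_base)))
    else:
        base = sampler.random(n_base)
    A, B = base[:, :d], base[:, d:]
    rows = [A, B]
    for i in range(d):
        AB = A.copy()
        AB[:, i] = B[:, i]
        rows.append(AB)
    for i in range(d):
        BA = B.copy()
        BA[:, i] = A[:, i]
        rows.append(BA)
    return SaltelliDesign(np.vstack(rows), n_base=n_base, d=d, seed=seed)


@dataclass
class SobolIndices:
    """First-order and total-order Sobol indices with bootstrap CIs.

    Small negative values are expected sampling noise for parameters with
    near-zero influence; they are reported as-is (flagged via ``ci_low``).
    """

    names: list[str]
    s1: np.ndarray
    st: np.ndarray
    s1_ci: np.ndarray  # (D, 2) low/high
    st_ci: np.ndarray

    def ranking(self, order: str = "total") -> list[str]:
        vals = self.st if order == "total" else self.s1
        return [self.names[i] for i in np.argsort(vals)[::-1]]

    def as_dict(self) -> dict:
        return {
            name: {
                "S1": float(self.s1[i]),
                "ST": float(self.st[i]),
                "S1_ci": [float(v) for v in self.s1_ci[i]],
                "ST_ci": [float(v) for v in self.st_ci[i]],
            }
            for i, name in enumerate(self.names)
        }


def _estimate(ya, yb, yab):
    """Saltelli-2010 first-order and Jansen total-order estimators."""
    yall = np.concatenate([ya, yb])
    var = np.var(yall)
    if var <= 0:
        d = yab.shape[1]
        return np.zeros(d), np.zeros(d)
    s1 = np.mean(yb[:, None] * (yab - ya[:, None]), axis=0) / var
    st = 0.5 * np.mean((ya[:, None] - yab) ** 2, axis=0) / var
    return s1, st


def sobol_indices(
    design: SaltelliDesign,
    y: np.ndarray,
    names: list[str] | None = None,
    *,
    n_boot: int = 200,
    ci_level: float = 0.95,
    seed: int = 0,
) -> SobolIndices:
    """Estimate Sobol indices from model outputs on a Saltelli design.

    Rows with non-finite outputs are handled by the caller (see
    ``parameter_exploration``); here they must already be finite.
    """
    ya, yb, yab, _ = design.blocks(y)
    if not (np.all(np.isfinite(ya)) and np.all(np.isfinite(yb))
            and np.all(np.isfinite(yab))):
        raise ValueError("non-finite outputs; impute or drop before estimating")
    if names is None:
        names = [f"x{i}" for i in range(design.d)]
    if len(names) != design.d:
        raise ValueError("one name per factor required")

    s1, st = _estimate(ya, yb, yab)

    rng = np.random.default_rng(seed)
    n = design.n_base
    boots_s1 = np.empty((n_boot, design.d))
    boots_st = np.empty((n_boot, design.d))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b1, bt = _estimate(ya[idx], yb[idx], yab[idx])
        boots_s1[b] = b1
        boots_st[b] = bt
    lo = 100 * (1 - ci_level) / 2
    s1_ci = np.percentile(boots_s1, [lo, 100 - lo], axis=0).T
    st_ci = np.percentile(boots_st, [lo, 100 - lo], axis=0).T
    return SobolIndices(list(names), s1, st, s1_ci, st_ci)
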