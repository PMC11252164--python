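"""Global parameter-space exploration of the mutant signaling model.

Covers the model-driven discovery loop: sample parameter sets over wide
(log-uniform) ranges, simulate the heterozygous GNAQ Q209L and CYSLTR2 L129Q
genotypes per set, then

* rank parameters by Sobol total sensitivity of the Q209L-minus-L129Q output
  differences,
* classify each set into diverging-behavior classes (strong/weak ERK x YAP),
* flag sets that match the experimentally observed activation pattern
  (L129Q PLC-beta >= Q209L's AND L129Q TRIO < Q209L's),
* discriminate matching from non-matching sets per parameter
  (two-sample Kolmogorov-Smirnov) and score single-parameter threshold
  classifiers (ROC / AUC),
* sweep the PLC-beta GAP strength k_hyd2 (as fold over basal hydrolysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, qmc
from statsmodels.stats.multitest import multipletests

from .genotype import GenotypeSpec, WT, parse_genotype
from .parameters import ModelParameters
from .sobol import SaltelliDesign, SobolIndices, saltelli_sample, sobol_indices
from .steady import SteadyStateError, check_multistability, fold_changes, \
    solve_steady_state

__all__ = [
    "ParameterRange",
    "ParameterRangeSpec",
    "ParameterSetBatch",
    "default_ranges",
    "sensitivity_ranges",
    "sample_parameter_sets",
    "evaluate_batch",
    "sobol_total",
    "classify_behavior",
    "behavior_fractions",
    "match_experiment",
    "ks_discriminate",
    "roc_classifier",
    "khyd2_sweep",
    "BEHAVIOR_LABELS",
]

logger = logging.getLogger(__name__)

BEHAVIOR_LABELS = ("strongERK_weakYAP", "weakERK_strongYAP", "weak_both",
                   "strong_both")

#: Symbols that are plain ModelParameters fields; ``effector_bias`` is the
#: composite mutant TRIO-over-PLC association bias of the Q209 mutants.
_COMPOSITE = ("effector_bias",)


@dataclass(frozen=True)
class ParameterRange:
    name: str
    low: float
    high: float
    scale: str = "log"  # "log" (log-uniform) or "linear"

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ValueError(f"scale must be 'log' or 'linear', got {self.scale!r}")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log-scale bounds must be positive")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        if self.scale == "log":
            lo, hi = np.log10(self.low), np.log10(self.high)
            return 10.0 ** (lo + u * (hi - lo))
        return self.low + u * (self.high - self.low)


@dataclass
class ParameterRangeSpec:
    """Varied-parameter ranges; everything else is fixed at the base preset."""

    ranges: list[ParameterRange]

    def __post_init__(self):
        if not self.ranges:
            raise ValueError("at least one varied parameter required")
        names = [r.name for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("duplicate varied parameter names")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.ranges]

    @property
    def d(self) -> int:
        return len(self.ranges)

    def from_unit(self, unit: np.ndarray) -> pd.DataFrame:
        unit = np.atleast_2d(unit)
        cols = {r.name: r.from_unit(unit[:, i]) for i, r in enumerate(self.ranges)}
        return pd.DataFrame(cols)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterRangeSpec":
        return cls([ParameterRange(name=k, **v) for k, v in d.items()])

    def to_dict(self) -> dict:
        return {r.name: {"low": r.low, "high": r.high, "scale": r.scale}
                for r in self.ranges}


def default_ranges(params: ModelParameters, half_decades: float = 1.5
                   ) -> ParameterRangeSpec:
    """The shipped exploration design: six parameters, log-uniform over
    +/- ``half_decades`` decades around the base preset's values.

    The varied set (PLC-beta GAP strength, Q209 effector bias, the three
    competing protein abundances and the GEF rate) spans the quantities the
    headline sensitivity and classifier analyses need.
    """
    centers = {
        "k_hyd2": params.k_hyd2,
        "effector_bias": params.variants["Q209L"].effector_bias,
        "TRIO_tot": params.TRIO_tot,
        "PLC_tot": params.PLC_tot,
        "RGS_tot": params.RGS_tot,
        "k_gef": params.k_gef,
    }
    f = 10.0 ** half_decades
    return ParameterRangeSpec(
        [ParameterRange(name, c / f, c * f, "log") for name, c in centers.items()]
    )


#: Half-widths (decades) for the Sobol sensitivity design: kinetic unknowns get
#: the full +-1.5 decades, protein abundances +-1.0 (cell-to-cell variation is
#: narrower than kinetic uncertainty), and the receptor-activity product k_gef
#: +-0.75 — at full width a pure throughput knob dominates the variance of the
#: output differences and masks every mechanistically interesting ranking.
_SENSITIVITY_WIDTHS = {
    "k_hyd2": 1.5,
    "effector_bias": 1.5,
    "TRIO_tot": 1.0,
    "PLC_tot": 1.0,
    "RGS_tot": 1.0,
    "k_gef": 0.75,
}


def sensitivity_ranges(params: ModelParameters) -> ParameterRangeSpec:
    """Ranges for the Sobol global-sensitivity batch (see module docs)."""
    centers = {
        "k_hyd2": params.k_hyd2,
        "effector_bias": params.variants["Q209L"].effector_bias,
        "TRIO_tot": params.TRIO_tot,
        "PLC_tot": params.PLC_tot,
        "RGS_tot": params.RGS_tot,
        "k_gef": params.k_gef,
    }
    return ParameterRangeSpec(
        [ParameterRange(name, c / 10.0 ** w, c * 10.0 ** w, "log")
         for (name, c), w in zip(centers.items(), _SENSITIVITY_WIDTHS.values())]
    )


@dataclass
class ParameterSetBatch:
    """Sampled parameter sets plus (after evaluation) per-set model outputs.

    ``table`` holds one row per set: the varied inputs, and after
    :func:`evaluate_batch` the readouts ``aT_q209l``/``aP_q209l``/
    ``aT_l129q``/``aP_l129q``, the folds vs each set's own WT baseline, the
    behavior ``label`` and the experiment-``match`` flag.  Non-converged (and,
    when screened, multistable) rows are retained with NaN outputs and
    counted, so Saltelli block pairing stays intact; consumers drop them.
    """

    spec: ParameterRangeSpec
    table: pd.DataFrame
    scheme: str
    seed: int
    n_base: int | None = None
    design: SaltelliDesign | None = None
    n_failed: int = 0
    n_multistable: int = 0
    evaluated: bool = False
    base_params: ModelParameters | None = None

    @property
    def n(self) -> int:
        return len(self.table)

    def ok_rows(self) -> pd.DataFrame:
        if not self.evaluated:
            raise ValueError("batch not evaluated yet")
        return self.table.dropna(subset=["aT_q209l"])

    def manifest(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "n": self.n,
            "n_base": self.n_base,
            "varied": self.spec.to_dict(),
            "n_failed": self.n_failed,
            "n_multistable": self.n_multistable,
        }


def sample_parameter_sets(
    spec: ParameterRangeSpec,
    scheme: str = "saltelli",
    *,
    n_base: int | None = None,
    n: int | None = None,
    seed: int = 0,
) -> ParameterSetBatch:
    """Draw parameter sets (inputs only).

    ``saltelli`` (for Sobol analysis; ``n_base * (2D + 2)`` rows),
    ``lhs`` (Latin hypercube) or ``uniform`` — the latter two take ``n``.
    Deterministic under a fixed seed.
    """
    d = spec.d
    if scheme == "saltelli":
        if n_base is None:
            raise ValueError("saltelli scheme requires n_base")
        if n_base & (n_base - 1) != 0:
            logger.warning("n_base=%d is not a power of two; Sobol'-sequence "
                           "balance (and estimator convergence) suffers", n_base)
        design = saltelli_sample(d, n_base, seed)
        table = spec.from_unit(design.unit_sample)
        return ParameterSetBatch(spec, table, scheme, seed, n_base=n_base,
                                 design=design)
    if n is None:
        raise ValueError(f"scheme {scheme!r} requires n")
    if scheme == "lhs":
        unit = qmc.LatinHypercube(d=d, rng=np.random.default_rng(seed)).random(n)
    elif scheme == "uniform":
        unit = np.random.default_rng(seed).random((n, d))
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    return ParameterSetBatch(spec, spec.from_unit(unit), scheme, seed)


def apply_row(params: ModelParameters, row: dict) -> ModelParameters:
    """Materialize one sampled row into a full parameter set."""
    plain = {k: v for k, v in row.items() if k not in _COMPOSITE}
    out = params.replace(**plain)
    if "effector_bias" in row:
        for variant in ("Q209L", "Q209P"):
            if variant in out.variants:
                out = out.set_effector_bias(row["effector_bias"], variant)
    return out


_GT_Q209L = parse_genotype("GNAQ:Q209L:het")
_GT_L129Q = parse_genotype("CYSLTR2:L129Q:het")


def evaluate_batch(
    batch: ParameterSetBatch,
    base_params: ModelParameters,
    *,
    check_multistable: bool = False,
    max_failed_frac: float = 0.2,
) -> ParameterSetBatch:
    """Fill per-set outputs: steady states for the set's own WT baseline and
    the heterozygous Q209L and L129Q genotypes, plus folds and flags.

    Rows whose solves fail (or that are flagged multistable when screening is
    on) get NaN outputs and are counted; more than ``max_failed_frac``
    failures aborts with advice to revise the ranges.
    """
    cols = {k: np.full(batch.n, np.nan) for k in
            ("aT_q209l", "aP_q209l", "aT_l129q", "aP_l129q",
             "foldT_q209l", "foldP_q209l", "foldT_l129q", "foldP_l129q")}
    n_failed = 0
    n_multi = 0
    for i, row in enumerate(batch.table[batch.spec.names].to_dict("records")):
        try:
            p = apply_row(base_params, row)
            if check_multistable:
                multi = False
                for gt in (WT, _GT_Q209L, _GT_L129Q):
                    flag, *_ = check_multistability(p, gt)
                    multi = multi or flag
                if multi:
                    n_multi += 1
                    logger.warning("row %d flagged multistable; excluded", i)
                    continue
            base = solve_steady_state(p, WT)
            q = solve_steady_state(p, _GT_Q209L)
            l = solve_steady_state(p, _GT_L129Q)
            fold_changes(q, base)
            fold_changes(l, base)
        except (SteadyStateError, ValueError):
            n_failed += 1
            continue
        cols["aT_q209l"][i], cols["aP_q209l"][i] = q.active_trio, q.active_plc
        cols["aT_l129q"][i], cols["aP_l129q"][i] = l.active_trio, l.active_plc
        cols["foldT_q209l"][i], cols["foldP_q209l"][i] = q.fold_trio, q.fold_plc
        cols["foldT_l129q"][i], cols["foldP_l129q"][i] = l.fold_trio, l.fold_plc

    bad_frac = (n_failed + n_multi) / batch.n
    if bad_frac > max_failed_frac:
        raise RuntimeError(
            f"{100 * bad_frac:.0f}% of parameter sets failed to converge "
            f"(limit {100 * max_failed_frac:.0f}%); revise the sampled ranges"
        )
    table = batch.table.copy()
    for k, v in cols.items():
        table[k] = v
    table["delta_trio"] = table["aT_q209l"] - table["aT_l129q"]
    table["delta_plc"] = table["aP_q209l"] - table["aP_l129q"]
    table["match"] = match_experiment(table).astype("boolean")
    table.loc[table["aT_q209l"].isna(), "match"] = pd.NA
    table["label"] = [classify_behavior(r) for _, r in table.iterrows()]

    batch.table = table
    batch.n_failed = n_failed
    batch.n_multistable = n_multi
    batch.evaluated = True
    batch.base_params = base_params
    if n_failed or n_multi:
        logger.info("excluded %d non-converged and %d multistable rows of %d",
                    n_failed, n_multi, batch.n)
    return batch


# -- Sobol sensitivity ------------------------------------------------------

def sobol_total(batch: ParameterSetBatch, outputs=("delta_trio", "delta_plc"),
                *, n_boot: int = 200, seed: int = 0) -> dict[str, SobolIndices]:
    """Sobol indices of the Q209L-minus-L129Q differences per varied parameter.

    Requires a Saltelli-schemed, evaluated batch.  Base-sample indices with
    any failed row across their 2D+2 design blocks are dropped pairwise.
    """
    if batch.scheme != "saltelli" or batch.design is None:
        raise ValueError("Sobol analysis requires a Saltelli-schemed batch")
    if not batch.evaluated:
        raise ValueError("evaluate the batch first")
    design = batch.design
    out: dict[str, SobolIndices] = {}
    for col in outputs:
        y = batch.table[col].to_numpy()
        ya, yb, yab, yba = design.blocks(y)
        keep = (np.isfinite(ya) & np.isfinite(yb)
                & np.all(np.isfinite(yab), axis=1)
                & np.all(np.isfinite(yba), axis=1))
        if keep.sum() < design.n_base:
            logger.info("%s: dropping %d/%d base samples with failed rows",
                        col, design.n_base - keep.sum(), design.n_base)
        sub = SaltelliDesign(design.unit_sample, int(keep.sum()), design.d,
                             design.seed)
        y_sub = np.concatenate([ya[keep], yb[keep], yab[keep].T.ravel(),
                                yba[keep].T.ravel()])
        out[col] = sobol_indices(sub, y_sub, batch.spec.names,
                                 n_boot=n_boot, seed=seed)
    return out


# -- behavior classification ------------------------------------------------

def classify_behavior(row, theta: float = 0.5) -> str:
    """Label one evaluated row by the L129Q network's ability to activate each
    pathway relative to Q209L.

    Pathway P of L129Q is *weak* iff (fold_P(L129Q) - 1) < theta *
    (fold_P(Q209L) - 1).  The PLC-beta readout proxies the ERK pathway, the
    TRIO readout the YAP pathway.  Rows where Q209L itself does not activate a
    pathway (fold <= 1) are ``undefined``; failed rows are ``excluded``.
    """
    fq_t, fq_p = row["foldT_q209l"], row["foldP_q209l"]
    fl_t, fl_p = row["foldT_l129q"], row["foldP_l129q"]
    if any(pd.isna(v) for v in (fq_t, fq_p, fl_t, fl_p)):
        return "excluded"
    if fq_t <= 1 or fq_p <= 1:
        return "undefined"
    weak_yap = (fl_t - 1) < theta * (fq_t - 1)
    weak_erk = (fl_p - 1) < theta * (fq_p - 1)
    if weak_erk and weak_yap:
        return "weak_both"
    if weak_erk:
        return "weakERK_strongYAP"
    if weak_yap:
        return "strongERK_weakYAP"
    return "strong_both"


def behavior_fractions(batch: ParameterSetBatch,
                       thetas=(0.25, 0.5, 0.75)) -> pd.DataFrame:
    """Class frequencies over the retained rows, for several weak/strong
    thresholds theta (the 0.5 column is the headline one)."""
    rows = batch.ok_rows()
    recs = {}
    for theta in thetas:
        labels = rows.apply(classify_behavior, axis=1, theta=theta)
        defined = labels[labels != "undefined"]
        frac = defined.value_counts(normalize=True)
        recs[theta] = {lab: float(frac.get(lab, 0.0)) for lab in BEHAVIOR_LABELS}
    return pd.DataFrame(recs).rename_axis(index="label", columns="theta")


# -- experiment matching and parameter discrimination -----------------------

def match_experiment(rows) -> pd.Series | bool:
    """The published predicate: L129Q activates PLC-beta at least as much as
    Q209L AND activates TRIO strictly less.  Accepts a row or a table."""
    single = not isinstance(rows, pd.DataFrame)
    t = pd.DataFrame([rows]) if single else rows
    flag = (t["aP_l129q"] >= t["aP_q209l"]) & (t["aT_l129q"] < t["aT_q209l"])
    return bool(flag.iloc[0]) if single else flag


def ks_discriminate(batch: ParameterSetBatch,
                    parameter: str | None = None) -> pd.DataFrame:
    """Two-sample KS test of each varied parameter's values split by the
    match flag; ranked by D with Benjamini-Hochberg adjusted p-values."""
    rows = batch.ok_rows()
    matched = rows[rows["match"].astype(bool)]
    unmatched = rows[~rows["match"].astype(bool)]
    if len(matched) == 0 or len(unmatched) == 0:
        raise ValueError("both match classes must be non-empty")
    if min(len(matched), len(unmatched)) < 10:
        logger.warning("a match class has <10 members (%d vs %d); KS results "
                       "will be unstable", len(matched), len(unmatched))
    names = [parameter] if parameter else batch.spec.names
    recs = []
    for name in names:
        d, p = ks_2samp(matched[name], unmatched[name])
        recs.append({"parameter": name, "D": float(d), "p": float(p)})
    df = pd.DataFrame(recs)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values("D", ascending=False, ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class RocCurve:
    parameter: str
    direction: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_classifier(batch: ParameterSetBatch, parameter: str,
                   direction: str = "ge") -> RocCurve:
    """Score a single-parameter threshold rule as a match classifier.

    ``direction="ge"`` predicts a match when the parameter is >= the
    threshold (used for the effector bias), ``"lt"`` when it is < the
    threshold (used for k_hyd2).  Thresholds sweep the parameter's sampled
    range; AUC is the trapezoidal area of the resulting curve.
    """
    if direction not in ("ge", "lt"):
        raise ValueError("direction must be 'ge' or 'lt'")
    rows = batch.ok_rows()
    y = rows["match"].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValueError("need both match and non-match rows for a ROC curve")
    v = rows[parameter].to_numpy()
    thr = np.unique(v)
    pad = np.array([thr[0] - 1, *thr, thr[-1] + 1], dtype=float)
    tpr = np.empty(len(pad))
    fpr = np.empty(len(pad))
    for i, t in enumerate(pad):
        pred = v >= t if direction == "ge" else v < t
        tpr[i] = np.sum(pred & y) / np.sum(y)
        fpr[i] = np.sum(pred & ~y) / np.sum(~y)
    # along the threshold sweep TPR and FPR are jointly monotone, so the
    # curve only needs orienting by ascending FPR (never a tie-breaking sort)
    if fpr[0] > fpr[-1]:
        tpr, fpr, pad = tpr[::-1], fpr[::-1], pad[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(parameter, direction, pad, tpr, fpr, auc)


# -- k_hyd2 sweep -----------------------------------------------------------

def khyd2_sweep(
    params: ModelParameters,
    ratio_grid: np.ndarray,
    genotypes: tuple[GenotypeSpec, ...] = (WT, _GT_Q209L, _GT_L129Q),
) -> pd.DataFrame:
    """Readouts vs the PLC-beta GAP strength expressed as k_hyd2 / k_hyd.

    Intended to run off the revised preset (Q209 effector bias fixed at 4);
    a warning is logged otherwise.  The returned table carries one row per
    (ratio, genotype) plus a per-ratio ``match`` column evaluated on the
    Q209L/L129Q pair.
    """
    bias = params.variants["Q209L"].effector_bias
    if abs(bias - 4.0) > 1e-9:
        logger.warning("k_hyd2 sweep is defined at Q209 effector bias 4; "
                       "params have %g", bias)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    recs = []
    for ratio in ratio_grid:
        p = params.replace(k_hyd2=ratio * params.k_hyd)
        sols = {}
        for gt in genotypes:
            r = solve_steady_state(p, gt)
            sols[str(gt)] = r
        q, l = sols.get(str(_GT_Q209L)), sols.get(str(_GT_L129Q))
        match = (q is not None and l is not None
                 and l.active_plc >= q.active_plc
                 and l.active_trio < q.active_trio)
        for name, r in sols.items():
            recs.append({
                "ratio": float(ratio), "genotype": name,
                "active_trio": r.active_trio, "active_plc": r.active_plc,
                "match": match,
            })
    return pd.DataFrame(recs)
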