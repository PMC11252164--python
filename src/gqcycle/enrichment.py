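"""Exact co-mutation enrichment probability with two independent checks.

For a cohort of N patients in which x carry an index-gene mutation and y carry
a mutation in a gene family of interest, the probability that the two carrier
sets — placed uniformly and independently at random — overlap in exactly k
patients is

    P(K = k) = (N-k)! / [(x-k)! (y-k)! (N+k-x-y)!] * C(N,k) / [C(N,x) C(N,y)]

(the number of ways of arranging the observed co-mutation count divided by the
number of ways of distributing both mutation sets at random).  This equals the
hypergeometric point mass C(x,k) C(N-x, y-k) / C(N,y); the module evaluates
the combinatorial expression in log-gamma space (stable to N ~ 1e5), checks it
against scipy's hypergeometric pmf and exact integer arithmetic, and estimates
it by Monte Carlo.  The point mass is the primary quantity; the right tail
P(K >= k) — the conventional "at least this much overlap" enrichment question
— is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentInputs",
    "EnrichmentResult",
    "enrichment_probability",
    "hypergeom_point_mass",
    "exact_point_mass",
    "tail_probability",
    "mc_enrichment",
    "enrichment_report",
    "CohortMutationTable",
    "table_to_inputs",
    "load_gene_family",
]


@dataclass(frozen=True)
class EnrichmentInputs:
    """The (N, x, y, k) quadruple: cohort size, index-gene carriers,
    family-gene carriers, and patients with both."""

    N: int
    x: int
    y: int
    k: int

    def __post_init__(self):
        checks = (
            (self.N >= 0, f"N >= 0 violated (N={self.N})"),
            (0 <= self.x <= self.N, f"0 <= x <= N violated (x={self.x}, N={self.N})"),
            (0 <= self.y <= self.N, f"0 <= y <= N violated (y={self.y}, N={self.N})"),
            (0 <= self.k <= min(self.x, self.y),
             f"0 <= k <= min(x, y) violated (k={self.k}, x={self.x}, y={self.y})"),
            (self.x + self.y - self.k <= self.N,
             f"x + y - k <= N violated ({self.x}+{self.y}-{self.k} > {self.N})"),
        )
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


def _lchoose(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def enrichment_probability(inputs: EnrichmentInputs) -> float:
    """The combinatorial co-mutation probability P(K = k), in log-gamma space."""
    N, x, y, k = inputs.N, inputs.x, inputs.y, inputs.k
    log_p = (
        gammaln(N - k + 1)
        - gammaln(x - k + 1) - gammaln(y - k + 1) - gammaln(N + k - x - y + 1)
        + _lchoose(N, k) - _lchoose(N, x) - _lchoose(N, y)
    )
    return float(np.exp(log_p))


def hypergeom_point_mass(inputs: EnrichmentInputs) -> float:
    """Independent check: the hypergeometric pmf P(K = k) for drawing y
    patients from N of which x are index carriers."""
    if inputs.N == 0:
        return 1.0  # empty cohort: the zero overlap is forced
    return float(hypergeom.pmf(inputs.k, inputs.N, inputs.x, inputs.y))


def exact_point_mass(inputs: EnrichmentInputs) -> Fraction:
    """Exact rational evaluation of the combinatorial expression (integer
    arithmetic; intended as a cross-check for moderate N)."""
    N, x, y, k = inputs.N, inputs.x, inputs.y, inputs.k
    num = Fraction(factorial(N - k), factorial(x - k) * factorial(y - k)
                   * factorial(N + k - x - y))
    return num * comb(N, k) / (Fraction(comb(N, x)) * comb(N, y))


def tail_probability(inputs: EnrichmentInputs) -> float:
    """Right tail P(K >= k): the probability of at least the observed overlap."""
    total = 0.0
    for kk in range(inputs.k, min(inputs.x, inputs.y) + 1):
        if inputs.x + inputs.y - kk <= inputs.N:
            total += enrichment_probability(
                EnrichmentInputs(inputs.N, inputs.x, inputs.y, kk))
    return min(total, 1.0)


def mc_enrichment(inputs: EnrichmentInputs, n_draws: int = 1_000_000,
                  seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo estimate of P(K = k) with its binomial standard error.

    Draws the x-set and y-set uniformly and independently from N patients and
    counts draws whose overlap is exactly k.  Seed-deterministic.
    """
    if n_draws < 10_000:
        raise ValueError("use at least 1e4 draws for a meaningful estimate")
    rng = np.random.default_rng(seed)
    N, x, y, k = inputs.N, inputs.x, inputs.y, inputs.k
    hits = 0
    chunk = 50_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        # a uniform size-s subset per draw: the s smallest of N iid uniforms
        masks = []
        for size in (x, y):
            u = rng.random((m, N))
            idx = np.argpartition(u, max(size - 1, 0), axis=1)[:, :size]
            mask = np.zeros((m, N), dtype=bool)
            np.put_along_axis(mask, idx, True, axis=1)
            masks.append(mask)
        overlap = np.sum(masks[0] & masks[1], axis=1)
        hits += int(np.sum(overlap == k))
        done += m
    p = hits / n_draws
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return p, se


def enrichment_report(inputs: EnrichmentInputs, n_draws: int = 0,
                      seed: int = 0) -> "EnrichmentResult":
    """Evaluate the point probability every available way (MC only when
    ``n_draws`` > 0) and package the results."""
    p_point = enrichment_probability(inputs)
    p_hyp = hypergeom_point_mass(inputs)
    p_mc = se = None
    if n_draws:
        p_mc, se = mc_enrichment(inputs, n_draws, seed)
    return EnrichmentResult(
        inputs=inputs, p_point=p_point, p_hypergeom=p_hyp,
        p_tail=tail_probability(inputs), p_mc=p_mc, mc_se=se,
        mc_draws=n_draws or None,
    )


@dataclass
class EnrichmentResult:
    inputs: EnrichmentInputs
    p_point: float
    p_hypergeom: float
    p_tail: float
    p_mc: float | None = None
    mc_se: float | None = None
    mc_draws: int | None = None

    def as_dict(self) -> dict:
        d = {"N": self.inputs.N, "x": self.inputs.x, "y": self.inputs.y,
             "k": self.inputs.k, "p_point": self.p_point,
             "p_hypergeom": self.p_hypergeom, "p_tail": self.p_tail}
        if self.p_mc is not None:
            d.update(p_mc=self.p_mc, mc_se=self.mc_se, mc_draws=self.mc_draws)
        return d


# -- cohort tables ----------------------------------------------------------

@dataclass
class CohortMutationTable:
    """Boolean patients-by-genes mutation matrix (unique patient index)."""

    flags: pd.DataFrame

    def __post_init__(self):
        if self.flags.index.has_duplicates:
            raise ValueError("patient identifiers must be unique")
        self.flags = self.flags.astype(bool)

    @property
    def patients(self) -> pd.Index:
        return self.flags.index

    @property
    def genes(self) -> pd.Index:
        return self.flags.columns

    @classmethod
    def from_long(cls, records: pd.DataFrame) -> "CohortMutationTable":
        """Pivot a MAF-like long table with ``patient_id`` and ``gene``
        columns (one row per mutation call) into the boolean matrix.
        Patients without mutations may be declared with an empty gene field.
        """
        required = {"patient_id", "gene"}
        if not required.issubset(records.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        records = records.copy()
        records["gene"] = records["gene"].fillna("")
        patients = pd.Index(records["patient_id"].unique(), name="patient_id")
        calls = records[records["gene"] != ""]
        flags = (
            calls.assign(flag=True)
            .pivot_table(index="patient_id", columns="gene", values="flag",
                         aggfunc="any", fill_value=False)
            .reindex(patients, fill_value=False)
        )
        return cls(flags)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortMutationTable":
        return cls.from_long(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        long = (self.flags.stack().rename("mut").reset_index()
                .rename(columns={"level_1": "gene"}))
        long = long[long["mut"]][["patient_id", "gene"]]
        # keep mutation-free patients visible as empty-gene rows
        empty = self.flags.index[~self.flags.any(axis=1)]
        long = pd.concat(
            [long, pd.DataFrame({"patient_id": empty, "gene": ""})],
            ignore_index=True)
        long.to_csv(path, sep="\t", index=False)


def table_to_inputs(table: CohortMutationTable, index_gene: str,
                    family_genes: list[str]) -> EnrichmentInputs:
    """Reduce a cohort table to the (N, x, y, k) quadruple.

    ``y`` counts patients with at least one mutated family gene; the index
    gene must be present as a column, family genes absent from the table
    count as unmutated.
    """
    if len(table.flags) == 0:
        raise ValueError("empty cohort table")
    if index_gene not in table.genes:
        raise ValueError(f"index gene {index_gene!r} not in the table")
    idx = table.flags[index_gene]
    present = [g for g in family_genes if g in table.genes]
    fam = (table.flags[present].any(axis=1) if present
           else pd.Series(False, index=table.patients))
    return EnrichmentInputs(
        N=len(table.flags), x=int(idx.sum()), y=int(fam.sum()),
        k=int((idx & fam).sum()),
    )


def load_gene_family(path: str | Path | None = None) -> list[str]:
    """Load a plain-text gene list (one symbol per line, '#' comments).

    Without a path, the packaged semaphorin/plexin family list is returned
    (a curated 29-gene stand-in; see the file header)."""
    if path is None:
        from importlib import resources
        text = (resources.files("gqcycle.data") / "sema_plexin_genes.txt").read_text()
    else:
        text = Path(path).read_text()
    genes = [ln.strip() for ln in text.splitlines()]
    return [g for g in genes if g and not g.startswith("#")]
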