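"""Co-mutation enrichment probability: identities, normalization, symmetry,
Monte-Carlo agreement, and cohort-table reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gqcycle.enrichment import (
    CohortMutationTable,
    EnrichmentInputs,
    enrichment_probability,
    enrichment_report,
    exact_point_mass,
    hypergeom_point_mass,
    load_gene_family,
    mc_enrichment,
    table_to_inputs,
    tail_probability,
)


def valid_quadruples(max_n):
    return st.integers(0, max_n).flatmap(
        lambda n: st.tuples(
            st.just(n), st.integers(0, n), st.integers(0, n)
        ).flatmap(
            lambda nxy: st.tuples(
                st.just(nxy[0]), st.just(nxy[1]), st.just(nxy[2]),
                st.integers(max(0, nxy[1] + nxy[2] - nxy[0]),
                            min(nxy[1], nxy[2])),
            )
        )
    )


class TestPointMass:
    def test_hand_enumerable_case(self):
        # two patients, one carrier of each mutation: 2 of the 4 equally
        # likely placements coincide
        assert enrichment_probability(EnrichmentInputs(2, 1, 1, 1)) == \
            pytest.approx(0.5)

    def test_forced_total_overlap(self):
        for n in (1, 5, 40):
            assert enrichment_probability(EnrichmentInputs(n, n, n, n)) == \
                pytest.approx(1.0)

    def test_identity_with_hypergeometric_exhaustive(self):
        """The combinatorial expression equals the hypergeometric point mass
        for every valid quadruple with N <= 30."""
        for n in range(31):
            for x in range(n + 1):
                for y in range(n + 1):
                    for k in range(max(0, x + y - n), min(x, y) + 1):
                        i = EnrichmentInputs(n, x, y, k)
                        p = enrichment_probability(i)
                        h = hypergeom_point_mass(i)
                        assert p == pytest.approx(h, rel=1e-10, abs=1e-300)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(valid_quadruples(200))
    def test_exact_integer_arithmetic_agrees(self, quad):
        i = EnrichmentInputs(*quad)
        assert enrichment_probability(i) == pytest.approx(
            float(exact_point_mass(i)), rel=1e-10, abs=1e-300)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(valid_quadruples(60))
    def test_symmetry_in_x_and_y(self, quad):
        n, x, y, k = quad
        a = enrichment_probability(EnrichmentInputs(n, x, y, k))
        b = enrichment_probability(EnrichmentInputs(n, y, x, k))
        assert a == pytest.approx(b, rel=1e-12, abs=1e-300)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40))
    def test_normalization_over_k(self, n, x, y):
        x, y = min(x, n), min(y, n)
        total = sum(
            enrichment_probability(EnrichmentInputs(n, x, y, k))
            for k in range(max(0, x + y - n), min(x, y) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_cohort_is_stable(self):
        p = enrichment_probability(EnrichmentInputs(100_000, 50, 80, 3))
        assert 0.0 < p < 1.0 and np.isfinite(p)

    @pytest.mark.parametrize("bad, msg", [
        ((10, 11, 2, 1), "x <= N"),
        ((10, 2, 3, 3), "min"),
        ((10, 8, 8, 2), "x \\+ y - k"),
    ])
    def test_invariant_violations_name_the_inequality(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            EnrichmentInputs(*bad)

    def test_tail_contains_point_and_caps_at_one(self):
        i = EnrichmentInputs(80, 3, 4, 2)
        assert tail_probability(i) >= enrichment_probability(i)
        assert tail_probability(EnrichmentInputs(10, 4, 5, 0)) == \
            pytest.approx(1.0)


class TestMonteCarlo:
    def test_hand_enumerable_case_within_3_se(self):
        p, se = mc_enrichment(EnrichmentInputs(2, 1, 1, 1), 100_000, seed=0)
        assert abs(p - 0.5) < 3 * se

    def test_seed_determinism(self):
        i = EnrichmentInputs(30, 5, 7, 2)
        assert mc_enrichment(i, 20_000, seed=8) == \
            mc_enrichment(i, 20_000, seed=8)

    def test_agrees_with_point_mass_on_random_grid(self):
        """Randomized quadruples: MC within 4 SE of the exact value."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 60))
            x = int(rng.integers(0, n + 1))
            y = int(rng.integers(0, n + 1))
            lo, hi = max(0, x + y - n), min(x, y)
            k = int(rng.integers(lo, hi + 1))
            i = EnrichmentInputs(n, x, y, k)
            p, se = mc_enrichment(i, 20_000, seed=int(rng.integers(1 << 30)))
            assert abs(p - enrichment_probability(i)) < 4 * se + 1e-12

    def test_estimator_unbiased_across_seeds(self):
        i = EnrichmentInputs(40, 6, 9, 2)
        truth = enrichment_probability(i)
        estimates = [mc_enrichment(i, 20_000, seed=s)[0] for s in range(12)]
        pooled_se = np.sqrt(truth * (1 - truth) / (12 * 20_000))
        assert abs(np.mean(estimates) - truth) < 4 * pooled_se

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            mc_enrichment(EnrichmentInputs(10, 2, 2, 1), 100)


class TestCohortTables:
    def _table(self, rows):
        return CohortMutationTable.from_long(
            pd.DataFrame(rows, columns=["patient_id", "gene"]))

    def test_no_family_carriers(self):
        t = self._table([("p1", "CYSLTR2"), ("p2", ""), ("p3", "OTHER")])
        i = table_to_inputs(t, "CYSLTR2", ["SEMA3A", "PLXNA1"])
        assert (i.N, i.x, i.y, i.k) == (3, 1, 0, 0)

    def test_overlap_counted_once_per_patient(self):
        t = self._table([
            ("p1", "CYSLTR2"), ("p1", "SEMA3A"), ("p1", "PLXNA1"),
            ("p2", "SEMA3A"), ("p3", ""),
        ])
        i = table_to_inputs(t, "CYSLTR2", ["SEMA3A", "PLXNA1"])
        assert (i.N, i.x, i.y, i.k) == (3, 1, 2, 1)

    def test_missing_index_gene_rejected(self):
        t = self._table([("p1", "SEMA3A")])
        with pytest.raises(ValueError, match="CYSLTR2"):
            table_to_inputs(t, "CYSLTR2", ["SEMA3A"])

    def test_empty_table_rejected(self):
        t = CohortMutationTable(pd.DataFrame(columns=["CYSLTR2"]))
        with pytest.raises(ValueError, match="empty"):
            table_to_inputs(t, "CYSLTR2", [])

    def test_duplicate_patients_rejected(self):
        flags = pd.DataFrame([[True], [False]], columns=["CYSLTR2"],
                             index=["p1", "p1"])
        with pytest.raises(ValueError, match="unique"):
            CohortMutationTable(flags)

    def test_tsv_round_trip(self, tmp_path):
        t = self._table([("p1", "CYSLTR2"), ("p2", "SEMA3A"), ("p3", "")])
        t.to_tsv(tmp_path / "c.tsv")
        back = CohortMutationTable.from_tsv(tmp_path / "c.tsv")
        assert len(back.flags) == 3
        assert bool(back.flags.loc["p1", "CYSLTR2"])

    def test_packaged_family_list_has_29_genes(self):
        fam = load_gene_family()
        assert len(fam) == 29
        assert "PLXND1" in fam and "SEMA7A" in fam


class TestReport:
    def test_printed_cohort_quadruples(self):
        tcga = enrichment_report(EnrichmentInputs(80, 3, 4, 2))
        assert tcga.p_point == pytest.approx(tcga.p_hypergeom, rel=1e-12)
        ref = enrichment_report(EnrichmentInputs(103, 2, 11, 2))
        assert 0 < ref.p_point < 1
        d = tcga.as_dict()
        assert {"N", "x", "y", "k", "p_point", "p_tail"} <= set(d)
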