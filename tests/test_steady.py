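"""Steady-state solver: convergence, conservation, solver cross-agreement,
and the hand-derived reduced-cycle oracle."""

import numpy as np
import pytest

from gqcycle import (
    WT,
    check_multistability,
    fold_changes,
    parse_genotype,
    solve_steady_state,
)
from gqcycle.steady import SteadyStateError
from gqcycle.synthetic import reduced_cycle_steady_state


def _random_params(base, rng):
    """Log-uniform jitter (half a decade) around a preset."""
    jitter = lambda v: v * 10 ** rng.uniform(-0.5, 0.5)
    return base.replace(
        k_gef=jitter(base.k_gef), k_hyd=jitter(base.k_hyd),
        k_hyd2=jitter(base.k_hyd2), k_rgs_cat=jitter(base.k_rgs_cat),
        TRIO_tot=jitter(base.TRIO_tot), PLC_tot=jitter(base.PLC_tot),
        RGS_tot=jitter(base.RGS_tot),
    )


class TestBaseline:
    def test_wt_baseline_has_small_positive_signal(self, revised_results,
                                                   revised_params):
        base = revised_results["WT"]
        assert 0 < base.active_trio < 0.2 * revised_params.TRIO_tot
        assert 0 < base.active_plc < 0.2 * revised_params.PLC_tot

    @pytest.mark.parametrize("preset_fixture", ["initial_results",
                                                "revised_results"])
    def test_conservation_everywhere(self, preset_fixture, request):
        results = request.getfixturevalue(preset_fixture)
        for r in results.values():
            assert r.conservation_error() < 1e-8
            assert r.residual_norm <= 1e-10 * 1.0 + 1e-18
            assert np.min(r.state) >= 0.0

    def test_stimulated_exceeds_basal(self, revised_params):
        basal = solve_steady_state(revised_params, WT)
        stim = solve_steady_state(revised_params, WT, stimulated=True)
        assert stim.active_trio > basal.active_trio
        assert stim.active_plc > basal.active_plc


class TestSolverAgreement:
    def test_integration_and_rootfinding_agree(self, revised_params):
        """The two solver routes agree to 1e-6 relative on the readouts over
        randomly jittered parameter sets and all three key genotypes."""
        rng = np.random.default_rng(7)
        genotypes = [WT, parse_genotype("GNAQ:Q209L:het"),
                     parse_genotype("CYSLTR2:L129Q:het")]
        for i in range(35):
            p = _random_params(revised_params, rng)
            gt = genotypes[i % 3]
            a = solve_steady_state(p, gt, method="integrate")
            b = solve_steady_state(p, gt, method="root")
            for x, y in ((a.active_trio, b.active_trio),
                         (a.active_plc, b.active_plc)):
                assert abs(x - y) / max(abs(x), abs(y), 1e-30) < 1e-6

    def test_two_initial_conditions_agree(self, revised_params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = _random_params(revised_params, rng)
            flag, a, b = check_multistability(p, parse_genotype("GNAQ:Q209L:het"))
            assert not flag

    def test_monotone_in_receptor_activity(self, revised_params):
        prev_t = prev_p = 0.0
        for f in (0.001, 0.01, 0.05, 0.2, 1.0):
            r = solve_steady_state(revised_params.replace(f_act_wt=f), WT)
            assert r.active_trio >= prev_t - 1e-12
            assert r.active_plc >= prev_p - 1e-12
            prev_t, prev_p = r.active_trio, r.active_plc


class TestReducedCycleOracle:
    def test_full_solver_matches_hand_derived_reduction(self, revised_params):
        """Without RGS, PLC-beta and the nucleotide-free branch the model
        collapses to a single-pool cycle solved by hand; the full solver must
        land on the same state to 1e-8."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = revised_params.replace(
                RGS_tot=0.0, PLC_tot=0.0, k_gtp_off=0.0,
                k_gef=float(10 ** rng.uniform(-1, 1)),
                k_hyd=float(10 ** rng.uniform(-3, -1)),
            )
            expect = reduced_cycle_steady_state(p)
            got = solve_steady_state(p, WT).species
            for name, v in expect.items():
                assert got[f"{name}_wt"] == pytest.approx(v, rel=1e-8, abs=1e-12)

    def test_reduction_requires_the_reduced_topology(self, revised_params):
        with pytest.raises(ValueError):
            reduced_cycle_steady_state(revised_params)


class TestFoldChanges:
    def test_identity(self, revised_results):
        base = revised_results["WT"]
        assert fold_changes(base, base) == pytest.approx((1.0, 1.0))

    def test_zero_baseline_rejected(self, revised_params, revised_results):
        dead = solve_steady_state(revised_params.replace(f_act_wt=0.0), WT)
        with pytest.raises(ValueError, match="baseline"):
            fold_changes(revised_results["WT"], dead)

    def test_nonconvergence_is_loud(self, revised_params):
        # a near-dead receptor drive onto a hydrolysis-dead mutant pool leaves
        # a ~1e12 s loading mode, beyond the integrator's longest window: the
        # solver must refuse rather than return the still-moving state
        import dataclasses
        p = revised_params.replace(f_act_wt=1e-11)
        p.variants["Q209L"] = dataclasses.replace(
            p.variants["Q209L"], r_hyd=1e-12, r_gap=1e-12)
        with pytest.raises(SteadyStateError, match="not converged"):
            solve_steady_state(p, parse_genotype("GNAQ:Q209L:het"),
                               method="integrate", atol_scale=1e-16)
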