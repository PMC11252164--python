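"""Parameter exploration: sampling, batch evaluation, behavior classification,
the experiment-match predicate, KS discrimination and ROC classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from sklearn.metrics import roc_auc_score

from gqcycle import parse_genotype, solve_steady_state, fold_changes, WT
from gqcycle.explore import (
    ParameterRange,
    ParameterRangeSpec,
    apply_row,
    classify_behavior,
    default_ranges,
    evaluate_batch,
    khyd2_sweep,
    ks_discriminate,
    match_experiment,
    roc_classifier,
    sample_parameter_sets,
    sensitivity_ranges,
)


@pytest.fixture(scope="module")
def spec(initial_params):
    return default_ranges(initial_params)


@pytest.fixture(scope="module")
def smoke_batch(spec, initial_params):
    """64-row evaluated batch shared by the discrimination tests."""
    batch = sample_parameter_sets(spec, "lhs", n=64, seed=5)
    return evaluate_batch(batch, initial_params)


class TestSampling:
    def test_log_uniform_marginals(self, spec):
        batch = sample_parameter_sets(spec, "uniform", n=400, seed=1)
        for r in spec.ranges:
            u = (np.log10(batch.table[r.name]) - np.log10(r.low)) / (
                np.log10(r.high) - np.log10(r.low))
            assert kstest(u, "uniform").pvalue > 0.01

    def test_seed_determinism(self, spec):
        a = sample_parameter_sets(spec, "lhs", n=32, seed=9).table
        b = sample_parameter_sets(spec, "lhs", n=32, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_saltelli_row_count(self, spec):
        batch = sample_parameter_sets(spec, "saltelli", n_base=8, seed=0)
        assert batch.n == 8 * (2 * spec.d + 2)

    def test_point_collapsed_ranges_give_identical_rows(self):
        tight = ParameterRangeSpec(
            [ParameterRange("k_hyd2", 0.2, 0.2 * (1 + 1e-12), "log")])
        batch = sample_parameter_sets(tight, "uniform", n=16, seed=3)
        assert batch.table["k_hyd2"].std() < 1e-10

    def test_default_designs_cover_the_classifier_parameters(self, spec,
                                                             initial_params):
        sens = sensitivity_ranges(initial_params)
        for s in (spec, sens):
            assert {"k_hyd2", "effector_bias"} <= set(s.names)
            assert s.d == 6


class TestEvaluateBatch:
    def test_smoke_batch_converges(self, smoke_batch):
        assert smoke_batch.n_failed / smoke_batch.n <= 0.1
        ok = smoke_batch.ok_rows()
        assert len(ok) >= 0.9 * smoke_batch.n

    def test_center_row_reproduces_single_simulation(self, spec,
                                                     initial_params):
        center = {r.name: float(np.sqrt(r.low * r.high)) for r in spec.ranges}
        batch = sample_parameter_sets(
            ParameterRangeSpec([ParameterRange(k, v, v * (1 + 1e-15), "log")
                                for k, v in center.items()]),
            "uniform", n=1, seed=0)
        batch.table.iloc[0] = list(center.values())
        evaluate_batch(batch, initial_params)
        p = apply_row(initial_params, center)
        base = solve_steady_state(p, WT)
        q = solve_steady_state(p, parse_genotype("GNAQ:Q209L:het"))
        row = batch.table.iloc[0]
        assert row["aT_q209l"] == q.active_trio
        assert row["foldT_q209l"] == q.active_trio / base.active_trio

    def test_apply_row_sets_bias_on_both_q209_variants(self, initial_params):
        p = apply_row(initial_params, {"effector_bias": 7.0, "k_hyd2": 0.5})
        assert p.variants["Q209L"].effector_bias == pytest.approx(7.0)
        assert p.variants["Q209P"].effector_bias == pytest.approx(7.0)
        assert p.k_hyd2 == 0.5


class TestClassifyBehavior:
    def _row(self, fq_t, fq_p, fl_t, fl_p):
        return {"foldT_q209l": fq_t, "foldP_q209l": fq_p,
                "foldT_l129q": fl_t, "foldP_l129q": fl_p}

    def test_identical_outputs_are_strong_both(self):
        assert classify_behavior(self._row(8, 8, 8, 8)) == "strong_both"

    def test_boundary_equal_plc_dead_trio(self):
        row = self._row(fq_t=5, fq_p=5, fl_t=1.0, fl_p=5)
        assert classify_behavior(row) == "strongERK_weakYAP"

    def test_weak_both_and_mirror(self):
        assert classify_behavior(self._row(10, 10, 1.1, 1.1)) == "weak_both"
        assert classify_behavior(self._row(10, 10, 10, 1.1)) == \
            "weakERK_strongYAP"

    def test_undefined_when_q209l_inactive(self):
        assert classify_behavior(self._row(0.9, 5, 2, 2)) == "undefined"

    def test_theta_controls_the_boundary(self):
        row = self._row(11, 11, 5, 11)  # L129Q TRIO excess = 0.4 x Q209L's
        assert classify_behavior(row, theta=0.25) == "strong_both"
        assert classify_behavior(row, theta=0.5) == "strongERK_weakYAP"


class TestMatchPredicate:
    def test_equal_outputs_do_not_match(self):
        row = {"aT_q209l": 1.0, "aP_q209l": 1.0,
               "aT_l129q": 1.0, "aP_l129q": 1.0}
        assert match_experiment(row) is False

    def test_inclusive_plc_strict_trio_boundary(self):
        row = {"aT_q209l": 1.0, "aP_q209l": 1.0,
               "aT_l129q": 0.99, "aP_l129q": 1.0}
        assert match_experiment(row) is True

    def test_flipping_trio_inequality_flips_the_flag(self, smoke_batch):
        ok = smoke_batch.ok_rows()
        flipped = ok.rename(columns={"aT_q209l": "aT_l129q",
                                     "aT_l129q": "aT_q209l"})
        ties = ok["aT_q209l"] == ok["aT_l129q"]
        orig = match_experiment(ok)
        swap = match_experiment(flipped)
        both_plc_ok = ok["aP_l129q"] >= ok["aP_q209l"]
        # wherever PLC qualifies and TRIO is not tied, exactly one orientation
        # of the TRIO inequality matches
        sel = both_plc_ok & ~ties
        assert ((orig ^ swap) | ~sel).all()


class TestDiscrimination:
    def test_planted_shift_is_detected_and_ranked_first(self, spec):
        rng = np.random.default_rng(0)
        n = 300
        table = pd.DataFrame(
            {r.name: r.from_unit(rng.random(n)) for r in spec.ranges})
        flag = rng.random(n) < 0.5
        # plant: matched rows draw k_hyd2 one decade lower
        table.loc[flag, "k_hyd2"] /= 10.0
        table["match"] = flag
        table["aT_q209l"] = 1.0  # mark every row as converged
        batch = sample_parameter_sets(spec, "uniform", n=n, seed=0)
        batch.table = table
        batch.evaluated = True
        ks = ks_discriminate(batch)
        assert ks.iloc[0]["parameter"] == "k_hyd2"
        assert ks.iloc[0]["p"] < 1e-3

    def test_shuffled_labels_show_no_signal(self, spec):
        rng = np.random.default_rng(1)
        n = 400
        table = pd.DataFrame(
            {r.name: r.from_unit(rng.random(n)) for r in spec.ranges})
        table["match"] = rng.random(n) < 0.5
        table["aT_q209l"] = 1.0
        batch = sample_parameter_sets(spec, "uniform", n=n, seed=1)
        batch.table = table
        batch.evaluated = True
        ks = ks_discriminate(batch)
        assert (ks["D"] < 0.15).all()

    def test_roc_on_perfect_and_independent_classifiers(self, spec):
        rng = np.random.default_rng(2)
        n = 500
        table = pd.DataFrame(
            {r.name: r.from_unit(rng.random(n)) for r in spec.ranges})
        flag = table["effector_bias"] > np.median(table["effector_bias"])
        table["match"] = flag
        table["aT_q209l"] = 1.0
        batch = sample_parameter_sets(spec, "uniform", n=n, seed=2)
        batch.table = table
        batch.evaluated = True
        assert roc_classifier(batch, "effector_bias", "ge").auc == \
            pytest.approx(1.0, abs=1e-9)
        assert roc_classifier(batch, "RGS_tot", "ge").auc == \
            pytest.approx(0.5, abs=0.1)

    def test_roc_recovers_a_planted_threshold(self, spec):
        rng = np.random.default_rng(3)
        n = 600
        table = pd.DataFrame(
            {r.name: r.from_unit(rng.random(n)) for r in spec.ranges})
        thr = 2.0
        noise = rng.random(n) < 0.05
        table["match"] = (table["k_hyd2"] < thr) ^ noise
        table["aT_q209l"] = 1.0
        batch = sample_parameter_sets(spec, "uniform", n=n, seed=3)
        batch.table = table
        batch.evaluated = True
        roc = roc_classifier(batch, "k_hyd2", "lt")
        youden = roc.tpr - roc.fpr
        best = roc.thresholds[np.argmax(youden)]
        assert 0.5 * thr < best < 2.0 * thr
        assert ks_discriminate(batch).iloc[0]["parameter"] == "k_hyd2"

    def _noisy_batch(self, spec, seed=4, n=300):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {r.name: r.from_unit(rng.random(n)) for r in spec.ranges})
        table["match"] = (table["k_hyd2"] < 2.0) ^ (rng.random(n) < 0.2)
        table["aT_q209l"] = 1.0
        batch = sample_parameter_sets(spec, "uniform", n=n, seed=seed)
        batch.table = table
        batch.evaluated = True
        return batch

    def test_auc_invariant_under_monotone_transform(self, spec):
        batch = self._noisy_batch(spec)
        auc = roc_classifier(batch, "k_hyd2", "lt").auc
        batch.table = batch.table.copy()
        batch.table["k_hyd2"] = batch.table["k_hyd2"] ** 2
        assert roc_classifier(batch, "k_hyd2", "lt").auc == \
            pytest.approx(auc, abs=1e-12)

    def test_auc_agrees_with_sklearn(self, spec):
        batch = self._noisy_batch(spec, seed=5)
        y = batch.ok_rows()["match"].astype(bool).to_numpy()
        mine = roc_classifier(batch, "effector_bias", "ge").auc
        ref = roc_auc_score(y, batch.ok_rows()["effector_bias"])
        assert mine == pytest.approx(ref, abs=1e-9)


class TestKhyd2Sweep:
    def test_l129q_plc_nonincreasing_and_match_region(self, revised_params):
        ratios = np.array([1.0, 5.0, 20.0, 60.0, 200.0, 770.0])
        df = khyd2_sweep(revised_params, ratios)
        l = df[df["genotype"] == "CYSLTR2:L129Q:het"].sort_values("ratio")
        assert np.all(np.diff(l["active_plc"]) <= 1e-10)
        assert set(df["genotype"]) == {"WT", "GNAQ:Q209L:het",
                                       "CYSLTR2:L129Q:het"}
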