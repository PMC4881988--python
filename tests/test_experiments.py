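"""Protocol registry, Monte Carlo aggregation, and experiment invariants."""

import numpy as np
import pytest

from hepsim import (
    PROTOCOLS,
    run_binding_falsification,
    run_enzyme_timecourse,
    run_isl_multidrug,
    run_isl_single_drug,
    run_protocol,
)
from hepsim.experiments import TrialResult, monte_carlo
from hepsim.io import write_results


class TestRegistry:
    def test_all_eight_validating_protocols_shipped(self):
        expected = {
            "ishc-dose-response", "ishc-timecourse",
            "isl-apap-control", "isl-apap-lps",
            "isl-ant-control", "isl-ant-lps",
            "isl-czn-control", "isl-czn-lps",
            "isl-multidrug-control", "isl-multidrug-lps",
        }
        assert expected == set(PROTOCOLS)

    def test_unknown_protocol_rejected(self, doc):
        with pytest.raises(KeyError):
            run_protocol("isl-caffeine-control", doc, 0)


class TestMonteCarlo:
    def test_single_trial_mean_equals_value(self):
        def run_one(seed):
            return TrialResult(seed=seed, series={"x": [(0, 5.0), (1, 7.0)]})

        agg = monte_carlo(run_one, 3, 1)
        np.testing.assert_array_equal(agg.mean["x"], [5.0, 7.0])
        np.testing.assert_array_equal(agg.sd["x"], [0.0, 0.0])

    def test_trial_seeds_are_base_plus_index(self):
        seen = []

        def run_one(seed):
            seen.append(seed)
            return TrialResult(seed=seed, series={"x": [(0, 1.0)]})

        monte_carlo(run_one, 10, 4)
        assert seen == [10, 11, 12, 13]

    def test_rerun_reproduces_means(self, doc):
        a = run_enzyme_timecourse(doc, base_seed=5, trials=2, scale=20.0)
        b = run_enzyme_timecourse(doc, base_seed=5, trials=2, scale=20.0)
        np.testing.assert_array_equal(a.mean["enzyme"], b.mean["enzyme"])


class TestDeterministicOutputs:
    def test_identical_seed_byte_identical_trial_csvs(self, doc, tmp_path):
        p1, p2 = tmp_path / "a", tmp_path / "b"
        for p in (p1, p2):
            agg = run_enzyme_timecourse(doc, base_seed=7, trials=2, scale=20.0)
            write_results(agg, p, "tc")
        assert (p1 / "tc_trials.csv").read_bytes() == (
            p2 / "tc_trials.csv"
        ).read_bytes()


class TestArmDesign:
    def test_control_shortcut_preserves_enzyme_state(self, doc):
        # bypassing the pretreatment phase cannot matter without lps:
        # enzyme totals at drug injection equal the basal totals either way
        short = run_isl_single_drug(
            doc, "czn", "control", base_seed=31, trials=2, scale=50.0,
            lobule="compact",
        )
        aged = run_isl_single_drug(
            doc, "czn", "control", base_seed=31, trials=2, scale=50.0,
            lobule="compact", pre_cycles=400,
        )
        for agg in (short, aged):
            for tr in agg.trials:
                assert tr.scalars["enzyme_total_czn"] > 0
        # same seeds build identical lobules: basal totals agree exactly
        assert [t.scalars["enzyme_total_czn"] for t in short.trials] == [
            t.scalars["enzyme_total_czn"] for t in aged.trials
        ]

    def test_multidrug_dose_arithmetic(self, doc):
        agg = run_isl_multidrug(
            doc, "control", base_seed=41, trials=1, scale=50.0,
            lobule="compact", pre_cycles=0,
        )
        doses = agg.trials[0].meta["doses"]
        assert doses == {d: 62_500 // 50 for d in ("apap", "ant", "czn")}

    def test_lps_arm_czn_vd_adjusted_dose(self, doc):
        agg = run_isl_single_drug(
            doc, "czn", "lps", base_seed=43, trials=1, scale=50.0,
            lobule="compact", pre_cycles=50,
        )
        dose = agg.trials[0].meta["doses"]["czn"]
        assert dose == round(125_000 / 50 / 1.69)

    def test_drug_measurements_follow_schedule(self, doc):
        agg = run_isl_single_drug(
            doc, "czn", "control", base_seed=45, trials=1, scale=50.0,
            lobule="compact",
        )
        cycles = [c for c, _ in agg.trials[0].series["body_czn"]]
        assert cycles[0] == 0 and cycles[-1] == 7200
        assert len(cycles) == 13  # dose point + 12 scheduled measurements


class TestFalsificationHarness:
    def test_produces_metabolism_events(self):
        n = run_binding_falsification("stepwise", False, seed=1,
                                      n_cells=10, n_cycles=30)
        assert n > 0

    def test_depletion_halves_variable_mode_production(self):
        full = run_binding_falsification("variable", False, seed=2,
                                         n_cells=20, n_cycles=60)
        depleted = run_binding_falsification("variable", True, seed=2,
                                             n_cells=20, n_cycles=60)
        assert depleted < full
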