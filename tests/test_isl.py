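"""Liver-analog structure: zonation, transfer, transit, conservation."""

import math

import numpy as np
import pytest

from hepsim import RngStream, apply_vd_change
from hepsim.config import isl_settings_from
from hepsim.isl import LiverModel


@pytest.fixture()
def compact(doc):
    return isl_settings_from(doc.isl, "compact")


def make_model(settings, seed=0):
    return LiverModel(settings, RngStream(seed))


class TestGraph:
    def test_layered_dag_every_node_wired(self, doc):
        s = isl_settings_from(doc.isl, "full")
        m = make_model(s, 3)
        # every non-last-layer segment has >=1 successor; every non-first
        # layer segment has >=1 predecessor (PV- and CV-reachability)
        for seg in range(m.n_seg):
            if seg not in m.last_layer:
                assert m.successors[seg]
                assert all(m.layer_of[c] == m.layer_of[seg] + 1
                           for c in m.successors[seg])
            if seg not in m.first_layer:
                assert m.predecessors[seg]

    def test_zonated_pmetabolize_by_layer(self, compact):
        m = make_model(compact)
        d = m.d_of_seg[m.seg_of_hep]
        np.testing.assert_allclose(m.pmet[:, m.drug_index["czn"]],
                                   0.35 + d * 0.6)
        assert m.pmet[d == 0.0].min() == pytest.approx(0.35)
        assert m.pmet[d == 1.0].max() == pytest.approx(0.95)
        assert m.pmet[d == 0.5, 0].mean() == pytest.approx(0.65)


class TestVdChange:
    def test_dose_and_factor_division(self):
        dose, srf = apply_vd_change(125_000, 0.52, 1.69)
        assert dose == 73_964
        assert srf == pytest.approx(0.52 / 1.69)

    def test_invalid_fold_change_rejected(self):
        with pytest.raises(ValueError):
            apply_vd_change(1000, 1.0, 0.0)


class TestBodyTransfer:
    def test_transfer_rate_matches_binomial_mean(self, compact):
        m = make_model(compact, 5)
        t = m.type_index["apap"]
        n, p = 125_000, compact.sampleRatio * 1.0  # apap factor 1.0
        m.body[t] = n
        m._body_exchange()
        moved = n - m.body[t]
        sd = math.sqrt(n * p * (1 - p))
        assert abs(moved - n * p) < 4 * sd
        assert m.core[:, 0, t].sum() == moved  # enters first-layer cores

    def test_absent_factor_means_no_transfer(self, compact):
        m = make_model(compact, 5)
        t = m.type_index["czn-metabolite"]
        m.body[t] = 50_000
        for _ in range(20):
            m._body_exchange()
        assert m.body[t] == 50_000

    def test_relative_factors_scale_transfer(self, compact):
        m = make_model(compact, 8)
        ta, tn = m.type_index["apap"], m.type_index["ant"]
        m.body[ta] = m.body[tn] = 200_000
        moved_a = moved_n = 0
        for _ in range(30):
            before_a, before_n = m.body[ta], m.body[tn]
            m._body_exchange()
            moved_a += before_a - m.body[ta]
            moved_n += before_n - m.body[tn]
            m.core[:] = 0  # keep the lobule from returning anything
        assert moved_n / moved_a == pytest.approx(0.26, rel=0.2)


class TestCoreTransit:
    def test_deterministic_transit_without_radial_exits(self, doc):
        s = isl_settings_from(doc.isl, "compact")
        s.forwardBias, s.lateralBias = 0.4, 0.6  # kernel remainder = 0
        m = make_model(s, 2)
        t = m.type_index["czn-metabolite"]  # inert tracer
        m.core[0, 0, t] = 1
        m.dosed[t] = 1
        expected = math.ceil(s.layers * s.core_length / s.flowRate)
        for cycle in range(1, expected + 2):
            m.run_cycle()
            if m.cv_stage[t] or m.body[t]:
                break
        assert cycle == expected
        m.run_cycle()
        assert m.body[t] == 1  # returns to body the next cycle

    def test_bound_solutes_are_stationary(self, compact):
        m = make_model(compact, 3)
        d = m.drug_index["czn"]
        m.hep_rb[0, d, 3] = 5
        m._move_solutes()
        assert m.hep_rb[0, d, 3] == 5


class TestConservation:
    def test_drug_partition_is_exact(self, compact):
        m = make_model(compact, 11)
        m.dose_body("czn", 2000)
        m.run(400)
        acct = m.accounting("czn")
        total = (acct["body"] + acct["cv_stage"] + acct["lobule"]
                 + acct["bile"] + acct["degraded"] + acct["metabolized"])
        assert total == acct["dosed"]

    def test_metabolite_partition_is_exact(self, compact):
        m = make_model(compact, 11)
        m.dose_body("czn", 2000)
        m.run(400)
        acct = m.accounting("czn-metabolite")
        total = (acct["body"] + acct["cv_stage"] + acct["lobule"]
                 + acct["bile"] + acct["degraded"])
        assert total == acct["created"]
        assert acct["created"] == m.accounting("czn")["metabolized"]

    def test_inert_transport_conserves_count(self, compact):
        m = make_model(compact, 12)
        t = m.type_index["czn-metabolite"]
        m.core[:, 0, t] = 40
        m.dosed[t] = m.n_seg * 40
        m.run(1000)
        acct = m.accounting("czn-metabolite")
        assert (acct["body"] + acct["cv_stage"] + acct["lobule"]
                + acct["bile"]) == m.n_seg * 40


class TestEnzymes:
    def test_control_enzyme_totals_constant(self, compact):
        m = make_model(compact, 6)
        start = {e: m.measure(e) for e in m.enzyme_pools}
        m.dose_body("czn", 5000)
        m.run(1500)
        assert {e: m.measure(e) for e in m.enzyme_pools} == start

    def test_lps_suppresses_enzymes(self, compact):
        totals = []
        for seed in (21, 22):
            m = make_model(compact, seed)
            start = m.measure("czn-enzyme")
            m.dose_body("lps", 12_500)
            m.run(7200)
            totals.append((start, m.measure("czn-enzyme")))
        assert all(after < before for before, after in totals)

    def test_enzyme_ceiling_never_exceeded(self, compact):
        m = make_model(compact, 6)
        m.dose_body("lps", 2000)
        m.run(2000)
        for pool in m.enzyme_pools.values():
            assert (pool.total <= pool.initial).all()
            assert (pool.total >= 0).all()

    def test_measure_unknown_selector_rejected(self, compact):
        with pytest.raises(KeyError):
            make_model(compact).measure("mystery")
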