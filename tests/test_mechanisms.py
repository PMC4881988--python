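"""The five cell mechanisms: probabilities, handlers, and queue timing."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepsim import (
    BindingConfig,
    DownRegConfig,
    InflammationConfig,
    RngStream,
    SimulationClock,
    binding_probability,
    cytokine_probability,
)
from hepsim.components import Solute
from hepsim.engine import EventQueue
from hepsim.mechanisms import (
    binding_handler,
    degradation_handler,
    downregulation_handler,
    fire_due_removals,
    inflammation_handler,
    metabolism_handler,
)

from test_components import make_registry


def hepatocyte(registry, rng=None, lo=4, hi=8):
    from hepsim import create_cell

    return create_cell("hepatocyte", registry, lo, hi, rng or RngStream(0))


class TestBindingProbability:
    def test_stepwise_is_pbind_or_zero(self):
        assert binding_probability("stepwise", 0.25, 3, 4, 8) == 0.25
        assert binding_probability("stepwise", 0.25, 4, 4, 8) == 0.0

    def test_variable_reconstructed_formula(self):
        # pBind * ((total - bound)/initial)^exponent
        assert binding_probability("variable", 0.25, 2, 4, 8, 1.0) == pytest.approx(
            0.0625
        )

    def test_variable_zero_at_full_occupancy(self):
        assert binding_probability("variable", 0.25, 4, 4, 8, 2.0) == 0.0

    def test_variable_equals_pbind_at_basal_unbound(self):
        assert binding_probability("variable", 0.25, 0, 8, 8, 1.7) == 0.25

    def test_inconsistent_state_rejected(self):
        with pytest.raises(ValueError):
            binding_probability("stepwise", 0.25, 5, 4, 8)

    @given(
        bound=st.integers(0, 10),
        extra=st.integers(0, 10),
        initial=st.integers(1, 20),
        exponent=st.floats(0.1, 4.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_variable_mode_is_a_probability_and_decreasing_in_bound(
        self, bound, extra, initial, exponent
    ):
        total = bound + extra
        if total > initial:
            total = initial
            bound = min(bound, total)
        p = binding_probability("variable", 0.25, bound, total, initial, exponent)
        assert 0.0 <= p <= 0.25
        if bound + 1 <= total:
            p_more = binding_probability(
                "variable", 0.25, bound + 1, total, initial, exponent
            )
            assert p_more <= p


class TestCytokineProbability:
    def test_zero_at_or_below_threshold(self):
        cfg = InflammationConfig(inflammatoryThreshold=3, cytokineExponent=3.0)
        assert cytokine_probability(3, cfg) == 0.0
        assert cytokine_probability(0, cfg) == 0.0

    def test_ratio_form_value(self):
        cfg = InflammationConfig(inflammatoryThreshold=3, cytokineExponent=3.0)
        assert cytokine_probability(6, cfg) == pytest.approx(1 - math.exp(-1.0))

    @given(n=st.integers(0, 200))
    @settings(deadline=None, max_examples=50)
    def test_monotone_nondecreasing_and_bounded(self, n):
        cfg = InflammationConfig(inflammatoryThreshold=1, cytokineExponent=3.0)
        p, q = cytokine_probability(n, cfg), cytokine_probability(n + 1, cfg)
        assert 0.0 <= p <= q <= 1.0  # saturates to 1.0 in float at large n

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            InflammationConfig(cytokineExponent=0.0)


class TestBindingHandler:
    def make(self, n_solutes, lo, hi, mode="stepwise", pBind=1.0):
        reg = make_registry()
        cell = hepatocyte(reg, lo=lo, hi=hi)
        for _ in range(n_solutes):
            cell.add_solute(Solute(reg.solute("apap")))
        cfg = BindingConfig(mode=mode, pBind=pBind, bindCycles=10)
        return cell, cfg, reg

    def test_enzyme_exhaustion_caps_binds(self):
        cell, cfg, reg = self.make(3, 2, 2)
        queue, clock = EventQueue(), SimulationClock(cycle_limit=100)
        n = binding_handler(cell, cfg, reg, RngStream(1), queue, clock)
        assert n == 2
        assert sum(1 for s in cell.solutes if s.bound) == 2
        assert len(queue) == 2

    def test_nonbindable_solute_never_binds(self):
        reg = make_registry()
        cell = hepatocyte(reg)
        cell.add_solute(Solute(reg.solute("lps")))
        queue, clock = EventQueue(), SimulationClock(cycle_limit=100)
        cfg = BindingConfig(mode="stepwise", pBind=1.0)
        assert binding_handler(cell, cfg, reg, RngStream(1), queue, clock) == 0

    def test_release_scheduled_bindcycles_later(self):
        from hepsim.mechanisms import release_bound_pair

        cell, cfg, reg = self.make(1, 4, 4)
        queue, clock = EventQueue(), SimulationClock(cycle_limit=100)
        binding_handler(cell, cfg, reg, RngStream(1), queue, clock)
        assert queue.peek_cycle() == clock.cycle + 10
        assert list(queue.pop_due(9)) == []
        (ev,) = list(queue.pop_due(10))
        release_bound_pair(*ev.payload)
        assert all(not s.bound for s in cell.solutes)
        assert len(cell.unbound_enzymes("apap-enzyme")) == 4

    def test_bound_solute_not_degraded(self):
        reg = make_registry()
        cell = hepatocyte(reg)
        cyt = Solute(reg.solute("cytokine"))
        cyt.bound_to = cell.enzymes["apap-enzyme"][0]  # force-bound marker
        cell.add_solute(cyt)
        rng = RngStream(1)
        assert degradation_handler(cell, rng) == 0
        assert len(cell.solutes) == 1


class TestMetabolismHandler:
    def test_certain_metabolism_converts_and_frees_enzyme(self):
        reg = make_registry()
        cell = hepatocyte(reg)
        cell.d = 1.0  # pMetabolize interpolates to 0.95; force to 1 via type
        st_apap = reg.solute("apap")
        drug = Solute(st_apap)
        enz = cell.enzymes["apap-enzyme"][0]
        drug.bound_to, enz.bound_solute = enz, drug
        cell.add_solute(drug)
        # drive to certainty by repeating until converted (p=0.95 at d=1)
        rng = RngStream(3)
        for _ in range(100):
            if metabolism_handler(cell, reg, rng):
                break
        assert cell.solute_count("apap") == 0
        assert cell.solute_count("apap-metabolite") == 1
        assert not enz.bound

    def test_nonspecific_never_metabolizes(self):
        from hepsim import create_cell

        reg = make_registry()
        ec = create_cell("endothelial-cell", reg, 4, 4, RngStream(0))
        drug = Solute(reg.solute("apap"))
        enz = ec.enzymes["nonspecific"][0]
        drug.bound_to, enz.bound_solute = enz, drug
        ec.add_solute(drug)
        rng = RngStream(3)
        assert metabolism_handler(ec, reg, rng) == 0  # not a hepatocyte
        hep = hepatocyte(reg)
        hep.enzymes["nonspecific"] = [enz]  # hypothetical mixed cell
        hep.add_solute(drug)
        assert metabolism_handler(hep, reg, rng) == 0  # metabolic=False
        assert drug.bound


class TestInflammationHandler:
    def setup_cell(self, n_lps, n_cyt, reg):
        from hepsim import create_cell

        kc = create_cell("kupffer-cell", reg, 4, 8, RngStream(0))
        for _ in range(n_lps):
            kc.add_solute(Solute(reg.solute("lps")))
        for _ in range(n_cyt):
            kc.add_solute(Solute(reg.solute("cytokine")))
        return kc

    def test_no_stimulus_no_cytokine(self):
        reg = make_registry()
        kc = self.setup_cell(0, 0, reg)
        cfg = InflammationConfig(inflammatoryThreshold=1, cytokineExponent=3.0)
        assert not inflammation_handler(kc, cfg, reg, RngStream(1))

    def test_cytokine_ceiling_blocks_production(self):
        reg = make_registry()
        cfg = InflammationConfig(
            inflammatoryThreshold=1, cytokineThreshold=2, cytokineExponent=3.0
        )
        kc = self.setup_cell(100, 3, reg)  # above ceiling
        rng = RngStream(1)
        assert all(
            not inflammation_handler(kc, cfg, reg, rng) for _ in range(50)
        )

    def test_production_rate_matches_formula(self):
        reg = make_registry()
        cfg = InflammationConfig(
            inflammatoryThreshold=1, cytokineThreshold=10**9, cytokineExponent=3.0
        )
        rng = RngStream(9)
        n_cells, n_lps = 4000, 5
        produced = 0
        for _ in range(n_cells):
            kc = self.setup_cell(n_lps, 0, reg)
            produced += inflammation_handler(kc, cfg, reg, rng)
        p = 1 - math.exp(-(n_lps - 1) / 3.0)
        se = math.sqrt(p * (1 - p) / n_cells)
        assert abs(produced / n_cells - p) < 3 * se


class TestDownRegulation:
    def make_cell(self, n_cyt, reg):
        cell = hepatocyte(reg, lo=6, hi=6)
        for _ in range(n_cyt):
            cell.add_solute(Solute(reg.solute("cytokine")))
        return cell

    def test_at_most_one_removal_scheduled_per_cycle(self):
        reg = make_registry()
        cell = self.make_cell(3, reg)
        cfg = DownRegConfig(delay=30, pReplenish=0.0, pRemove=1.0)
        clock = SimulationClock(cycle_limit=1000)
        clock.cycle = 5
        et = reg.enzyme("apap-enzyme")
        downregulation_handler(cell, et, cfg, RngStream(1), clock)
        state = cell.downreg["apap-enzyme"]
        assert state.pending_removals == [35]  # exactly one, fires at t+delay

    def test_tail_append_rule_enumerated_timeline(self):
        reg = make_registry()
        cell = self.make_cell(5, reg)
        cfg = DownRegConfig(delay=600, pReplenish=0.0, pRemove=1.0)
        clock = SimulationClock(cycle_limit=10**6)
        et = reg.enzyme("apap-enzyme")
        clock.cycle = 100
        downregulation_handler(cell, et, cfg, RngStream(1), clock)
        clock.cycle = 101
        downregulation_handler(cell, et, cfg, RngStream(1), clock)
        # second removal queues behind the first: (100+600)+600
        assert cell.downreg["apap-enzyme"].pending_removals == [700, 1300]
        clock.cycle = 700
        assert fire_due_removals(cell, clock) == 1
        assert cell.enzyme_count("apap-enzyme") == 5
        clock.cycle = 1300
        assert fire_due_removals(cell, clock) == 1
        assert cell.enzyme_count("apap-enzyme") == 4

    def test_no_replenish_at_basal_level(self):
        reg = make_registry()
        cell = self.make_cell(0, reg)
        cfg = DownRegConfig(delay=30, pReplenish=1.0, pRemove=1.0)
        clock = SimulationClock(cycle_limit=1000)
        et = reg.enzyme("apap-enzyme")
        for _ in range(20):
            downregulation_handler(cell, et, cfg, RngStream(1), clock)
        assert cell.enzyme_count("apap-enzyme") == 6  # never exceeds basal

    def test_replenish_requires_no_cytokine_and_empty_queue(self):
        reg = make_registry()
        cfg = DownRegConfig(delay=30, pReplenish=1.0, pRemove=1.0)
        clock = SimulationClock(cycle_limit=1000)
        et = reg.enzyme("apap-enzyme")
        cell = self.make_cell(0, reg)
        cell.enzymes["apap-enzyme"].pop()  # below basal
        cell.downreg["apap-enzyme"].pending_removals.append(500)  # queue busy
        downregulation_handler(cell, et, cfg, RngStream(1), clock)
        assert cell.enzyme_count("apap-enzyme") == 5
        cell.downreg["apap-enzyme"].pending_removals.clear()
        downregulation_handler(cell, et, cfg, RngStream(1), clock)
        assert cell.enzyme_count("apap-enzyme") == 6

    def test_bound_enzymes_defer_removal_until_release(self):
        reg = make_registry()
        cell = self.make_cell(0, reg)
        drug = Solute(reg.solute("apap"))
        for enz in cell.enzymes["apap-enzyme"]:
            enz.bound_solute = drug  # everything bound
        cell.downreg["apap-enzyme"].pending_removals.append(10)
        clock = SimulationClock(cycle_limit=1000)
        clock.cycle = 10
        assert fire_due_removals(cell, clock) == 0
        assert cell.downreg["apap-enzyme"].deferred == 1
        assert cell.enzyme_count("apap-enzyme") == 6
        # release one: the deferred removal executes immediately
        from hepsim.mechanisms import _execute_deferred_removals

        cell.enzymes["apap-enzyme"][0].bound_solute = None
        _execute_deferred_removals(cell)
        assert cell.enzyme_count("apap-enzyme") == 5
        assert cell.downreg["apap-enzyme"].deferred == 0


class TestDegradation:
    def test_types_without_pdegrade_never_degraded(self):
        reg = make_registry()
        cell = hepatocyte(reg)
        for _ in range(50):
            cell.add_solute(Solute(reg.solute("apap-metabolite")))
        rng = RngStream(1)
        for _ in range(100):
            degradation_handler(cell, rng)
        assert cell.solute_count("apap-metabolite") == 50

    def test_survivors_match_binomial_closed_form_small(self):
        reg = make_registry()
        cell = hepatocyte(reg)
        n0, p, t = 2000, 0.002, 500
        for _ in range(n0):
            cell.add_solute(Solute(reg.solute("cytokine")))
        rng = RngStream(7)
        for _ in range(t):
            degradation_handler(cell, rng)
        q = (1 - p) ** t
        expect = n0 * q
        se = math.sqrt(n0 * q * (1 - q))
        assert abs(cell.solute_count("cytokine") - expect) < 3 * se
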