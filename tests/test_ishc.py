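"""Culture-analog structure, dosing, movement, and measurement."""

import math

import numpy as np
import pytest

from hepsim import ISHCSettings, RngStream
from hepsim.config import ishc_settings_from
from hepsim.ishc import KC, CultureModel


@pytest.fixture()
def dr_settings(doc):
    return ishc_settings_from(doc.ishc_dose_response)


@pytest.fixture()
def tc_settings(doc):
    return ishc_settings_from(doc.ishc_timecourse)


class TestBuild:
    def test_kupffer_only_build_fills_625_points(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(0))
        assert model.cell_kind.size == 625
        assert (model.cell_kind == KC).all()

    def test_hepatocyte_only_build(self, tc_settings):
        model = CultureModel(tc_settings, RngStream(0))
        assert len(model.hep_points) == 625

    def test_partial_density_binomial_count(self, dr_settings):
        dr_settings.kcDensity, dr_settings.hepDensity = 0.5, 0.0
        total = sum(
            len(CultureModel(dr_settings, RngStream(s)).kc_points)
            for s in range(10)
        )
        expect, sd = 10 * 625 * 0.5, math.sqrt(10 * 625 * 0.25)
        assert abs(total - expect) < 3 * sd

    def test_densities_summing_above_one_rejected(self, doc):
        sec = doc.ishc_dose_response
        with pytest.raises(ValueError):
            ISHCSettings(
                registry=CultureModel(
                    ishc_settings_from(sec), RngStream(0)
                ).registry,
                kcDensity=0.7,
                hepDensity=0.6,
            )


class TestDosing:
    def test_zero_dose_is_noop(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(0))
        model.dose("lps", 0)
        assert model.total_solutes() == 0

    def test_dose_conserved_at_time_zero(self, tc_settings):
        model = CultureModel(tc_settings, RngStream(0))
        model.dose("cytokine", 2000)
        assert model.measure("cytokine") == 2000

    def test_negative_dose_rejected(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(0))
        with pytest.raises(ValueError):
            model.dose("lps", -5)

    def test_uniform_allocation_over_both_grids(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(3))
        model.dose("lps", 700_000)
        t = model.type_index["lps"]
        per_point = model.counts[..., t].astype(float)
        assert per_point.sum() == 700_000
        # expected load 560 per point over 1250 points
        assert abs(per_point.mean() - 560.0) < 1e-9
        assert per_point.std() < 4 * math.sqrt(560)


class TestMovement:
    def test_movement_conserves_solutes_without_degradation(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(1))
        model.dose("lps", 5000)  # lps defines no pDegrade in the culture
        model.run(200)
        assert model.measure("lps") == 5000

    def test_vertical_asymmetry_favors_media(self, tc_settings):
        # cytokine: pExitCell=0.2 >> pExitMedia=0.02 -> most ends in media
        model = CultureModel(tc_settings, RngStream(1))
        t = model.type_index["cytokine"]
        model.counts[0, :, :, t] = 4  # all start in cell space
        model.settings.downreg = model.settings.downreg  # no-op
        for _ in range(100):
            model._move_pooled()
        in_media = model.counts[1, :, :, t].sum()
        in_cell = model.counts[0, :, :, t].sum()
        assert in_media > 4 * in_cell

    def test_no_flux_when_exit_probabilities_zero(self, dr_settings):
        reg = dr_settings.registry
        model = CultureModel(dr_settings, RngStream(1))
        # metaphorical tracer: reuse cytokine but zero its exits
        object.__setattr__(reg.solutes["cytokine"], "pExitCell", 0.0)
        object.__setattr__(reg.solutes["cytokine"], "pExitMedia", 0.0)
        t = model.type_index["cytokine"]
        model.counts[0, :, :, t] = 2
        for _ in range(50):
            model._move_pooled()
        assert model.counts[1, :, :, t].sum() == 0
        assert model.counts[0, :, :, t].sum() == 2 * 625


class TestMeasure:
    def test_enzyme_count_range_hepatocyte_build(self, tc_settings):
        model = CultureModel(tc_settings, RngStream(2))
        total = model.measure("enzyme")
        assert 2500 <= total <= 5000  # 625 cells x [4, 8]

    def test_unknown_selector_rejected(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(0))
        with pytest.raises(KeyError):
            model.measure("mystery")

    def test_no_dose_no_cytokines(self, dr_settings):
        model = CultureModel(dr_settings, RngStream(4))
        model.run(100)
        assert model.measure("cytokine") == 0


class TestDeterminism:
    def test_fixed_seed_replays_identically(self, dr_settings, doc):
        def run(seed):
            model = CultureModel(
                ishc_settings_from(doc.ishc_dose_response), RngStream(seed)
            )
            model.dose("lps", 7000)
            model.run(300)
            return model.measure("cytokine"), model.counts.copy()

        c1, arr1 = run(99)
        c2, arr2 = run(99)
        assert c1 == c2
        np.testing.assert_array_equal(arr1, arr2)
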