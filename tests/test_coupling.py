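"""Intramyocardial pressure: CEP + VE, territory weighting, ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroflow.coupling import IMPCalculator, branch_imp, cep, ve
from coroflow.micro import LAYER_RADIAL_POSITION
from coroflow.network import TerritoryTable, WallSpec
from coroflow.units import KPA_TO_MMHG


class TestCEP:
    def test_subendocardial_value_at_peak_lv_pressure(self):
        assert float(cep(5.0 / 6.0, 110.0, 0.0)) == pytest.approx(91.67, abs=0.01)

    def test_midwall_is_arithmetic_mean(self):
        assert float(cep(0.5, 83.0, 17.0)) == pytest.approx((83.0 + 17.0) / 2.0)

    @given(p=st.floats(-20.0, 200.0), r=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None)
    def test_degenerate_gradient(self, p, r):
        assert float(cep(r, p, p)) == pytest.approx(p, rel=1e-12, abs=1e-9)

    def test_limits_toward_endo_and_epi(self):
        assert float(cep(1.0, 110.0, 5.0)) == pytest.approx(110.0)
        assert float(cep(0.0, 110.0, 5.0)) == pytest.approx(5.0)


class TestVE:
    def test_zero_stress_zero_ve(self):
        assert float(ve(0.0)) == 0.0

    def test_unit_conversion_kpa_to_mmhg(self):
        # γ=0.06 with σ_f = 10 kPa: VE = 0.6 kPa expressed in mmHg
        assert float(ve(10.0, 0.06)) == pytest.approx(0.6 * KPA_TO_MMHG)

    def test_linear_in_gamma(self):
        assert float(ve(42.0, 0.12)) == pytest.approx(2.0 * float(ve(42.0, 0.06)))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            ve(10.0, -0.01)


class TestBranchIMP:
    def test_uniform_imp_passes_through(self):
        imp = np.full((4, 3), 37.0)
        out = branch_imp(imp, np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(out, 37.0)

    def test_equal_volume_mean(self):
        imp = np.array([[40.0] * 3, [80.0] * 3])
        out = branch_imp(imp, np.array([1.0, 1.0]))
        assert np.allclose(out, 60.0)

    def test_empty_territory_rejected(self):
        with pytest.raises(Exception):
            branch_imp(np.zeros((2, 3)), np.zeros(2))


def reference_calculator(gamma=0.06):
    walls = [WallSpec("LV", 108.0, 12), WallSpec("S", 45.0, 5),
             WallSpec("RV", 39.0, 1)]
    return IMPCalculator(walls, TerritoryTable.reference(), gamma=gamma)


class TestIMPCalculator:
    def test_territory_weights_normalized(self):
        calc = reference_calculator()
        assert np.allclose(calc.weights.sum(axis=1), 1.0)

    @given(p_lv=st.floats(10.0, 180.0), p_rv=st.floats(0.0, 40.0),
           p_peri=st.floats(-2.0, 8.0), sig=st.floats(0.0, 80.0))
    @settings(max_examples=40, deadline=None)
    def test_transmural_ordering(self, p_lv, p_rv, p_peri, sig):
        """Subendo ≥ mid ≥ subepi whenever cavity pressure ≥ outer pressure."""
        if p_lv < p_peri or p_rv < p_peri or p_lv < p_rv:
            return
        state = reference_calculator().compute(
            p_lv, p_rv, p_peri, {"LV": sig, "S": sig, "RV": sig})
        imp = state.imp
        assert np.all(imp[:, 2] >= imp[:, 1] - 1e-9)
        assert np.all(imp[:, 1] >= imp[:, 0] - 1e-9)

    def test_rca_imp_between_pure_rv_and_pure_lv(self):
        calc = reference_calculator()
        state = calc.compute(110.0, 25.0, 2.0, {"LV": 40.0, "S": 40.0, "RV": 40.0})
        r = LAYER_RADIAL_POSITION
        ve_term = 0.06 * 40.0 * KPA_TO_MMHG
        pure_rv = cep(r, 25.0, 2.0) + ve_term
        pure_lv = cep(r, 110.0, 2.0) + ve_term
        rca = state.imp[2]  # branch order LCx, LAD, RCA
        assert np.all(rca > pure_rv) and np.all(rca < pure_lv)

    def test_rca_peak_imp_below_left_branches(self, reference_beat):
        rec = reference_beat
        assert rec["imp_rca_subendo"].max() < rec["imp_lad_subendo"].max()
        assert rec["imp_rca_subendo"].max() < rec["imp_lcx_subendo"].max()

    def test_gamma_zero_reduces_to_pure_cep(self):
        state = reference_calculator(gamma=0.0).compute(
            110.0, 25.0, 2.0, {"LV": 50.0, "S": 50.0, "RV": 50.0})
        assert np.allclose(state.ve, 0.0)
        assert np.allclose(state.imp, state.cep)

    def test_zero_cavity_pressures_reduce_to_pure_ve(self):
        state = reference_calculator().compute(
            0.0, 0.0, 0.0, {"LV": 50.0, "S": 50.0, "RV": 50.0})
        assert np.allclose(state.cep, 0.0)
        assert np.allclose(state.imp, state.ve)

    def test_imp_is_exact_sum_of_components(self):
        state = reference_calculator().compute(
            120.0, 30.0, 1.0, {"LV": 60.0, "S": 55.0, "RV": 30.0})
        assert np.allclose(state.imp, state.cep + state.ve)

    def test_reference_peak_ve_near_twenty_percent_of_peak_lv_pressure(
            self, reference_beat):
        rec = reference_beat
        ratio = rec["ve_lad"].max() / rec["p_lv"].max()
        assert 0.17 <= ratio <= 0.23
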