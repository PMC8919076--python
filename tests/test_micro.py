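"""Collapsible-tube law, volume-dependent resistances, bed circuit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroflow._tubelaw import dp_dA, transmural_pressure_area
from coroflow.config import MicroConfig
from coroflow.fixtures import make_driven_bed_fixture
from coroflow.micro import (Compartment, build_bed, layer_target_flows,
                            micro_derivatives, reference_resistances,
                            resistance, transmural_pressure)


class TestTransmuralPressureLaw:
    def test_reference_anchor(self):
        # A = A0, A_w = A0: elastic factor 1, collapse term inactive
        comp = Compartment(v0=1.0, p0=45.0, k=12.0, aw_ratio=1.0)
        assert float(transmural_pressure(comp.a0, comp)) == pytest.approx(45.0)

    def test_progressively_negative_toward_collapse(self):
        comp = Compartment(v0=1.0, p0=45.0, k=12.0, aw_ratio=1.0)
        assert float(transmural_pressure(0.01 * comp.a0, comp)) < 0.0
        # and monotone decreasing as the lumen empties
        a = np.array([0.3, 0.1, 0.05, 0.01]) * comp.a0
        p = transmural_pressure(a, comp)
        assert np.all(np.diff(p) < 0.0)

    def test_analytic_derivative_matches_finite_difference(self):
        p0, a0, aw, k = 45.0, 1.0, 0.4, 12.0
        for a in (0.4, 0.8, 1.0, 1.6):
            h = 1e-6 * a
            fd = (transmural_pressure_area(a + h, p0, a0, aw, k)
                  - transmural_pressure_area(a - h, p0, a0, aw, k)) / (2 * h)
            assert float(dp_dA(a, p0, a0, aw, k)) == pytest.approx(
                float(fd), rel=1e-6)

    def test_area_guard(self):
        comp = Compartment(v0=1.0, p0=45.0, k=12.0, aw_ratio=1.0)
        with pytest.raises(ValueError):
            transmural_pressure(-0.1, comp)


class TestResistanceLaw:
    @pytest.mark.parametrize("v_over_v0, factor", [(1.0, 1.0), (0.5, 4.0), (2.0, 0.25)])
    def test_poiseuille_volume_scaling(self, v_over_v0, factor):
        assert float(resistance(v_over_v0 * 2.0, 10.0, 2.0)) == pytest.approx(
            10.0 * factor, rel=1e-9)


class TestReferenceResistances:
    def test_total_from_perfusion_pressure_and_flow(self):
        q_layer = layer_target_flows(83.0 / 60.0, 1.11)
        res = reference_resistances(q_layer, 94.0, 4.0)
        assert res["R_total"] == pytest.approx(90.0 / (83.0 / 60.0), rel=1e-12)
        assert res["R_total"] == pytest.approx(65.06, abs=0.01)
        assert res["R_a"] == pytest.approx(0.28 * res["R_total"], rel=1e-12)
        assert res["R_v"] == pytest.approx(0.07 * res["R_total"], rel=1e-12)

    def test_intramyocardial_split_60_30_10(self):
        q_layer = layer_target_flows(83.0 / 60.0, 1.11)
        res = reference_resistances(q_layer, 94.0, 4.0)
        r_im = 0.65 * res["R_total"]
        # per-layer series path scales inversely with the layer's flow share,
        # and R1 takes 60% of it
        for li in range(3):
            r_layer = r_im * q_layer.sum() / q_layer[li]
            assert res["R1"][li] == pytest.approx(0.60 * r_layer, rel=1e-12)
            assert res["Rm"][li] == pytest.approx(0.30 * r_layer, rel=1e-12)
            assert res["R2"][li] == pytest.approx(0.10 * r_layer, rel=1e-12)
        # the three layer paths in parallel reproduce the intramyocardial block
        r_parallel = 1.0 / sum(1.0 / (res["R1"] + res["Rm"] + res["R2"]))
        assert r_parallel == pytest.approx(r_im, rel=1e-12)

    def test_degenerate_single_layer(self):
        res = reference_resistances(np.array([83.0 / 60.0]), 94.0, 4.0)
        layer_total = res["R1"][0] + res["Rm"][0] + res["R2"][0]
        assert layer_total == pytest.approx(0.65 * res["R_total"], rel=1e-12)

    def test_layer_targets_honor_endo_epi_ratio(self):
        q = layer_target_flows(83.0, 1.11)
        assert q.sum() == pytest.approx(83.0)
        assert q[2] / q[0] == pytest.approx(1.11)

    def test_nonpositive_perfusion_pressure_rejected(self):
        with pytest.raises(ValueError):
            reference_resistances(layer_target_flows(1.0, 1.11), 4.0, 9.0)


def uniform_pressure_bed():
    """Bed whose compartments all sit at one pressure at reference volume."""
    micro = MicroConfig(p0_epi_art=50.0, p0_epi_ven=50.0, p0_arteriolar=50.0,
                        p0_venular=50.0)
    bed = build_bed("LAD", 83.0, 1.11, 94.0, 4.0, micro)
    return bed


class TestBedCircuit:
    def test_equilibrium_all_pressures_equal(self):
        bed = uniform_pressure_bed()
        state = bed.reference_state()
        rates = micro_derivatives(bed, state, 50.0, 50.0, np.zeros(3), 2.0, 1.0)
        for key in ("q_in", "q_out", "q_a", "q_v"):
            assert rates[key] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rates["q1"], 0.0, atol=1e-12)
        assert np.allclose(rates["dv1"], 0.0, atol=1e-12)

    def test_bed_mass_conservation_kirchhoff(self, rng):
        micro = MicroConfig()
        bed = build_bed("LAD", 83.0, 1.11, 91.0, 4.0, micro)
        state = bed.reference_state()
        state["v1"] = state["v1"] * rng.uniform(0.6, 1.3, 3)
        state["v2"] = state["v2"] * rng.uniform(0.6, 1.3, 3)
        rates = micro_derivatives(bed, state, 95.0, 3.0,
                                  np.array([10.0, 40.0, 80.0]), 2.0, 1.0)
        total_dv = (rates["dv_ea"] + rates["dv_ev"]
                    + rates["dv1"].sum() + rates["dv2"].sum())
        assert total_dv == pytest.approx(rates["q_in"] - rates["q_out"], abs=1e-12)

    def test_subendo_imp_step_causes_retrograde_arteriolar_flow(self):
        micro = MicroConfig()
        bed = build_bed("LAD", 83.0, 1.11, 91.0, 4.0, micro)
        state = bed.reference_state()
        base = micro_derivatives(bed, state, 91.0, 4.0, np.zeros(3), 2.0, 1.0)
        squeezed = micro_derivatives(bed, state, 91.0, 4.0,
                                     np.array([0.0, 0.0, 90.0]), 2.0, 1.0)
        # instantaneous subendocardial arteriolar flow reverses ...
        assert squeezed["q1"][2] < 0.0
        # ... while the subepicardial response is far smaller than the
        # subendocardial one
        d_epi = abs(squeezed["q1"][0] - base["q1"][0])
        d_endo = abs(squeezed["q1"][2] - base["q1"][2])
        assert d_epi < 0.3 * d_endo

    def test_quasistatic_imp_sweep_compresses_arterioles(self):
        """Rising tissue pressure squeezes the arteriolar compartments.

        A small (<3%) initial wiggle is tolerated: at low IMP the reduced
        flow raises intravascular pressure slightly before compression
        dominates.
        """
        volumes = []
        for p_im in (0.0, 40.0, 80.0, 120.0):
            rig = make_driven_bed_fixture(0.0)
            rig.imp = lambda t, v=p_im: np.full(3, v)  # constant layer IMP
            rig.run_to_steady(max_beats=25, tol=1e-4)
            volumes.append(rig.state["v1"].sum())
        assert all(b < 1.03 * a for a, b in zip(volumes, volumes[1:]))
        assert volumes[-1] < 0.5 * volumes[0]


class TestDrivenBedFixture:
    def test_zero_peak_settles_to_steady_poiseuille(self):
        rig = make_driven_bed_fixture(0.0)
        rec = rig.run_to_steady(max_beats=40, tol=1e-5)
        q1 = rec["q1"]
        # steady: no within-beat variation; flows near the construction targets
        assert np.ptp(q1, axis=0).max() < 1e-4
        assert np.allclose(q1.mean(axis=0), rig.bed.q0_layer, rtol=0.10)

    def test_systolic_squeeze_gives_early_systolic_retrograde_subendo(self):
        rig = make_driven_bed_fixture(110.0)
        rec = rig.run_to_steady(max_beats=30, tol=1e-4)
        n = rec["q1"].shape[0]
        early_systole = rec["q1"][: int(0.25 * n), 2]
        assert early_systole.min() < 0.0

    def test_doubling_hr_halves_fixture_period(self):
        a = make_driven_bed_fixture(110.0, hr=60.0)
        b = make_driven_bed_fixture(110.0, hr=120.0)
        assert b.p_lv.period == pytest.approx(a.p_lv.period / 2.0)

    @given(gamma=st.floats(0.0, 0.12))
    @settings(max_examples=5, deadline=None)
    def test_fixture_parameters_validated(self, gamma):
        rig = make_driven_bed_fixture(80.0, gamma=max(gamma, 1e-6))
        assert rig.bed.q0 > 0
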