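"""One-fiber wall mechanics, TriSeg junction equilibrium, pericardium."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroflow.mechanics import (FiberMaterial, Pericardium, StrainBoundsError,
                                TriSegSolver, TriSegWall, WallGeometry,
                                activation_time_course, segment_stress,
                                sphere_transmural_pressure,
                                wall_pressure_from_stress)


def one_fiber_sphere_oracle(sigma_f, v_wall, v_cav):
    """Independent closed form: p = (σ_f/3)·ln(1 + V_wall/V_cavity)."""
    return sigma_f / 3.0 * math.log(1.0 + v_wall / v_cav)


class TestFiberLaw:
    def test_zero_stress_at_reference(self):
        total, active, passive = segment_stress(0.0, 0.0, FiberMaterial())
        assert total == 0.0 and active == 0.0 and passive == 0.0

    def test_passive_only_when_inactive(self):
        mat = FiberMaterial()
        total, active, passive = segment_stress(0.12, 0.0, mat)
        assert active == 0.0
        assert passive > 0.0
        assert total == passive

    @given(eps=st.floats(-0.3, 0.5), act=st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_stress_decomposition_and_sign(self, eps, act):
        total, active, passive = segment_stress(eps, act, FiberMaterial())
        assert passive >= 0.0
        assert active >= 0.0
        assert total == pytest.approx(active + passive)

    def test_monotone_in_strain_at_fixed_activation(self):
        mat = FiberMaterial()
        eps = np.linspace(-0.05, 0.3, 40)
        total, _, _ = segment_stress(eps, 0.6, mat)
        assert np.all(np.diff(total) >= -1e-12)

    def test_force_velocity_reduces_shortening_stress(self):
        mat = FiberMaterial(v_max=2.0)
        slow, _, _ = segment_stress(0.1, 1.0, mat, strain_rate=0.0)
        fast, _, _ = segment_stress(0.1, 1.0, mat, strain_rate=-1.5)  # shortening
        assert fast < slow

    def test_strain_guard(self):
        with pytest.raises(StrainBoundsError):
            segment_stress(1.5, 0.5, FiberMaterial())

    def test_activation_bounds(self):
        with pytest.raises(ValueError):
            segment_stress(0.1, 1.2, FiberMaterial())


class TestLaplace:
    def test_spherical_closed_form_oracle(self):
        geom = WallGeometry("sphere", v_wall=108.0, v_cavity=120.0)
        for sigma in (1.0, 17.3, 55.0):
            assert wall_pressure_from_stress(sigma, geom) == pytest.approx(
                one_fiber_sphere_oracle(sigma, 108.0, 120.0), rel=1e-10)

    def test_zero_stress_zero_pressure(self):
        geom = WallGeometry("sphere", v_wall=108.0, v_cavity=120.0)
        assert wall_pressure_from_stress(0.0, geom) == 0.0

    def test_linear_in_stress_at_frozen_geometry(self):
        cap = WallGeometry("cap", v_wall=45.0, am=50.0, cm=0.2)
        p1 = wall_pressure_from_stress(10.0, cap)
        p2 = wall_pressure_from_stress(20.0, cap)
        assert p2 == pytest.approx(2.0 * p1, rel=1e-12)


def symmetric_solver():
    mat = FiberMaterial(sigma_act=60.0, sigma_pas=0.2, k_pas=14.0)
    return TriSegSolver({
        "LV": TriSegWall("LV", 80.0, 90.0, mat),
        "S": TriSegWall("S", 40.0, 40.0, mat),
        "RV": TriSegWall("RV", 80.0, 90.0, mat),
    }, dt=0.0)


class TestTriSeg:
    def test_symmetric_loading_gives_flat_septum(self):
        sol = symmetric_solver().solve(110.0, 110.0, {"LV": 0.4, "S": 0.4, "RV": 0.4})
        # equal cavities and identical free walls: the septal cap stays flat
        assert abs(sol.cm["S"]) < 5e-3
        assert sol.p_lv_trans == pytest.approx(sol.p_rv_trans, rel=1e-4, abs=1e-4)

    def test_junction_residual_below_tolerance(self):
        solver = symmetric_solver()
        sol = solver.solve(120.0, 90.0, {"LV": 0.7, "S": 0.7, "RV": 0.7})
        assert sol.residual < solver.tol

    def test_septum_bulges_toward_rv_when_lv_pressure_higher(self, reference_beat):
        # systolic samples of the converged reference beat: trans-septal
        # pressure is leftward-positive, so septal curvature points to the RV
        rec = reference_beat
        systole = rec.window_mask(rec.events["aortic_open"],
                                  rec.events["aortic_close"])
        assert np.all(rec["p_lv"][systole] > rec["p_rv"][systole])
        assert np.all(rec["septal_curvature"][systole] > 0.0)


class TestPericardium:
    def test_reference_anchor(self):
        peri = Pericardium(v_ref=700.0)
        assert peri.pressure(700.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_and_convex(self):
        peri = Pericardium(v_ref=700.0)
        v = np.linspace(600.0, 900.0, 31)
        p = np.array([peri.pressure(x) for x in v])
        assert np.all(np.diff(p) > 0.0)
        # secant slopes increase with volume: convexity by direct evaluation
        slopes = np.diff(p) / np.diff(v)
        assert np.all(np.diff(slopes) > 0.0)


class TestActivation:
    def test_periodic_and_bounded(self):
        vals = [activation_time_course(t, 0.8, 0.1, 0.35) for t in
                np.arange(0.0, 1.6, 0.01)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert activation_time_course(0.3, 0.8, 0.1, 0.35) == pytest.approx(
            activation_time_course(1.1, 0.8, 0.1, 0.35), abs=1e-12)

    def test_plateau_reaches_full_activation(self):
        assert activation_time_course(0.25, 0.8, 0.1, 0.35) == 1.0

    def test_zero_outside_twitch(self):
        assert activation_time_course(0.6, 0.8, 0.1, 0.35) == 0.0
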