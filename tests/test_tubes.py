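"""Non-linear tube law, wave impedance and pulse propagation."""

import numpy as np
import pytest

from coroflow.tubes import TubeChain, TubeParams, junction_reflection
from coroflow.units import wave_impedance_mmhg_s_ml


def aorta_like(n_k=8.0):
    return TubeParams("test_tube", length=40.0, a_ref=4.0, p_ref=91.0,
                      k=n_k, aw_ratio=0.2)


class TestTubeLaw:
    def test_reference_anchor(self):
        p = aorta_like()
        assert float(p.pressure(p.a_ref)) == pytest.approx(p.p_ref, rel=1e-12)

    def test_pressure_increases_with_area(self):
        p = aorta_like()
        areas = np.linspace(0.7 * p.a_ref, 1.5 * p.a_ref, 30)
        assert np.all(np.diff(p.pressure(areas)) > 0.0)

    def test_impedance_scaling_with_area(self):
        # Z = rho*c/A: halving the area at fixed wave speed doubles Z
        z1 = wave_impedance_mmhg_s_ml(1.0, 5.0)
        z2 = wave_impedance_mmhg_s_ml(0.5, 5.0)
        assert z2 == pytest.approx(2.0 * z1, rel=1e-12)


class TestJunctionReflection:
    def test_matched_junction_is_reflectionless(self):
        assert junction_reflection(1.3, [1.3]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_end_reflects_fully(self):
        assert junction_reflection(1.3, []) == 1.0
        assert junction_reflection(1.3, [np.inf]) == 1.0


class TestTubeChain:
    def test_equilibrium_zero_flow(self):
        chain = TubeChain(aorta_like(), n_segments=8)
        p_eq = float(chain.params.pressure(chain.params.a_ref))
        chain.run(lambda t: p_eq, lambda t: p_eq, t_end=0.3, dt=2e-4)
        assert np.all(np.abs(chain.q) < 1e-6)

    def test_mass_conserved_per_step(self):
        chain = TubeChain(aorta_like(), n_segments=8)
        v0 = chain.v.sum()
        p_eq = float(chain.params.pressure(chain.params.a_ref))
        q_net = 0.0
        dt = 2e-4
        for i in range(500):
            t = i * dt
            p_in = p_eq + 5.0 * np.sin(40.0 * t)
            chain.step(p_in, p_eq, dt)
            q_net += dt * (chain.q[0] - chain.q[-1])
        assert chain.v.sum() - v0 == pytest.approx(q_net, rel=1e-9)

    def test_small_pulse_travels_at_linearized_wave_speed(self):
        params = aorta_like()
        n = 80
        chain = TubeChain(params, n_segments=n)
        p_eq = float(params.pressure(params.a_ref))
        c = params.wave_speed(params.a_ref)  # m/s

        dt = 2.5e-5
        pulse_t0, pulse_w = 0.004, 0.0015

        def p_in(t):
            return p_eq + 0.5 * np.exp(-((t - pulse_t0) / pulse_w) ** 2)

        times, rec = chain.run(p_in, lambda t: p_eq, t_end=0.12, dt=dt)
        # pulse arrival = pressure maximum at near and far interior segments
        i_near, i_far = 4, n - 6
        t_near = times[np.argmax(rec[:, i_near])]
        t_far = times[np.argmax(rec[:, i_far])]
        distance_m = (i_far - i_near) * chain.dx / 100.0
        c_measured = distance_m / (t_far - t_near)
        assert c_measured == pytest.approx(c, rel=0.02)
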