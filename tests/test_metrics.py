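"""Waveform metrics on synthetic beats with analytically known answers."""

import numpy as np
import pytest

from coroflow.metrics import (MetricError, PhaseSegmentation,
                              diameter_change_ed_es, dtvi,
                              mean_transvalvular_gradient, pdsvr,
                              retrograde_fraction)
from coroflow.record import BeatRecord


def synthetic_beat(n=900, dt=0.001, sys_frac=1.0 / 3.0):
    """Beat with plateau velocities: systole in the first third of the cycle."""
    t_open, t_close = 0.0, sys_frac * n * dt
    v = np.empty(n)
    n_sys = int(sys_frac * n)
    v[:n_sys] = 0.1
    v[n_sys:] = 0.25
    rec = BeatRecord(dt=dt, channels={"u": v},
                     events={"aortic_open": t_open, "aortic_close": t_close,
                             "mitral_close": t_open})
    phases = PhaseSegmentation.from_record(rec)
    return rec, phases


class TestPDSVR:
    def test_plateau_ratio(self):
        rec, ph = synthetic_beat()
        assert pdsvr(rec["u"], rec, ph) == pytest.approx(2.5)

    def test_constant_velocity_gives_unity(self):
        rec, ph = synthetic_beat()
        assert pdsvr(np.full(rec.n, 0.2), rec, ph) == pytest.approx(1.0)

    def test_nonpositive_systolic_peak_flagged_undefined(self):
        rec, ph = synthetic_beat()
        u = rec["u"].copy()
        u[ph.systolic_mask(rec)] = -0.05
        assert np.isnan(pdsvr(u, rec, ph))


class TestDTVi:
    def test_equal_plateaus_diastole_twice_as_long(self):
        n = 900
        rec = BeatRecord(dt=0.001, channels={"u": np.full(n, 0.2)},
                         events={"aortic_open": 0.0, "aortic_close": 0.3,
                                 "mitral_close": 0.0})
        ph = PhaseSegmentation.from_record(rec)
        assert dtvi(rec["u"], rec, ph) == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_zero_diastolic_velocity(self):
        rec, ph = synthetic_beat()
        u = rec["u"].copy()
        u[ph.diastolic_mask(rec)] = 0.0
        assert dtvi(u, rec, ph) == 0.0

    def test_retrograde_clipped_from_integrals(self):
        rec, ph = synthetic_beat()
        u = rec["u"].copy()
        u[:50] = 0.0
        baseline = dtvi(u, rec, ph)
        u[:50] = -1.0  # retrograde clips to zero: same integral as zeros
        assert dtvi(u, rec, ph) == pytest.approx(baseline)

    def test_bounded_zero_one(self, rng):
        rec, ph = synthetic_beat()
        u = rng.normal(0.1, 0.2, rec.n)
        val = dtvi(u, rec, ph)
        assert 0.0 <= val <= 1.0


class TestDiameterChange:
    def test_sqrt_volume_convention(self):
        rec, ph = synthetic_beat()
        v = np.full(rec.n, 1.0)
        i_es = int(round(ph.t_es / rec.dt))
        v[i_es] = 0.81  # V_ES = 0.81 V_ED → d change −10%
        assert diameter_change_ed_es(v, rec, ph) == pytest.approx(-10.0)

    def test_constant_volume_zero_change(self):
        rec, ph = synthetic_beat()
        assert diameter_change_ed_es(np.full(rec.n, 0.7), rec, ph) == 0.0


class TestGradientAndPurity:
    def test_mean_gradient_uses_forward_flow_only(self):
        n = 600
        q = np.zeros(n)
        q[:200] = 300.0
        dp = np.full(n, -5.0)
        dp[:200] = 45.0
        rec = BeatRecord(dt=0.001, channels={"q_aortic": q, "dp_av": dp},
                         events={"aortic_open": 0.0, "aortic_close": 0.2})
        assert mean_transvalvular_gradient(rec) == pytest.approx(45.0)

    def test_no_forward_flow_raises(self):
        rec = BeatRecord(dt=0.001,
                         channels={"q_aortic": np.zeros(10),
                                   "dp_av": np.zeros(10)},
                         events={})
        with pytest.raises(MetricError):
            mean_transvalvular_gradient(rec)

    def test_metrics_are_pure(self):
        rec, ph = synthetic_beat()
        assert pdsvr(rec["u"], rec, ph) == pdsvr(rec["u"], rec, ph)
        assert dtvi(rec["u"], rec, ph) == dtvi(rec["u"], rec, ph)

    def test_retrograde_fraction(self):
        u = np.array([1.0] * 8 + [-1.0] * 2)
        assert retrograde_fraction(u) == pytest.approx(0.25)
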