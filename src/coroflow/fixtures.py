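"""Analytic driving waveforms and a standalone driven coronary bed rig.

These fixtures exercise the microcirculation and the cardiac-coronary
coupling without the full heart: a half-sinusoid LV pressure of configurable
peak and systolic fraction, a matched fiber-stress waveform (scaled so that
peak VE is the configured fraction of peak LV pressure), and a coronary bed
with constant arterial/venous boundary pressures driven by the resulting
layer intramyocardial pressures, integrated by the same explicit stepper as
the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import micro as mi
from .config import MicroConfig
from .coupling import cep, ve
from .micro import LAYER_RADIAL_POSITION
from .units import KPA_TO_MMHG


@dataclass
class FixtureWaveform:
    """Half-sinusoid pressure pulse, periodic with the cardiac cycle."""

    peak: float  # mmHg
    period: float  # s
    systolic_frac: float
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.peak < 0 or self.period <= 0 or not 0 < self.systolic_frac < 1:
            raise ValueError("fixture waveform parameters must be positive")

    def __call__(self, t):
        ts = self.systolic_frac * self.period
        tau = np.mod(np.asarray(t, float) - self.onset, self.period)
        return np.where(tau < ts, self.peak * np.sin(np.pi * tau / ts), 0.0)


@dataclass
class DrivenBed:
    """A coronary bed driven by prescribed analytic IMP waveforms.

    Boundary pressures are constant (mean aortic and right-atrial); layer
    IMP = CEP + VE with the analytic LV-pressure and fiber-stress pulses.
    """

    bed: mi.BedParams
    p_lv: FixtureWaveform
    gamma: float
    sigma_peak_kpa: float
    p_in: float  # mmHg
    p_out: float
    z_in: float = 2.0  # mmHg·s/mL
    z_out: float = 1.0
    dt: float = 0.001
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.state:
            self.state = self.bed.reference_state()

    def imp(self, t) -> np.ndarray:
        """Layer IMP (3,) at time t: CEP (P2 = 0) plus VE."""
        plv = float(self.p_lv(t))
        sigma = self.sigma_peak_kpa * (plv / self.p_lv.peak if self.p_lv.peak else 0.0)
        return cep(LAYER_RADIAL_POSITION, plv, 0.0) + ve(sigma, self.gamma)

    def step(self, t: float) -> dict:
        rates = mi.micro_derivatives(
            self.bed, self.state, self.p_in, self.p_out, self.imp(t),
            self.z_in, self.z_out)
        s = self.state
        s["v_ea"] = s["v_ea"] + self.dt * rates["dv_ea"]
        s["v_ev"] = s["v_ev"] + self.dt * rates["dv_ev"]
        s["v1"] = s["v1"] + self.dt * rates["dv1"]
        s["v2"] = s["v2"] + self.dt * rates["dv2"]
        return rates

    def run(self, n_beats: int = 1, record_last: bool = True) -> dict | None:
        n = int(round(self.p_lv.period / self.dt))
        rec: dict[str, list] = {k: [] for k in
                                ("t", "q_in", "q_out", "q1", "q2", "qm",
                                 "v1", "v2", "p_im")}
        for beat in range(n_beats):
            last = beat == n_beats - 1
            for i in range(n):
                t = i * self.dt
                rates = self.step(t)
                if last and record_last:
                    rec["t"].append(t)
                    rec["q_in"].append(rates["q_in"])
                    rec["q_out"].append(rates["q_out"])
                    rec["q1"].append(rates["q1"].copy())
                    rec["q2"].append(rates["q2"].copy())
                    rec["qm"].append(rates["qm"].copy())
                    rec["v1"].append(self.state["v1"].copy())
                    rec["v2"].append(self.state["v2"].copy())
                    rec["p_im"].append(self.imp(t))
        if not record_last:
            return None
        return {k: np.array(v) for k, v in rec.items()}

    def run_to_steady(self, max_beats: int = 40, tol: float = 1e-4) -> dict:
        prev = np.concatenate([np.atleast_1d(self.state[k]).ravel()
                               for k in ("v_ea", "v_ev", "v1", "v2")])
        for _ in range(max_beats):
            self.run(1, record_last=False)
            cur = np.concatenate([np.atleast_1d(self.state[k]).ravel()
                                  for k in ("v_ea", "v_ev", "v1", "v2")])
            if np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-6)) < tol:
                break
            prev = cur
        return self.run(1, record_last=True)


def make_driven_bed_fixture(
    peak_lv_pressure: float,
    hr: float = 71.0,
    systolic_frac: float = 0.41,
    q0_ml_min: float = 83.0,
    endo_epi_ratio: float = 1.11,
    gamma: float = 0.06,
    ve_peak_frac: float = 0.20,
    p_in: float = 91.0,
    p_out: float = 4.0,
    micro_cfg: MicroConfig | None = None,
    branch: str = "LAD",
) -> DrivenBed:
    """Standalone coronary bed rig with analytic IMP driving.

    ``peak_lv_pressure`` = 0 gives steady Poiseuille flow at the reference
    operating point; 110 mmHg reproduces the resting systolic flow
    impediment with early-systolic retrograde subendocardial flow.
    """
    if hr <= 0 or peak_lv_pressure < 0:
        raise ValueError("fixture parameters must be positive")
    micro_cfg = micro_cfg or MicroConfig()
    bed = mi.build_bed(branch, q0_ml_min, endo_epi_ratio, p_in, p_out, micro_cfg)
    period = 60.0 / hr
    wave = FixtureWaveform(peak=peak_lv_pressure, period=period,
                           systolic_frac=systolic_frac)
    # fiber-stress amplitude chosen so that at the nominal γ = 0.06 the peak
    # VE is the configured fraction of peak LV pressure; sweeping γ then
    # varies VE alone while the stress waveform stays fixed
    sigma_peak = (ve_peak_frac * peak_lv_pressure) / (0.06 * KPA_TO_MMHG) \
        if peak_lv_pressure > 0 else 0.0
    return DrivenBed(bed=bed, p_lv=wave, gamma=gamma, sigma_peak_kpa=sigma_peak,
                     p_in=p_in, p_out=p_out)
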