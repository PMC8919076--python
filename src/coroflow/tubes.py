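"""Quasi-1D non-linear elastic tube vessels.

Large systemic, pulmonary and coronary conduit vessels are non-linear
elastic tubes of fixed length and variable cross-sectional area.  Blood is
treated as incompressible and Newtonian; conservation of mass and momentum
in the linearized limit gives pulse waves travelling at

    c = sqrt((A/ρ) · dp/dA)

with characteristic wave impedance Z = ρ·c/A.  In the closed-loop engine a
vessel is a single storage element whose two ends couple to junction nodes
through their instantaneous wave impedance (the pressure a neighbour sees at
an end is the tube pressure plus Z times the flow drawn).  For studying
pulse propagation within a vessel, :class:`TubeChain` discretizes the same
tube into N segments with inter-segment blood inertance, recovering wave
transit at speed c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tubelaw import dp_dA, transmural_pressure_area
from .units import (MMHG_TO_PA, RHO_BLOOD, MU_BLOOD,
                    wave_impedance_mmhg_s_ml, wave_speed_m_s)


class AreaCollapseError(RuntimeError):
    pass


@dataclass
class TubeParams:
    """Geometry and wall properties of one conduit vessel."""

    name: str
    length: float  # cm
    a_ref: float  # cm², lumen area at p_ref
    p_ref: float  # mmHg, transmural reference pressure
    k: float  # stiffness exponent (≈8 arteries, ≈10 veins)
    aw_ratio: float = 0.2  # wall area / reference lumen area

    @property
    def a_wall(self) -> float:
        return self.aw_ratio * self.a_ref

    @property
    def v_ref(self) -> float:
        return self.a_ref * self.length  # mL

    def pressure(self, area):
        """Transmural pressure (mmHg) at lumen area (cm²)."""
        return transmural_pressure_area(area, self.p_ref, self.a_ref, self.a_wall, self.k)

    def slope(self, area):
        return dp_dA(area, self.p_ref, self.a_ref, self.a_wall, self.k)

    def wave_speed(self, area) -> float:
        """Linearized wave speed (m/s) at the given area."""
        return wave_speed_m_s(float(area), float(self.slope(area)))

    def wave_impedance(self, area) -> float:
        """Characteristic impedance Z = ρc/A (mmHg·s/mL); pressure dependent."""
        a = float(area)
        if a <= 0.01 * self.a_ref:
            raise AreaCollapseError(f"vessel {self.name}: area collapsed")
        return wave_impedance_mmhg_s_ml(a, self.wave_speed(a))


def junction_reflection(z_parent: float, z_children: list[float]) -> float:
    """Linear reflection coefficient for a wave arriving through ``z_parent``.

    R = (Z_eff − Z_parent)/(Z_eff + Z_parent) with Z_eff the parallel
    combination of the child impedances; 0 for a matched junction, → +1 for
    a closed end (Z → ∞).
    """
    if not z_children:
        return 1.0
    inv = sum(1.0 / z for z in z_children if np.isfinite(z))
    z_eff = np.inf if inv == 0.0 else 1.0 / inv
    if np.isinf(z_eff):
        return 1.0
    return (z_eff - z_parent) / (z_eff + z_parent)


class TubeChain:
    """A tube discretized into N axial segments for wave-propagation studies.

    State: per-segment volumes (mL) and interface flows (mL/s) with blood
    inertance L = ρ·Δx/A at every interface (half-length at the boundaries).
    Driven by prescribed pressures at both ends; a Poiseuille viscous term
    damps the flow.
    """

    def __init__(self, params: TubeParams, n_segments: int = 1, p_external: float = 0.0):
        self.params = params
        self.n = int(n_segments)
        self.dx = params.length / self.n
        self.p_external = p_external
        self.v = np.full(self.n, params.a_ref * self.dx)  # mL
        self.q = np.zeros(self.n + 1)  # mL/s at interfaces

    # -- helpers -----------------------------------------------------------
    def areas(self) -> np.ndarray:
        a = self.v / self.dx
        if np.any(a <= 0.01 * self.params.a_ref):
            raise AreaCollapseError(f"vessel {self.params.name}: area collapsed")
        return a

    def pressures(self) -> np.ndarray:
        return self.params.pressure(self.areas()) + self.p_external

    def _inertance(self, area: float, dx_cm: float) -> float:
        """Blood inertance ρ·Δx/A in mmHg·s²/mL."""
        l_si = RHO_BLOOD * (dx_cm / 100.0) / (area * 1e-4)  # Pa·s²/m³
        return l_si / (MMHG_TO_PA * 1e6)

    def _visc_resistance(self, area: float, dx_cm: float) -> float:
        """Poiseuille resistance 8πμΔx/A² in mmHg·s/mL."""
        r_si = 8.0 * np.pi * MU_BLOOD * (dx_cm / 100.0) / (area * 1e-4) ** 2
        return r_si / (MMHG_TO_PA * 1e6)

    # -- integration -------------------------------------------------------
    def step(self, p_in: float, p_out: float, dt: float) -> None:
        """One explicit update; conserves mass to round-off per step."""
        a = self.areas()
        p = self.pressures()
        p_faces = np.concatenate(([p_in], p, [p_out]))
        a_faces = np.concatenate(([a[0]], 0.5 * (a[:-1] + a[1:]), [a[-1]]))
        dx_faces = np.concatenate(([self.dx / 2], np.full(self.n - 1, self.dx), [self.dx / 2]))
        for j in range(self.n + 1):
            lj = self._inertance(a_faces[j], dx_faces[j])
            rj = self._visc_resistance(a_faces[j], dx_faces[j])
            dq = (p_faces[j] - p_faces[j + 1] - rj * self.q[j]) / lj
            self.q[j] += dt * dq
        self.v += dt * (self.q[:-1] - self.q[1:])

    def run(self, p_in_fn, p_out_fn, t_end: float, dt: float):
        """Integrate with time-dependent boundary pressures; returns (t, p(x,t))."""
        nt = int(round(t_end / dt))
        times = np.arange(nt) * dt
        rec = np.empty((nt, self.n))
        for i, t in enumerate(times):
            self.step(p_in_fn(t), p_out_fn(t), dt)
            rec[i] = self.pressures()
        return times, rec
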