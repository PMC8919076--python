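"""Closed-loop time integration, beat-to-beat convergence and scenarios.

The full model is a system of volume and flow states advanced explicitly at
a 1 ms time step (RK4 available for step-size studies):

* four cavity volumes (LV, RV, LA, RA) with one-fiber/TriSeg wall mechanics
  and a shared pericardial pressure;
* four valve flows (orifice Bernoulli pressure–flow law with blood
  inertance, diode closure, no regurgitation);
* thirteen conduit-vessel volumes (single-element non-linear tubes whose
  ends couple to junction nodes through their wave impedance);
* three coronary beds × (2 epicardial + 3 layers × 2 compartments) volumes
  driven by the transmurally varying intramyocardial pressure.

Massless junction nodes are solved algebraically each step (pressures are
impedance-weighted averages, so Kirchhoff's current law holds exactly);
peripheral beds and venous inlets are resistive series connections.  Blood
volume is conserved to round-off because every flow leaves one compartment
and enters another.

A homeostatic controller acts between beats, scaling circulating volume
toward the mean-arterial-pressure target and the systemic peripheral
resistance toward the cardiac-output target.  Coronary autoregulation tunes
each layer's reference arteriolar resistance until mean layer flows match
the branch targets and endo-to-epi ratio, after which the stenosis scenario
reuses the tuned bed unchanged (only the aortic orifice area differs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import micro as mi
from ._tubelaw import dp_dA, transmural_pressure_area
from .config import Config
from .coupling import IMPCalculator
from .mechanics import (FiberMaterial, Pericardium, TriSegSolver, TriSegWall,
                        activation_time_course, recoil_stress, segment_stress,
                        sphere_midwall_area, sphere_transmural_pressure)
from .network import BRANCHES, build_reference_network
from .record import BeatRecord
from .units import (KPA_TO_MMHG, bernoulli_coeff_mmhg_s2_ml2,
                    impedance_from_slope, inertance_mmhg_s2_ml, velocity_m_s)

log = logging.getLogger(__name__)

VESSEL_ORDER = [
    "sys_art", "sys_ven", "pulm_art", "pulm_ven",
    "cor_lm", "cor_lcx", "cor_lad", "cor_rca",
    "cor_lcx_vein", "cor_lad_vein", "cor_rca_vein",
    "cor_cs_dist", "cor_cs_prox",
]
VALVE_ORDER = ["mitral", "aortic", "tricuspid", "pulmonary"]
LAYERS = mi.LAYERS


class SimulationError(RuntimeError):
    pass


class ConvergenceError(SimulationError):
    pass


@dataclass
class State:
    """Complete dynamic state (volumes in mL, flows in mL/s)."""

    v_cav: np.ndarray  # (4,) LV, RV, LA, RA
    q_valve: np.ndarray  # (4,) mitral, aortic, tricuspid, pulmonary
    v_tube: np.ndarray  # (13,) in VESSEL_ORDER
    v_ea: np.ndarray  # (3,) per bed in BRANCHES order
    v_ev: np.ndarray
    v1: np.ndarray  # (3, 3) bed × layer arteriolar
    v2: np.ndarray  # (3, 3) venular
    q_bed: np.ndarray  # (3,) coronary bed inlet flows (inertial states)

    def copy(self) -> "State":
        return State(*(getattr(self, f).copy() for f in
                       ("v_cav", "q_valve", "v_tube", "v_ea", "v_ev", "v1", "v2",
                        "q_bed")))

    def vector(self) -> np.ndarray:
        return np.concatenate([
            self.v_cav, self.q_valve, self.v_tube, self.v_ea, self.v_ev,
            self.v1.ravel(), self.v2.ravel(), self.q_bed,
        ])

    def total_blood_volume(self) -> float:
        return float(self.v_cav.sum() + self.v_tube.sum() + self.v_ea.sum()
                     + self.v_ev.sum() + self.v1.sum() + self.v2.sum())

    def axpy(self, a: float, d: "State") -> "State":
        return State(
            self.v_cav + a * d.v_cav, self.q_valve + a * d.q_valve,
            self.v_tube + a * d.v_tube, self.v_ea + a * d.v_ea,
            self.v_ev + a * d.v_ev, self.v1 + a * d.v1, self.v2 + a * d.v2,
            self.q_bed + a * d.q_bed,
        )

    def check_finite(self, t: float) -> None:
        for name in ("v_cav", "q_valve", "v_tube", "v_ea", "v_ev", "v1", "v2",
                     "q_bed"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                idx = int(np.argmax(~np.isfinite(arr).ravel()))
                raise SimulationError(
                    f"non-finite state in {name}[{idx}] at t = {t:.4f} s"
                )


class Simulator:
    """Closed-loop beat-to-beat simulator built from a validated config."""

    def __init__(self, config: Config, initial_state: State | None = None):
        self.config = config
        self.topology = build_reference_network(config)
        g = config.general
        self.dt = config.solver.dt_s
        self.n_steps = int(round(g.period_s / self.dt))
        self.period = self.n_steps * self.dt

        self._build_heart()
        self._build_tubes()
        self._build_beds()
        self._build_valves()

        # systemic / pulmonary peripheral resistances (tuned by homeostasis);
        # the initial systemic value discounts the wave-impedance drop of the
        # arterial and venous conduits at their reference state
        co = g.co_l_min * 1000.0 / 60.0  # mL/s
        from .tubes import TubeParams
        z_est = sum(
            TubeParams(n, v.length_cm, v.a_ref_cm2, v.p_ref_mmhg, v.k,
                       v.aw_ratio).wave_impedance(v.a_ref_cm2)
            for n, v in ((x, config.vessels[x]) for x in ("sys_art", "sys_ven"))
        )
        if config.circulation.r_sys_init is not None:
            self.r_sys = config.circulation.r_sys_init
        else:
            self.r_sys = max(
                (g.map_mmhg - config.micro.p_ra_mean_mmhg) / co - z_est, 0.1)
        self.r_pulm = (config.circulation.p_pulm_art_mean
                       - config.circulation.p_la_mean) / co

        self._homeo_jac: np.ndarray | None = None
        self._last_update: tuple[float, float] | None = None
        self._controller_frozen = False
        self._err_history: list[float] = []
        self.state = initial_state.copy() if initial_state else self._initial_state()
        self.beats_run = 0
        self.last_measure: dict | None = None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def _build_heart(self) -> None:
        cfg = self.config
        m = cfg.mechanics

        def mat(w) -> FiberMaterial:
            return FiberMaterial(
                sigma_act=w.sigma_act_kpa, length_slope=w.length_slope,
                eps_act0=w.eps_act0, sigma_pas=w.sigma_pas_kpa,
                k_pas=w.k_pas, eps_limit=w.eps_limit,
                v_max=w.v_max_strain_rate,
            )

        self.triseg = TriSegSolver({
            "LV": TriSegWall("LV", cfg.walls.lv_wall_volume, m.lv.am_ref_cm2, mat(m.lv)),
            "S": TriSegWall("S", cfg.walls.septal_wall_volume, m.septum.am_ref_cm2,
                            mat(m.septum)),
            "RV": TriSegWall("RV", cfg.walls.rv_wall_volume, m.rv.am_ref_cm2, mat(m.rv)),
        }, dt=self.dt)
        self.atria = {
            "LA": (cfg.walls.la_wall_volume, m.la.am_ref_cm2, mat(m.la)),
            "RA": (cfg.walls.ra_wall_volume, m.ra.am_ref_cm2, mat(m.ra)),
        }
        self.pericardium = Pericardium(
            v_ref=cfg.pericardium.v_ref_ml,
            stiffness=cfg.pericardium.stiffness_mmhg,
            exponent=cfg.pericardium.exponent,
            include_coronary=cfg.pericardium.include_coronary_volume,
        )
        self.imp_calc = IMPCalculator(self.topology.walls, self.topology.territory,
                                      gamma=cfg.micro.gamma)
        # activation timing (fractions of the cycle)
        self.t_atrial_on = m.atrial_onset_frac * self.period
        self.t_atrial_dur = m.atrial_duration_frac * self.period
        self.t_vent_on = m.av_delay_frac * self.period
        self.t_vent_dur = cfg.general.systolic_duration_frac * self.period

    def _build_tubes(self) -> None:
        vs = self.config.vessels
        self.tube_len = np.array([vs[n].length_cm for n in VESSEL_ORDER])
        self.tube_aref = np.array([vs[n].a_ref_cm2 for n in VESSEL_ORDER])
        self.tube_pref = np.array([vs[n].p_ref_mmhg for n in VESSEL_ORDER])
        self.tube_k = np.array([vs[n].k for n in VESSEL_ORDER])
        self.tube_aw = np.array([vs[n].aw_ratio for n in VESSEL_ORDER]) * self.tube_aref
        self.tube_vref = self.tube_aref * self.tube_len
        self.tube_idx = {n: i for i, n in enumerate(VESSEL_ORDER)}
        # coronary vessels sit inside the pericardial sac
        self.tube_in_pericardium = np.array(
            [n.startswith("cor_") for n in VESSEL_ORDER])

    def _build_beds(self) -> None:
        cfg = self.config
        self.beds = [
            mi.build_bed(
                branch,
                cfg.coronary_targets[branch].q0_ml_min,
                cfg.coronary_targets[branch].endo_epi_ratio,
                cfg.general.map_mmhg,
                cfg.micro.p_ra_mean_mmhg,
                cfg.micro,
            )
            for branch in BRANCHES
        ]
        # vectorized parameter arrays (bed × layer)
        self.bed_v0_ea = np.array([b.ea.v0 for b in self.beds])
        self.bed_v0_ev = np.array([b.ev.v0 for b in self.beds])
        self.bed_v0_1 = np.array([[c.v0 for c in b.art] for b in self.beds])
        self.bed_v0_2 = np.array([[c.v0 for c in b.ven] for b in self.beds])
        self.bed_r0_a = np.array([b.ea.r0 for b in self.beds])
        self.bed_r0_v = np.array([b.ev.r0 for b in self.beds])
        self.bed_r0_1 = np.array([b.r0_1 for b in self.beds])
        self.bed_r0_m = np.array([b.r0_m for b in self.beds])
        self.bed_r0_2 = np.array([b.r0_2 for b in self.beds])
        self.bed_q0_layer = np.array([b.q0_layer for b in self.beds])  # mL/s
        m = cfg.micro
        # reference pressures per compartment; the intramyocardial ones are
        # re-anchored at the tuned resting operating state (arrays bed × layer)
        self.bed_p0 = dict(ea=m.p0_epi_art, ev=m.p0_epi_ven,
                           a=np.full((3, 3), m.p0_arteriolar),
                           v=np.full((3, 3), m.p0_venular))
        self.bed_k = dict(ea=m.k_art, ev=m.k_ven, a=m.k_arteriole, v=m.k_venule)
        self.bed_awr = dict(ea=m.aw_epi_art, ev=m.aw_epi_ven, a=m.aw_arteriole,
                            v=m.aw_venule)
        # compartment nominal length 1 cm: A0 (cm²) = V0 (mL) numerically
        self.bed_artery = [self.tube_idx[f"cor_{b.lower()}"] for b in BRANCHES]
        self.bed_vein = [self.tube_idx[f"cor_{b.lower()}_vein"] for b in BRANCHES]
        # blood inertance of the feeding artery column (smooths the bed
        # inlet flow on the ~50 ms scale)
        self.bed_inertance = np.array([
            inertance_mmhg_s2_ml(cfg.vessels[f"cor_{b.lower()}"].length_cm,
                                 cfg.vessels[f"cor_{b.lower()}"].a_ref_cm2)
            for b in BRANCHES
        ])

    def _build_valves(self) -> None:
        v = self.config.valves
        specs = [v.mitral, v.aortic, v.tricuspid, v.pulmonary]
        self.valve_area = np.array([s.area_cm2 for s in specs])
        self.valve_B = bernoulli_coeff_mmhg_s2_ml2(self.valve_area)
        self.valve_L = inertance_mmhg_s2_ml(
            np.array([s.l_eff_cm for s in specs]), self.valve_area)
        self.valve_Rlam = 1e-3  # mmHg·s/mL, laminar damping

    def _initial_state(self) -> State:
        v_tube = self.tube_vref.copy()
        v_tube[self.tube_idx["sys_ven"]] +=             self.config.circulation.venous_volume_offset_ml
        return State(
            v_cav=np.array([130.0, 130.0, 60.0, 60.0]),
            q_valve=np.zeros(4),
            v_tube=v_tube,
            v_ea=self.bed_v0_ea.copy(),
            v_ev=self.bed_v0_ev.copy(),
            v1=self.bed_v0_1.copy(),
            v2=self.bed_v0_2.copy(),
            q_bed=np.zeros(3),
        )

    # ------------------------------------------------------------------
    # physics: one evaluation of all pressures, flows and state derivatives
    # ------------------------------------------------------------------
    def _tube_pressures(self, v_tube: np.ndarray, p_peri: float):
        a = np.maximum(v_tube, 0.02 * self.tube_vref) / self.tube_len
        p = transmural_pressure_area(a, self.tube_pref, self.tube_aref,
                                     self.tube_aw, self.tube_k)
        p = p + np.where(self.tube_in_pericardium, p_peri, 0.0)
        slope = np.maximum(dp_dA(a, self.tube_pref, self.tube_aref,
                                 self.tube_aw, self.tube_k), 1e-8)
        z = impedance_from_slope(a, slope)
        return a, p, z

    def _tube_rpois_half(self, a: np.ndarray) -> np.ndarray:
        """Poiseuille resistance (mmHg·s/mL) of half of each vessel."""
        from .units import MMHG_TO_PA, MU_BLOOD
        r_si = 8.0 * np.pi * MU_BLOOD * (self.tube_len / 200.0) / (a * 1e-4) ** 2
        return r_si / (MMHG_TO_PA * 1e6)

    def _bed_compartment(self, v, v0, which):
        """Pressure and (for epicardial compartments) impedance arrays."""
        v_eff = mi.soft_floor(v, 0.01 * v0)
        a0 = v0  # length 1 cm
        aw = self.bed_awr[which] * a0
        p = transmural_pressure_area(v_eff, self.bed_p0[which], a0, aw,
                                     self.bed_k[which])
        return v_eff, p

    def derivatives(self, state: State, tau: float) -> tuple[State, dict]:
        """Time derivatives and instantaneous diagnostics at beat time tau."""
        cfg = self.config
        # geometric guard: wall mechanics evaluated at a small positive floor
        # (state volumes themselves evolve only through flows)
        v_lv, v_rv, v_la, v_ra = np.maximum(state.v_cav, 0.5)

        mcfg = cfg.mechanics
        act_v = activation_time_course(tau, self.period, self.t_vent_on,
                                       self.t_vent_dur,
                                       rise_frac=mcfg.twitch_rise_frac,
                                       decay_frac=mcfg.twitch_decay_frac)
        act_a = activation_time_course(tau, self.period, self.t_atrial_on,
                                       self.t_atrial_dur)

        # --- heart walls -------------------------------------------------
        tri = self.triseg.solve(v_lv, v_rv, {"LV": act_v, "S": act_v, "RV": act_v})
        sigma = dict(tri.sigma_f)

        atr_p_trans = {}
        for name, (vw, am_ref, mat) in self.atria.items():
            v = v_la if name == "LA" else v_ra
            am = sphere_midwall_area(v, vw)
            eps = 0.5 * math.log(am / am_ref)
            sig, _, _ = segment_stress(eps, act_a, mat)
            sigma[name] = float(sig)
            atr_p_trans[name] = sphere_transmural_pressure(
                float(sig) + recoil_stress(eps), vw, v)

        # --- pericardium -------------------------------------------------
        wall_vol = (cfg.walls.lv_wall_volume + cfg.walls.septal_wall_volume
                    + cfg.walls.rv_wall_volume + cfg.walls.la_wall_volume
                    + cfg.walls.ra_wall_volume)
        v_peri = state.v_cav.sum() + wall_vol
        if self.pericardium.include_coronary:
            v_peri += (state.v_tube[self.tube_in_pericardium].sum()
                       + state.v_ea.sum() + state.v_ev.sum())
        p_peri = self.pericardium.pressure(v_peri)

        p_lv = p_peri + tri.p_lv_trans * KPA_TO_MMHG
        p_rv = p_peri + tri.p_rv_trans * KPA_TO_MMHG
        p_la = p_peri + atr_p_trans["LA"] * KPA_TO_MMHG
        p_ra = p_peri + atr_p_trans["RA"] * KPA_TO_MMHG

        # --- conduit vessels ---------------------------------------------
        a_t, p_t, z_t = self._tube_pressures(state.v_tube, p_peri)
        # end-coupling resistance of a conduit: the Poiseuille resistance of
        # half the vessel plus a damping fraction of the characteristic
        # impedance (a single storage element transmits mean flow with only
        # its viscous loss; the Z fraction damps junction transients)
        zc = self._tube_rpois_half(a_t) +             self.config.solver.tube_coupling_z_frac * z_t
        ix = self.tube_idx

        # --- coronary beds: pressures and impedances ---------------------
        v_ea_eff, p_ea_tm = self._bed_compartment(state.v_ea, self.bed_v0_ea, "ea")
        v_ev_eff, p_ev_tm = self._bed_compartment(state.v_ev, self.bed_v0_ev, "ev")
        imp_state = self.imp_calc.compute(p_lv, p_rv, p_peri, {
            "LV": sigma["LV"], "S": sigma["S"], "RV": sigma["RV"]})
        p_im = imp_state.imp  # (3 beds, 3 layers)

        v1_eff, p1_tm = self._bed_compartment(state.v1, self.bed_v0_1, "a")
        v2_eff, p2_tm = self._bed_compartment(state.v2, self.bed_v0_2, "v")
        p_ea = p_ea_tm + p_peri
        p_ev = p_ev_tm + p_peri
        p1 = p1_tm + p_im
        p2 = p2_tm + p_im

        slope_ea = np.maximum(dp_dA(v_ea_eff, self.bed_p0["ea"], self.bed_v0_ea,
                                    self.bed_awr["ea"] * self.bed_v0_ea,
                                    self.bed_k["ea"]), 1e-8)
        slope_ev = np.maximum(dp_dA(v_ev_eff, self.bed_p0["ev"], self.bed_v0_ev,
                                    self.bed_awr["ev"] * self.bed_v0_ev,
                                    self.bed_k["ev"]), 1e-8)
        z_a_bed = impedance_from_slope(v_ea_eff, slope_ea)
        z_v_bed = impedance_from_slope(v_ev_eff, slope_ev)

        # --- valves and junction nodes -----------------------------------
        q_mv, q_av, q_tv, q_pv = state.q_valve

        i_sa, i_sv = ix["sys_art"], ix["sys_ven"]
        i_pa, i_pv = ix["pulm_art"], ix["pulm_ven"]
        i_lm, i_lcx, i_lad, i_rca = (ix["cor_lm"], ix["cor_lcx"], ix["cor_lad"],
                                     ix["cor_rca"])
        i_lcxv, i_ladv, i_rcav = (ix["cor_lcx_vein"], ix["cor_lad_vein"],
                                  ix["cor_rca_vein"])
        i_csd, i_csp = ix["cor_cs_dist"], ix["cor_cs_prox"]

        # aortic root: three tube mouths + aortic valve inflow
        g_ao = 1.0 / zc[i_sa] + 1.0 / zc[i_lm] + 1.0 / zc[i_rca]
        p_ao = (p_t[i_sa] / zc[i_sa] + p_t[i_lm] / zc[i_lm]
                + p_t[i_rca] / zc[i_rca] + q_av) / g_ao
        q_sa_in = (p_ao - p_t[i_sa]) / zc[i_sa]
        q_lm_in = (p_ao - p_t[i_lm]) / zc[i_lm]
        q_rca_in = (p_ao - p_t[i_rca]) / zc[i_rca]

        # pulmonary root: single tube mouth + pulmonary valve inflow
        p_par = p_t[i_pa] + zc[i_pa] * q_pv
        q_pa_in = q_pv

        # left main bifurcation
        g_bif = 1.0 / zc[i_lm] + 1.0 / zc[i_lcx] + 1.0 / zc[i_lad]
        p_bif = (p_t[i_lm] / zc[i_lm] + p_t[i_lcx] / zc[i_lcx]
                 + p_t[i_lad] / zc[i_lad]) / g_bif
        q_lm_out = (p_t[i_lm] - p_bif) / zc[i_lm]
        q_lcx_in = (p_bif - p_t[i_lcx]) / zc[i_lcx]
        q_lad_in = (p_bif - p_t[i_lad]) / zc[i_lad]

        # peripheral beds (series: tube end – resistance – tube end)
        q_sys = (p_t[i_sa] - p_t[i_sv]) / (zc[i_sa] + self.r_sys + zc[i_sv])
        q_pulm = (p_t[i_pa] - p_t[i_pv]) / (zc[i_pa] + self.r_pulm + zc[i_pv])

        # venous inlets into the atria
        r_in = cfg.circulation.venous_inlet_resistance
        q_sv_ra = (p_t[i_sv] - p_ra) / (zc[i_sv] + r_in)
        q_pv_la = (p_t[i_pv] - p_la) / (zc[i_pv] + r_in)
        q_cs_ra = (p_t[i_csp] - p_ra) / (zc[i_csp]
                                         + cfg.circulation.cs_inlet_resistance)

        # coronary bed inflow (inertial flow source across Z_a) and outflow
        art_idx = np.array(self.bed_artery)
        vein_idx = np.array(self.bed_vein)
        q_bed_in = state.q_bed
        dq_bed = (p_t[art_idx] - p_ea
                  - q_bed_in * (zc[art_idx] + z_a_bed)) / self.bed_inertance
        q_bed_out = (p_ev - p_t[vein_idx]) / (z_v_bed + zc[vein_idx])

        # coronary sinus junctions
        g_csl = 1.0 / zc[i_ladv] + 1.0 / zc[i_lcxv] + 1.0 / zc[i_csd]
        p_csl = (p_t[i_ladv] / zc[i_ladv] + p_t[i_lcxv] / zc[i_lcxv]
                 + p_t[i_csd] / zc[i_csd]) / g_csl
        q_ladv_out = (p_t[i_ladv] - p_csl) / zc[i_ladv]
        q_lcxv_out = (p_t[i_lcxv] - p_csl) / zc[i_lcxv]
        q_csd_in = (p_csl - p_t[i_csd]) / zc[i_csd]

        g_csr = 1.0 / zc[i_csd] + 1.0 / zc[i_rcav] + 1.0 / zc[i_csp]
        p_csr = (p_t[i_csd] / zc[i_csd] + p_t[i_rcav] / zc[i_rcav]
                 + p_t[i_csp] / zc[i_csp]) / g_csr
        q_csd_out = (p_t[i_csd] - p_csr) / zc[i_csd]
        q_rcav_out = (p_t[i_rcav] - p_csr) / zc[i_rcav]
        q_csp_in = (p_csr - p_t[i_csp]) / zc[i_csp]

        # --- intramyocardial circuit (vectorized over beds × layers) ------
        r_a = self.bed_r0_a * (self.bed_v0_ea / v_ea_eff) ** 2
        r_v = self.bed_r0_v * (self.bed_v0_ev / v_ev_eff) ** 2
        r1 = self.bed_r0_1 * (self.bed_v0_1 / v1_eff) ** 2
        r2 = self.bed_r0_2 * (self.bed_v0_2 / v2_eff) ** 2
        rm = self.bed_r0_m * ((0.5 * (self.bed_v0_1 + self.bed_v0_2))
                              / (0.5 * (v1_eff + v2_eff))) ** 2

        g_a, g1 = 1.0 / r_a, 1.0 / r1
        p_split = (p_ea * g_a + (p1 * g1).sum(axis=1)) / (g_a + g1.sum(axis=1))
        q_a = (p_ea - p_split) * g_a
        q1 = (p_split[:, None] - p1) * g1
        qm = (p1 - p2) / rm
        g_v, g2 = 1.0 / r_v, 1.0 / r2
        p_merge = (p_ev * g_v + (p2 * g2).sum(axis=1)) / (g_v + g2.sum(axis=1))
        q2 = (p2 - p_merge[:, None]) * g2
        q_v = (p_merge - p_ev) * g_v

        # --- valve dynamics ----------------------------------------------
        dp_valve = np.array([
            p_la - p_lv,
            p_lv - p_ao,
            p_ra - p_rv,
            p_rv - p_par,
        ])
        dq_valve = (dp_valve - self.valve_B * state.q_valve * np.abs(state.q_valve)
                    - self.valve_Rlam * state.q_valve) / self.valve_L
        # diode: a closed valve with adverse gradient stays closed
        dq_valve = np.where((state.q_valve <= 0.0) & (dp_valve <= 0.0),
                            np.minimum(dq_valve, 0.0) * 0.0, dq_valve)

        # --- assemble derivatives ----------------------------------------
        dv_cav = np.array([
            q_mv - q_av,
            q_tv - q_pv,
            q_pv_la - q_mv,
            q_sv_ra + q_cs_ra - q_tv,
        ])
        dv_tube = np.zeros_like(state.v_tube)
        dv_tube[i_sa] = q_sa_in - q_sys
        dv_tube[i_sv] = q_sys - q_sv_ra
        dv_tube[i_pa] = q_pa_in - q_pulm
        dv_tube[i_pv] = q_pulm - q_pv_la
        dv_tube[i_lm] = q_lm_in - q_lm_out
        dv_tube[i_lcx] = q_lcx_in - q_bed_in[0]
        dv_tube[i_lad] = q_lad_in - q_bed_in[1]
        dv_tube[i_rca] = q_rca_in - q_bed_in[2]
        dv_tube[i_lcxv] = q_bed_out[0] - q_lcxv_out
        dv_tube[i_ladv] = q_bed_out[1] - q_ladv_out
        dv_tube[i_rcav] = q_bed_out[2] - q_rcav_out
        dv_tube[i_csd] = q_csd_in - q_csd_out
        dv_tube[i_csp] = q_csp_in - q_cs_ra

        dstate = State(
            v_cav=dv_cav,
            q_valve=dq_valve,
            v_tube=dv_tube,
            v_ea=q_bed_in - q_a,
            v_ev=q_v - q_bed_out,
            v1=q1 - qm,
            v2=qm - q2,
            q_bed=dq_bed,
        )
        aux = {
            "p_lv": p_lv, "p_rv": p_rv, "p_la": p_la, "p_ra": p_ra,
            "p_peri": p_peri, "p_ao": p_ao, "p_par": p_par,
            "p_tube": p_t, "a_tube": a_t, "z_tube": z_t,
            "p_ea": p_ea, "p_ev": p_ev, "p1": p1, "p2": p2,
            "p_im": p_im, "cep": imp_state.cep, "ve": imp_state.ve,
            "sigma": sigma, "tri": tri,
            "q_bed_in": q_bed_in, "q_bed_out": q_bed_out,
            "q_a": q_a, "q1": q1, "qm": qm, "q2": q2, "q_v": q_v,
            "q_sys": q_sys, "q_pulm": q_pulm,
            "q_sv_ra": q_sv_ra, "q_pv_la": q_pv_la, "q_cs_ra": q_cs_ra,
            "q_lm_in": q_lm_in, "q_lcx_in": q_lcx_in, "q_lad_in": q_lad_in,
            "q_rca_in": q_rca_in, "q_csd_in": q_csd_in, "q_csd_out": q_csd_out,
            "dp_av": p_lv - p_ao,
            "act_v": act_v, "act_a": act_a,
        }
        return dstate, aux

    # ------------------------------------------------------------------
    # stepping
    # ------------------------------------------------------------------
    def step(self, state: State, tau: float) -> tuple[State, dict]:
        """One explicit update of every state over dt; returns (state, aux)."""
        dt = self.dt
        if self.config.solver.scheme == "rk4":
            k1, aux = self.derivatives(state, tau)
            k2, _ = self.derivatives(state.axpy(0.5 * dt, k1), tau + 0.5 * dt)
            k3, _ = self.derivatives(state.axpy(0.5 * dt, k2), tau + 0.5 * dt)
            k4, _ = self.derivatives(state.axpy(dt, k3), tau + dt)
            new = state.axpy(dt / 6.0, k1).axpy(dt / 3.0, k2).axpy(dt / 3.0, k3) \
                       .axpy(dt / 6.0, k4)
        else:
            d, aux = self.derivatives(state, tau)
            new = state.axpy(dt, d)
        # competent valves: no sustained retrograde valve flow
        new.q_valve = np.maximum(new.q_valve, 0.0)
        # an (almost) empty chamber cannot keep ejecting: valve order is
        # mitral, aortic, tricuspid, pulmonary with upstream LA, LV, RA, RV
        upstream = new.v_cav[[2, 0, 3, 1]]
        new.q_valve = np.where(upstream < 2.0, 0.0, new.q_valve)
        return new, aux

    def _canonical_events(self, transitions: dict[str, list[float]]) -> dict:
        """Reduce valve transition lists to one canonical event per type.

        Ejection is bracketed by the first aortic opening and the first
        closure after it; end-diastole is the last mitral closure before
        aortic opening (wrap-aware), so brief diastolic flutter of an inflow
        valve does not displace the ED marker.
        """
        events: dict[str, float] = {}
        ao_open = min(transitions.get("aortic_open", []), default=None)
        if ao_open is not None:
            events["aortic_open"] = ao_open
            closes = [t for t in transitions.get("aortic_close", []) if t > ao_open]
            if closes:
                events["aortic_close"] = min(closes)
        for name in ("pulmonary",):
            opens = transitions.get(f"{name}_open", [])
            if opens:
                events[f"{name}_open"] = min(opens)
                closes = [t for t in transitions.get(f"{name}_close", [])
                          if t > events[f"{name}_open"]]
                if closes:
                    events[f"{name}_close"] = min(closes)
        for name in ("mitral", "tricuspid"):
            opens = transitions.get(f"{name}_open", [])
            closes = transitions.get(f"{name}_close", [])
            if opens:
                events[f"{name}_open"] = min(opens)
            if closes:
                if ao_open is not None:
                    before = [t for t in closes if t <= ao_open]
                    events[f"{name}_close"] = max(before) if before else max(closes)
                else:
                    events[f"{name}_close"] = max(closes)
        return events

    def run_beat(self, record: bool = False):
        """Advance one cardiac cycle; returns (measures, BeatRecord | None)."""
        state = self.state
        n = self.n_steps
        sums: dict[str, float | np.ndarray] = {
            "p_ao": 0.0, "p_art": 0.0, "p_sv": 0.0, "q_av": 0.0, "q_sys": 0.0,
            "q1": np.zeros((3, 3)), "q_bed_in": np.zeros(3), "q_csd": 0.0,
            "p_ra": 0.0,
        }
        channels: dict[str, np.ndarray] = {}
        prev_q = state.q_valve.copy()
        transitions: dict[str, list[float]] = {}
        rec_rows: list[dict] | None = [] if record else None

        for i in range(n):
            tau = i * self.dt
            state, aux = self.step(state, tau)
            sums["p_ao"] += aux["p_ao"]
            sums["p_art"] += aux["p_tube"][self.tube_idx["sys_art"]]
            sums["p_sv"] += aux["p_tube"][self.tube_idx["sys_ven"]]
            sums["q_sys"] += aux["q_sys"]
            sums["p_ra"] += aux["p_ra"]
            sums["q_av"] += state.q_valve[1]
            sums["q1"] += aux["q1"]
            sums["q_bed_in"] += aux["q_bed_in"]
            sums["q_csd"] += 0.5 * (aux["q_csd_in"] + aux["q_csd_out"])
            # valve transition times (post-processed into canonical events)
            for vi, name in enumerate(VALVE_ORDER):
                if prev_q[vi] <= 0.0 < state.q_valve[vi]:
                    transitions.setdefault(f"{name}_open", []).append(tau)
                elif prev_q[vi] > 0.0 >= state.q_valve[vi]:
                    transitions.setdefault(f"{name}_close", []).append(tau)
            prev_q = state.q_valve.copy()
            if record:
                rec_rows.append(self._record_row(state, aux))

        state.check_finite(self.beats_run * self.period)
        self.state = state
        self.beats_run += 1
        events = self._canonical_events(transitions)
        for key in ("p_ao", "p_art", "p_sv", "p_ra", "q_av", "q_sys", "q_csd"):
            sums[key] = float(sums[key]) / n
        sums["q1"] = sums["q1"] / n
        sums["q_bed_in"] = sums["q_bed_in"] / n
        self.last_measure = sums

        if not record:
            return sums, None
        names = rec_rows[0].keys()
        channels = {k: np.array([r[k] for r in rec_rows]) for k in names}
        beat = BeatRecord(dt=self.dt, channels=channels, events=events,
                          meta={"period": self.period,
                                "aortic_area_cm2": self.config.valves.aortic.area_cm2,
                                "mean": sums})
        return sums, beat

    def _record_row(self, state: State, aux: dict) -> dict:
        ix = self.tube_idx
        row = {
            "p_lv": aux["p_lv"], "p_rv": aux["p_rv"], "p_la": aux["p_la"],
            "p_ra": aux["p_ra"], "p_peri": aux["p_peri"], "p_ao": aux["p_ao"],
            "p_aorta": aux["p_tube"][ix["sys_art"]],
            "dp_av": aux["dp_av"],
            "v_lv": state.v_cav[0], "v_rv": state.v_cav[1],
            "v_la": state.v_cav[2], "v_ra": state.v_cav[3],
            "q_mitral": state.q_valve[0], "q_aortic": state.q_valve[1],
            "q_tricuspid": state.q_valve[2], "q_pulmonary": state.q_valve[3],
            "u_aortic": velocity_m_s(state.q_valve[1], self.valve_area[1]),
            "q_sys": aux["q_sys"], "q_cs_ra": aux["q_cs_ra"],
            "sig_lv": aux["sigma"]["LV"], "sig_s": aux["sigma"]["S"],
            "sig_rv": aux["sigma"]["RV"],
            "septal_curvature": aux["tri"].cm["S"],
        }
        for name in ("cor_lm", "cor_lcx", "cor_lad", "cor_rca", "cor_cs_dist"):
            i = ix[name]
            row[f"p_{name}"] = aux["p_tube"][i]
            row[f"a_{name}"] = aux["a_tube"][i]
        row["q_cor_lm_in"] = aux["q_lm_in"]
        row["q_cor_lcx_in"] = aux["q_lcx_in"]
        row["q_cor_lad_in"] = aux["q_lad_in"]
        row["q_cor_rca_in"] = aux["q_rca_in"]
        row["q_cor_cs_dist"] = 0.5 * (aux["q_csd_in"] + aux["q_csd_out"])
        for bi, name in ((0, "cor_lcx"), (1, "cor_lad"), (2, "cor_rca")):
            i = ix[name]
            # mid-vessel flow: mean of proximal inflow and distal (bed) flow
            q_prox = {"cor_lcx": aux["q_lcx_in"], "cor_lad": aux["q_lad_in"],
                      "cor_rca": aux["q_rca_in"]}[name]
            qn = 0.5 * (q_prox + aux["q_bed_in"][bi])
            row[f"u_{name}"] = velocity_m_s(qn, aux["a_tube"][i])
        i = ix["cor_cs_dist"]
        row["u_cor_cs_dist"] = velocity_m_s(
            0.5 * (aux["q_csd_in"] + aux["q_csd_out"]), aux["a_tube"][i])
        row["u_cor_lm"] = velocity_m_s(aux["q_lm_in"], aux["a_tube"][ix["cor_lm"]])
        for bi, branch in enumerate(BRANCHES):
            b = branch.lower()
            row[f"q_{b}_in"] = aux["q_bed_in"][bi]
            row[f"q_{b}_out"] = aux["q_bed_out"][bi]
            row[f"v_{b}_ea"] = state.v_ea[bi]
            row[f"v_{b}_ev"] = state.v_ev[bi]
            row[f"ve_{b}"] = aux["ve"][bi, 0]
            for li, layer in enumerate(LAYERS):
                row[f"q1_{b}_{layer}"] = aux["q1"][bi, li]
                row[f"qm_{b}_{layer}"] = aux["qm"][bi, li]
                row[f"q2_{b}_{layer}"] = aux["q2"][bi, li]
                row[f"v1_{b}_{layer}"] = state.v1[bi, li]
                row[f"v2_{b}_{layer}"] = state.v2[bi, li]
                row[f"imp_{b}_{layer}"] = aux["p_im"][bi, li]
                row[f"cep_{b}_{layer}"] = aux["cep"][bi, li]
        return row

    # ------------------------------------------------------------------
    # beat-to-beat protocols
    # ------------------------------------------------------------------
    # -- homeostatic control: (r_sys, circulating volume) -> (MAP, CO) ----
    def _run_window(self, n_beats: int, measure_last: int = 2) -> np.ndarray:
        """Run beats and return mean (MAP, CO) over the final beats."""
        acc = np.zeros(2)
        for i in range(n_beats):
            m, _ = self.run_beat(record=False)
            if i >= n_beats - measure_last:
                acc += (m["p_art"], m["q_av"])
        return acc / measure_last

    def _identify_homeostasis(self, n_settle: int = 10) -> None:
        """One-time system identification: the 2×2 sensitivity of (MAP, CO)
        to the systemic resistance and the circulating volume, by explicit
        perturbation.  The baseline and both perturbed windows start from the
        same settled state, so any residual beat-to-beat drift cancels in the
        differences."""
        self._run_window(n_settle)  # settle before probing
        base_state = self.state.copy()
        base_r = self.r_sys

        y0 = self._run_window(n_settle)

        dr = 0.05 * base_r
        self.state = base_state.copy()
        self.r_sys = base_r + dr
        y_r = self._run_window(n_settle)

        dvol = 150.0
        self.state = base_state.copy()
        self.r_sys = base_r
        self.state.v_tube[self.tube_idx["sys_ven"]] += dvol
        y_v = self._run_window(n_settle)

        self.state = base_state
        self.r_sys = base_r
        jac = np.column_stack([(y_r - y0) / dr, (y_v - y0) / dvol])
        # guard against a near-singular plant (e.g. pericardial congestion)
        if abs(np.linalg.det(jac)) < 1e-6:
            jac = jac + np.diag([0.05, 1e-3])
        self._homeo_jac = jac
        log.info("homeostasis identification: J = %s", jac.round(4))

    def _homeostasis_window_update(self, measures: np.ndarray) -> None:
        """Damped Newton update of (r_sys, volume) toward (MAP, CO) targets."""
        g = self.config.general
        target = np.array([g.map_mmhg, g.co_l_min * 1000.0 / 60.0])
        err = target - measures
        step = np.linalg.solve(self._homeo_jac, err)
        damp = self.config.solver.homeostasis_gain
        dr = float(np.clip(damp * step[0], -0.15 * self.r_sys, 0.15 * self.r_sys))
        dv = float(np.clip(damp * step[1], -120.0, 120.0))
        # congestion/collapse guards: stop volume loading once right atrial
        # pressure is frankly elevated (Starling saturated) and stop draining
        # once it is near zero (venous collapse)
        if self.last_measure:
            if dv > 0 and self.last_measure["p_ra"] > 10.0:
                dv = 0.0
            if dv < 0 and self.last_measure["p_ra"] < 0.5:
                dv = 0.0
        self.r_sys = max(self.r_sys + dr, 0.05)
        self.state.v_tube[self.tube_idx["sys_ven"]] += dv
        self._last_update = (abs(dr) / max(self.r_sys, 1e-6), abs(dv))

    def run_to_steady_state(self, record: bool = True, homeostasis: bool = True,
                            max_beats: int | None = None,
                            periodicity_tol: float | None = None,
                            require_targets: bool = True):
        """Run until the beat-to-beat state change and the hemodynamic targets
        converge; returns the final converged beat as a :class:`BeatRecord`.

        With ``homeostasis`` the controller adjusts systemic resistance and
        circulating volume every few beats (damped Newton on an identified
        2×2 sensitivity) until cardiac output and mean arterial pressure sit
        within 1% of their targets.
        """
        cfg = self.config
        tol = periodicity_tol or cfg.solver.periodicity_tol
        max_beats = max_beats or cfg.solver.max_beats
        g = cfg.general
        co_target = g.co_l_min * 1000.0 / 60.0
        prev = self.state.vector()
        scale = np.maximum(np.abs(prev), 1.0)
        history = []
        window: list[np.ndarray] = []
        for beat in range(max_beats):
            measures, _ = self.run_beat(record=False)
            cur = self.state.vector()
            rel = float(np.max(np.abs(cur - prev) / scale))
            prev = cur
            scale = np.maximum(np.abs(cur), 1.0)
            targets_ok = True
            if homeostasis:
                targets_ok = (abs(measures["p_art"] - g.map_mmhg) < 0.01 * g.map_mmhg
                              and abs(measures["q_av"] - co_target) < 0.01 * co_target)
                window.append(np.array([measures["p_art"], measures["q_av"]]))
                if (len(window) >= 10 and not targets_ok
                        and not self._controller_frozen):
                    # identify the plant lazily, once settled, only if the
                    # calibrated operating point needs trimming
                    if self._homeo_jac is None:
                        self._identify_homeostasis(n_settle=10)
                        window.clear()
                    else:
                        meas = np.mean(window[-3:], axis=0)
                        err = math.hypot((meas[0] - g.map_mmhg) / g.map_mmhg,
                                         (meas[1] - co_target) / co_target)
                        self._err_history.append(err)
                        # at the plant's reachability frontier further updates
                        # only slide along it: freeze once progress stops
                        h = self._err_history
                        if len(h) >= 4 and h[-1] > 0.98 * min(h[:-1]):
                            recent_best = min(h[-3:])
                            if recent_best > 0.98 * min(h[:-3] or h):
                                self._controller_frozen = True
                                log.info("homeostatic controller frozen at "
                                         "MAP %.1f CO %.2f", meas[0],
                                         meas[1] * 60 / 1000)
                        if not self._controller_frozen:
                            self._homeostasis_window_update(meas)
                        window.clear()
            history.append((beat, measures["p_art"], measures["q_av"] * 60 / 1000, rel))
            log.info("beat %3d  MAP %6.1f mmHg  CO %5.2f L/min  dstate %.2e",
                     beat, measures["p_art"], measures["q_av"] * 60.0 / 1000.0, rel)
            # without strict targets, the run still waits for the controller
            # to stall (its last update negligibly small) so the achieved
            # MAP/CO reflect the controller's best effort
            stalled = self._controller_frozen or (
                self._last_update is not None
                and self._last_update[0] < 0.005
                and self._last_update[1] < 5.0)
            if rel < tol and beat > 3 and (
                    targets_ok or (not require_targets and
                                   (stalled or not homeostasis))):
                if record:
                    _, rec = self.run_beat(record=True)
                    return rec
                return None
        trend = "; ".join(f"beat {b}: MAP {m:.1f}, CO {c:.2f}, d {r:.1e}"
                          for b, m, c, r in history[-5:])
        raise ConvergenceError(
            f"no periodic steady state within {max_beats} beats ({trend})")

    def _anchor_bed_references(self, relax: float = 0.5) -> float:
        """Re-anchor intramyocardial reference volumes and pressures at the
        diastolic operating state of the current beat.

        The wall law's (V0, p0) pair describes the compartment's reference
        state; the printed tables do not pin it down, so it is taken to be
        the diastolic mean of the tuned resting beat (the state in which the
        vessels are unloaded by the intramyocardial pressure).  R(V) then
        fluctuates around R0 over the cycle, which makes the 28:65:7 /
        60:30:10 reference splits hold at the operating point.  Returns the
        largest relative change applied.
        """
        _, rec = self.run_beat(record=True)
        from .metrics import PhaseSegmentation
        ph = PhaseSegmentation.from_record(rec)
        mask = ph.diastolic_mask(rec)
        v1m = np.empty((3, 3))
        v2m = np.empty((3, 3))
        for bi, b in enumerate(b.lower() for b in BRANCHES):
            for li, layer in enumerate(LAYERS):
                v1m[bi, li] = rec[f"v1_{b}_{layer}"][mask].mean()
                v2m[bi, li] = rec[f"v2_{b}_{layer}"][mask].mean()
        # transmural pressure of the anchor state under the current law
        m = self.config.micro
        p1m = transmural_pressure_area(v1m, self.bed_p0["a"], self.bed_v0_1,
                                       m.aw_arteriole * self.bed_v0_1,
                                       m.k_arteriole)
        p2m = transmural_pressure_area(v2m, self.bed_p0["v"], self.bed_v0_2,
                                       m.aw_venule * self.bed_v0_2, m.k_venule)
        new_v1 = (1 - relax) * self.bed_v0_1 + relax * v1m
        new_v2 = (1 - relax) * self.bed_v0_2 + relax * v2m
        new_p1 = np.maximum((1 - relax) * self.bed_p0["a"] + relax * p1m, 1.0)
        new_p2 = np.maximum((1 - relax) * self.bed_p0["v"] + relax * p2m, 1.0)
        change = max(
            float(np.max(np.abs(new_v1 / self.bed_v0_1 - 1))),
            float(np.max(np.abs(new_v2 / self.bed_v0_2 - 1))),
        )
        self.bed_v0_1, self.bed_v0_2 = new_v1, new_v2
        self.bed_p0["a"], self.bed_p0["v"] = new_p1, new_p2
        return change

    def autoregulate_reference(self, run_tol: float | None = None,
                               anchor_iters: int = 6) -> dict:
        """Tune each layer's reference arteriolar resistance R_0,1 until mean
        layer flows match the branch targets and endo-to-epi ratio within
        the autoregulation tolerance.  Only R_0,1 is rescaled; the reference
        splits of R_m and R_2 are untouched.  During the first iterations the
        intramyocardial reference states are co-anchored at the resting
        diastolic operating point (see :meth:`_anchor_bed_references`), then
        frozen.  Returns tuning diagnostics.
        """
        cfg = self.config.solver
        info = {"iterations": 0, "residual": None}
        prev_r = prev_q = None
        for it in range(cfg.autoreg_max_iter):
            # resistance tuning perturbs the loop only weakly; the homeostatic
            # trim stays off here and a final controlled run follows tuning
            self.run_to_steady_state(record=False, homeostasis=False,
                                     periodicity_tol=run_tol or cfg.periodicity_tol)
            if it < anchor_iters:
                self._anchor_bed_references()
                prev_r = prev_q = None  # plant changed: restart the secant
            q1_mean = self.last_measure["q1"]  # mL/s, beds × layers
            ratio = q1_mean / self.bed_q0_layer
            resid = float(np.max(np.abs(ratio - 1.0)))
            info["iterations"] = it + 1
            info["residual"] = resid
            log.info("autoregulation iter %d: max layer-flow error %.3f", it, resid)
            if resid < cfg.autoreg_tol and it >= anchor_iters:
                return info
            r_cur = self.bed_r0_1.copy()
            if prev_r is None:
                r_new = r_cur * np.clip(ratio, 0.6, 1.6)
            else:
                # per-layer secant on mean flow vs reference resistance
                dq = q1_mean - prev_q
                dr = r_cur - prev_r
                slope = np.where(np.abs(dr) > 1e-9, dq / np.where(dr == 0, 1, dr),
                                 0.0)
                step = np.where(slope < -1e-9,
                                (self.bed_q0_layer - q1_mean) / slope, 0.0)
                fallback = r_cur * (np.clip(ratio, 0.6, 1.6) - 1.0)
                step = np.where(step == 0.0, fallback, step)
                r_new = r_cur + np.clip(step, -0.7 * r_cur, 2.0 * r_cur)
            prev_r, prev_q = r_cur, q1_mean
            self.bed_r0_1 = np.maximum(r_new, 1e-3)
        raise ConvergenceError(
            f"autoregulation did not converge: layer flow errors "
            f"{(self.last_measure['q1'] / self.bed_q0_layer - 1.0).round(3)}")


# ----------------------------------------------------------------------
# scenarios
# ----------------------------------------------------------------------

@dataclass
class ScenarioResult:
    name: str
    record: BeatRecord
    simulator: Simulator = field(repr=False)


def run_scenario_pair(config: Config, autoregulate: bool = True
                      ) -> dict[str, ScenarioResult]:
    """Tuned reference simulation plus the aortic-stenosis case.

    The stenosis run changes a single parameter — the aortic orifice area,
    4.8 → 0.8 cm² — while the homeostatic controller maintains cardiac
    output and mean arterial pressure; coronary parameters stay frozen at
    their reference-tuned values (no re-autoregulation).
    """
    ref_sim = Simulator(config)
    if autoregulate:
        ref_sim.autoregulate_reference()
    ref_rec = ref_sim.run_to_steady_state(record=True)

    sten_cfg = config.model_copy(deep=True)
    sten_cfg.valves.aortic.area_cm2 = 0.8
    sten_sim = Simulator(sten_cfg, initial_state=ref_sim.state)
    sten_sim.bed_r0_1 = ref_sim.bed_r0_1.copy()
    sten_sim.bed_v0_1 = ref_sim.bed_v0_1.copy()
    sten_sim.bed_v0_2 = ref_sim.bed_v0_2.copy()
    sten_sim.bed_p0["a"] = ref_sim.bed_p0["a"].copy()
    sten_sim.bed_p0["v"] = ref_sim.bed_p0["v"].copy()
    sten_sim.r_sys = ref_sim.r_sys
    # the stenosed loop may not be able to hold both targets exactly; the
    # controller still trims toward them and convergence is judged on
    # periodicity (achieved MAP/CO are reported in the record metadata)
    sten_rec = sten_sim.run_to_steady_state(record=True, require_targets=False,
                                            max_beats=280)

    return {
        "reference": ScenarioResult("reference", ref_rec, ref_sim),
        "aortic_stenosis": ScenarioResult("aortic_stenosis", sten_rec, sten_sim),
    }
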