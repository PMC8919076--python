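"""Lumped three-layer coronary microcirculation.

Each coronary branch (LCx, LAD, RCA) terminates in an arterial–venous lumped
bed: an epicardial arterial compartment, three transmural layers
(subepicardial, mid, subendocardial — radial positions r = 1/6, 3/6, 5/6)
each holding an arteriolar and a venular compartment, and an epicardial
venous compartment.  Compartment volumes obey the collapsible-tube
pressure–area law (see :mod:`coroflow._tubelaw`); compliances are its local
slope dV/dp, not independent parameters.  Intervascular flows pass through
volume-dependent resistances

    R(V) = R0 · V0² / V²            (Poiseuille: R ∝ 1/A² at fixed length)

and the layer intramyocardial pressure p_im adds to the transmural pressure
of both compartments of that layer.  Bed inflow/outflow are
pressure-difference-controlled flow sources across the arterial and venous
wave impedances of the connecting 1D vessels.

Reference resistances are set by target flow and reference pressure drop
(R0 = Δp0/q0), split 28% : 65% : 7% over the epicardial arterial,
intramyocardial and epicardial venous compartments and 60% : 30% : 10% over
R1 : Rm : R2 within each layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._tubelaw import dp_dA, transmural_pressure_area
from .units import wave_impedance_mmhg_s_ml, wave_speed_m_s

log = logging.getLogger(__name__)

LAYERS = ("subepi", "mid", "subendo")
LAYER_RADIAL_POSITION = np.array([1.0 / 6.0, 3.0 / 6.0, 5.0 / 6.0])

#: reference resistance split over epicardial arterial : intramyocardial : venous
SPLIT_COMPARTMENTS = (0.28, 0.65, 0.07)
#: split of intramyocardial resistance over arteriolar : middle : venular
SPLIT_INTRAMYOCARDIAL = (0.60, 0.30, 0.10)


@dataclass
class Compartment:
    """Parameters of one collapsible compartment (volume state lives outside).

    The nominal length converts volume to lumen area (V = A·L); p0 is the
    transmural pressure at the reference state (A = A0, V = V0).
    """

    v0: float  # mL
    p0: float  # mmHg
    k: float  # stiffness exponent
    aw_ratio: float  # wall area / reference lumen area
    r0: float = 0.0  # mmHg·s/mL, reference resistance of the attached resistor
    length: float = 1.0  # cm

    @property
    def a0(self) -> float:
        return self.v0 / self.length

    @property
    def a_wall(self) -> float:
        return self.aw_ratio * self.a0


def soft_floor(v, v_floor, width_frac: float = 0.25):
    """Smooth lower clamp of a volume at ``v_floor``.

    Exactly the identity for v ≥ v_floor·(1 + width_frac); below that the
    clamp decays smoothly (C¹) toward ``v_floor``, so resistances stay
    finite in the collapse regime without perturbing normal operation.
    """
    v = np.asarray(v, dtype=float)
    w = width_frac * v_floor
    x = v - v_floor
    # identity above the blend region, exponential blend below
    out = np.where(x >= w, v, v_floor + w * np.exp(np.minimum(x / w, 1.0) - 1.0))
    return out if out.ndim else float(out)


def transmural_pressure(area, comp: Compartment):
    """Collapsible-tube transmural pressure (mmHg) at lumen area (cm²)."""
    return transmural_pressure_area(area, comp.p0, comp.a0, comp.a_wall, comp.k)


def pressure_from_volume(volume, comp: Compartment, v_floor_frac: float = 0.01):
    v_eff = soft_floor(np.asarray(volume, float), v_floor_frac * comp.v0)
    return transmural_pressure(v_eff / comp.length, comp)


def resistance(volume, r0, v0, v_floor_frac: float = 0.01):
    """Volume-dependent resistance R = R0·V0²/V², floored in collapse."""
    v = np.asarray(volume, dtype=float)
    vf = v_floor_frac * np.asarray(v0, dtype=float)
    if np.any(v < vf):
        log.warning("compartment volume below floor; resistance clamped (collapse regime)")
    v_eff = soft_floor(v, vf)
    return r0 * (np.asarray(v0, float) / v_eff) ** 2


def layer_target_flows(q0: float, endo_epi_ratio: float) -> np.ndarray:
    """Per-layer target flows (same units as q0), subepi → subendo.

    The mid layer sits halfway between the subepicardial and subendocardial
    targets; layer flows sum to the branch target.
    """
    w = np.array([1.0, 0.5 * (1.0 + endo_epi_ratio), endo_epi_ratio])
    return q0 * w / w.sum()


def reference_resistances(
    q0_layer: np.ndarray,
    p_arterial_mean: float,
    p_venous_mean: float,
    split_compartments=SPLIT_COMPARTMENTS,
    split_intramyocardial=SPLIT_INTRAMYOCARDIAL,
) -> dict:
    """Reference resistances of one bed from layer target flows (mL/s).

    Total bed resistance = mean perfusion pressure / total target flow,
    apportioned 28:65:7 over R_a : (R1+Rm+R2 in parallel layers) : R_v and
    60:30:10 over R1 : Rm : R2 within each layer.  Per-layer path resistance
    scales inversely with that layer's flow share.
    """
    q0_layer = np.asarray(q0_layer, dtype=float)
    if np.any(q0_layer <= 0):
        raise ValueError("layer target flows must be > 0")
    if abs(sum(split_compartments) - 1.0) > 1e-12 or abs(sum(split_intramyocardial) - 1.0) > 1e-12:
        raise ValueError("resistance splits must each sum to 100%")
    dp = p_arterial_mean - p_venous_mean
    if dp <= 0:
        raise ValueError("mean perfusion pressure must be positive")
    q0 = q0_layer.sum()
    r_total = dp / q0
    r_a = split_compartments[0] * r_total
    r_v = split_compartments[2] * r_total
    r_im = split_compartments[1] * r_total  # parallel combination over layers
    r_layer = r_im * q0 / q0_layer  # per-layer series path
    return {
        "R_total": r_total,
        "R_a": r_a,
        "R_v": r_v,
        "R1": split_intramyocardial[0] * r_layer,
        "Rm": split_intramyocardial[1] * r_layer,
        "R2": split_intramyocardial[2] * r_layer,
    }


# --------------------------------------------------------------------------
# bed parameter bundle and circuit derivatives (vectorized over beds)
# --------------------------------------------------------------------------

@dataclass
class BedParams:
    """All parameters of one coronary bed (arrays over the three layers)."""

    branch: str
    q0: float  # mL/s, branch target flow
    q0_layer: np.ndarray  # (3,), mL/s
    ea: Compartment
    ev: Compartment
    art: list[Compartment]  # arteriolar, per layer
    ven: list[Compartment]  # venular, per layer
    r0_1: np.ndarray = field(default=None)  # (3,)
    r0_m: np.ndarray = field(default=None)
    r0_2: np.ndarray = field(default=None)

    def reference_state(self) -> dict[str, np.ndarray]:
        return {
            "v_ea": self.ea.v0,
            "v_ev": self.ev.v0,
            "v1": np.array([c.v0 for c in self.art]),
            "v2": np.array([c.v0 for c in self.ven]),
        }


def build_bed(
    branch: str,
    q0_ml_min: float,
    endo_epi_ratio: float,
    p_arterial_mean: float,
    p_venous_mean: float,
    micro_cfg,
) -> BedParams:
    """Assemble a bed's compartments and reference resistances from targets.

    ``micro_cfg`` supplies the non-printed wall-law constants (p0 per
    compartment class, stiffness k, wall-area ratios, reference volumes per
    unit flow); defaults are calibrated, see docs/methods.md.
    """
    q0 = q0_ml_min / 60.0
    q_layer = layer_target_flows(q0, endo_epi_ratio)
    res = reference_resistances(q_layer, p_arterial_mean, p_venous_mean)
    flow_scale = q0_ml_min / 83.0  # compartment volumes scale with branch flow
    ea = Compartment(micro_cfg.v0_epi_art * flow_scale, micro_cfg.p0_epi_art,
                     micro_cfg.k_art, micro_cfg.aw_epi_art, r0=res["R_a"])
    ev = Compartment(micro_cfg.v0_epi_ven * flow_scale, micro_cfg.p0_epi_ven,
                     micro_cfg.k_ven, micro_cfg.aw_epi_ven, r0=res["R_v"])
    art = [Compartment(micro_cfg.v0_arteriolar * flow_scale / 3.0, micro_cfg.p0_arteriolar,
                       micro_cfg.k_arteriole, micro_cfg.aw_arteriole)
           for _ in LAYERS]
    ven = [Compartment(micro_cfg.v0_venular * flow_scale / 3.0, micro_cfg.p0_venular,
                       micro_cfg.k_venule, micro_cfg.aw_venule)
           for _ in LAYERS]
    return BedParams(
        branch=branch, q0=q0, q0_layer=q_layer, ea=ea, ev=ev, art=art, ven=ven,
        r0_1=res["R1"], r0_m=res["Rm"], r0_2=res["R2"],
    )


def bed_impedances(bed: BedParams, v_ea, v_ev) -> tuple[float, float]:
    """Instantaneous wave impedances Z_a, Z_v of the epicardial compartments."""
    za = zv = 0.0
    for comp, v in ((bed.ea, v_ea), (bed.ev, v_ev)):
        a = float(soft_floor(v, 0.01 * comp.v0)) / comp.length
        slope = float(dp_dA(a, comp.p0, comp.a0, comp.a_wall, comp.k))
        slope = max(slope, 1e-6)
        z = wave_impedance_mmhg_s_ml(a, wave_speed_m_s(a, slope))
        if comp is bed.ea:
            za = z
        else:
            zv = z
    return za, zv


def micro_derivatives(
    bed: BedParams,
    state: dict,
    p_arterial_inlet: float,
    p_venous_outlet: float,
    p_im: np.ndarray,
    z_in: float,
    z_out: float,
    p_external_epi: float = 0.0,
) -> dict:
    """Flows and dV/dt of every compartment of one bed.

    ``state`` holds volumes {v_ea, v_ev, v1(3,), v2(3,)}; ``p_im`` the layer
    intramyocardial pressures.  Epicardial compartments feel
    ``p_external_epi`` (pericardial pressure) as external pressure,
    intramyocardial compartments feel their layer's p_im.  Mass is conserved
    exactly: Σ dV/dt = q_in − q_out.
    """
    v_ea, v_ev = state["v_ea"], state["v_ev"]
    v1 = np.asarray(state["v1"], float)
    v2 = np.asarray(state["v2"], float)

    p_ea = float(pressure_from_volume(v_ea, bed.ea)) + p_external_epi
    p_ev = float(pressure_from_volume(v_ev, bed.ev)) + p_external_epi
    p1 = np.array([float(pressure_from_volume(v1[i], bed.art[i])) for i in range(3)]) + p_im
    p2 = np.array([float(pressure_from_volume(v2[i], bed.ven[i])) for i in range(3)]) + p_im

    r_a = float(resistance(v_ea, bed.ea.r0, bed.ea.v0))
    r_v = float(resistance(v_ev, bed.ev.r0, bed.ev.v0))
    v0_1 = np.array([c.v0 for c in bed.art])
    v0_2 = np.array([c.v0 for c in bed.ven])
    r1 = resistance(v1, bed.r0_1, v0_1)
    r2 = resistance(v2, bed.r0_2, v0_2)
    rm = resistance(0.5 * (v1 + v2), bed.r0_m, 0.5 * (v0_1 + v0_2))

    q_in = (p_arterial_inlet - p_ea) / z_in
    q_out = (p_ev - p_venous_outlet) / z_out

    g_a, g1 = 1.0 / r_a, 1.0 / r1
    p_split = (p_ea * g_a + (p1 * g1).sum()) / (g_a + g1.sum())
    q_a = (p_ea - p_split) * g_a
    q1 = (p_split - p1) * g1

    qm = (p1 - p2) / rm

    g_v, g2 = 1.0 / r_v, 1.0 / r2
    p_merge = (p_ev * g_v + (p2 * g2).sum()) / (g_v + g2.sum())
    q2 = (p2 - p_merge) * g2
    q_v = (p_merge - p_ev) * g_v

    return {
        "q_in": q_in, "q_out": q_out, "q_a": q_a, "q1": q1, "qm": qm,
        "q2": q2, "q_v": q_v,
        "p_ea": p_ea, "p_ev": p_ev, "p1": p1, "p2": p2,
        "dv_ea": q_in - q_a, "dv1": q1 - qm, "dv2": qm - q2, "dv_ev": q_v - q_out,
    }


def diameters_from_volumes(v, v_ref):
    """Relative diameter d/d_ref = sqrt(V/V_ref) (circular lumen, fixed length)."""
    return np.sqrt(np.asarray(v, float) / np.asarray(v_ref, float))
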