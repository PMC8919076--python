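"""One-fiber myocardial mechanics, TriSeg ventricular interaction, pericardium.

Each cardiac wall is treated as a thick shell of incompressible myocardium in
which myofiber tension is homogeneously distributed.  Cavity volume stretches
the wall; midwall area determines the natural myofiber strain

    eps_f = 0.5 * ln(Am / Am_ref),

a myofiber constitutive law maps strain and activation to total fiber stress
(active + passive), and wall tension follows from stress and wall volume.
Transmural pressure is recovered from wall tension and curvature by Laplace's
law.  For a closed thick-walled sphere the same assumptions give the closed
form

    p_trans = (sigma_f / 3) * ln(1 + V_wall / V_cavity),

used for the atria (single-segment chambers) and as a benchmark for the
tension/curvature route.

Ventricular interaction: the LV free wall, septum and RV free wall are three
spherical caps meeting in a common junction ring.  The septal cap volume and
the ring radius are solved from force equilibrium (axial and radial tension
components sum to zero at the junction); cavity pressures then follow from
the free walls' tension and curvature plus the intrapericardial pressure of
the non-linearly compliant pericardium.

All one-fiber material constants are configuration parameters; the shipped
defaults are calibrated to reproduce the reference resting hemodynamics
(see docs/methods.md and scripts/calibrate.py).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class StrainBoundsError(ValueError):
    """Fiber strain left the configured physiologic bounds."""


class TriSegConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterate: tuple[float, float]):
        self.residual = residual
        self.iterate = iterate
        super().__init__(
            f"TriSeg junction solve did not converge: residual {residual:.3e} "
            f"at (Vm_sept, y) = {iterate}"
        )


@dataclass
class FiberMaterial:
    """Myofiber constitutive parameters for one wall.

    sigma_act : peak isometric active stress at full activation, kPa
    length_slope : linear length-dependence of active stress on strain
    eps_act0 : strain at which active stress vanishes
    sigma_pas : passive stress scale, kPa
    k_pas : passive exponential stiffness exponent
    eps_limit : guard bound on |strain|
    """

    sigma_act: float = 84.0
    length_slope: float = 2.6
    eps_act0: float = -0.30
    sigma_pas: float = 0.30
    k_pas: float = 16.0
    eps_limit: float = 1.0
    #: maximum unloaded shortening strain rate (1/s), force-velocity relation
    v_max: float = 3.0


def activation_time_course(t: float, period: float, onset: float, duration: float,
                           rise_frac: float = 0.30, decay_frac: float = 0.35) -> float:
    """Periodic twitch activation in [0, 1].

    A rise–plateau–decay pulse of the given ``duration`` starting at
    ``onset`` within each cycle of length ``period``: smooth sin² rise over
    ``rise_frac`` of the duration, full activation plateau, smooth cos²
    decay over ``decay_frac``.  The systolic duration of the ventricular
    twitch is a configured fraction of the cycle.
    """
    tau = (t - onset) % period
    if tau < 0 or tau >= duration:
        return 0.0
    t_rise = rise_frac * duration
    t_decay = decay_frac * duration
    if tau < t_rise:
        return math.sin(0.5 * math.pi * tau / t_rise) ** 2
    if tau > duration - t_decay:
        return math.cos(0.5 * math.pi * (tau - (duration - t_decay)) / t_decay) ** 2
    return 1.0


def segment_stress(
    strain: float | np.ndarray,
    activation: float,
    material: FiberMaterial,
    strain_rate: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total, active and passive fiber stress (kPa) of a wall segment.

    Active stress = sigma_act × activation × length-dependence (ascending
    limb saturating at the optimal-length plateau) × force-velocity factor
    (linearized Hill relation: force falls with shortening rate, vanishing
    at v_max, and is mildly enhanced during lengthening).  Passive stress is
    exponential in strain and zero at/below the zero-stress reference state,
    so total stress is purely passive when activation = 0 and zero at the
    reference strain.
    """
    eps = np.asarray(strain, dtype=float)
    if not (0.0 <= activation <= 1.0):
        raise ValueError(f"activation {activation} outside [0, 1]")
    if np.any(np.abs(eps) > material.eps_limit):
        bad = np.argmax(np.abs(eps))
        raise StrainBoundsError(
            f"fiber strain {np.atleast_1d(eps).ravel()[bad]:.3f} beyond "
            f"±{material.eps_limit} (segment index {bad})"
        )
    length_dep = np.clip((eps - material.eps_act0) * material.length_slope, 0.0, 1.0)
    # shortening rate = -d(eps)/dt; force-velocity factor in [0, 1.1]
    shortening = -np.asarray(strain_rate, dtype=float)
    fv = np.clip(1.0 - shortening / material.v_max, 0.0, 1.1)
    sigma_a = np.clip(material.sigma_act * activation * length_dep * fv, 0.0, None)
    sigma_p = material.sigma_pas * np.expm1(material.k_pas * np.clip(eps, 0.0, None))
    return sigma_a + sigma_p, sigma_a, sigma_p


def recoil_stress(eps: float, c_rec: float = 0.3, k_rec: float = 8.0) -> float:
    """Compressive elastic recoil below the zero-stress strain (kPa, ≤ 0).

    Myocardium resists compression: below the passive reference length the
    wall develops a (small) negative stress, giving diastolic suction and
    preventing cavity collapse.  Zero at and above the reference strain.
    """
    if eps >= 0.0:
        return 0.0
    return -c_rec * math.expm1(-k_rec * eps)


def sphere_transmural_pressure(sigma_f: float, v_wall: float, v_cavity: float) -> float:
    """One-fiber thick-walled sphere: p_trans = (σ_f/3)·ln(1 + V_wall/V_cav).

    Units follow ``sigma_f`` (kPa in → kPa out).
    """
    if v_cavity <= 0:
        raise ValueError("cavity volume must be > 0")
    return sigma_f / 3.0 * math.log1p(v_wall / v_cavity)


def sphere_midwall_area(v_cavity: float, v_wall: float) -> float:
    """Midwall surface area (cm²) of a spherical chamber."""
    v_mid = v_cavity + 0.5 * v_wall
    r = (3.0 * v_mid / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 4.0 * math.pi * r * r


# --------------------------------------------------------------------------
# spherical-cap geometry (TriSeg)
# --------------------------------------------------------------------------

def cap_height_from_volume(vm: float, y: float, x0: float | None = None) -> float:
    """Solve Vm = (π/6)·x·(x² + 3y²) for the signed cap height x.

    The cubic is strictly increasing in x, so Newton from any start converges.
    """
    x = x0 if x0 is not None else vm / (0.5 * math.pi * y * y + 1e-9)
    for _ in range(60):
        f = math.pi / 6.0 * x * (x * x + 3.0 * y * y) - vm
        df = math.pi / 6.0 * (3.0 * x * x + 3.0 * y * y)
        dx = f / df
        x -= dx
        if abs(dx) < 1e-14 * (1.0 + abs(x)):
            return x
    return x


def cap_geometry(vm: float, y: float, x0: float | None = None) -> tuple[float, float, float]:
    """(x, Am, Cm): cap height, midwall area, curvature of a spherical cap."""
    x = cap_height_from_volume(vm, y, x0)
    am = math.pi * (x * x + y * y)
    cm = 2.0 * x / (x * x + y * y)
    return x, am, cm


def wall_tension(sigma_f: float, v_wall: float, am: float, cm: float) -> float:
    """Representative midwall tension Tm (kPa·cm) of a curved thick wall.

    Tm = σ_f·Vw/(2·Am)·(1 + z²/3 + z⁴/5) with z = 3·Cm·Vw/(2·Am); the z
    terms correct for wall thickness relative to the radius of curvature.
    """
    z = 3.0 * cm * v_wall / (2.0 * am)
    return sigma_f * v_wall / (2.0 * am) * (1.0 + z * z / 3.0 + z**4 / 5.0)


@dataclass
class WallGeometry:
    """Geometry of one wall for the Laplace pressure computation."""

    kind: str  # "sphere" | "cap"
    v_wall: float
    v_cavity: float | None = None  # sphere
    am: float | None = None  # cap
    cm: float | None = None


def wall_pressure_from_stress(sigma_f: float, geom: WallGeometry) -> float:
    """Transmural pressure (kPa) from fiber stress and wall geometry.

    Positive when net wall tension compresses the enclosed cavity; linear in
    ``sigma_f`` at fixed geometry.  A flat cap (zero curvature) carries no
    transmural pressure and is resolved by the TriSeg junction balance.
    """
    if geom.kind == "sphere":
        return sphere_transmural_pressure(sigma_f, geom.v_wall, geom.v_cavity)
    if geom.kind == "cap":
        tm = wall_tension(sigma_f, geom.v_wall, geom.am, geom.cm)
        return 2.0 * tm * geom.cm
    raise ValueError(f"unknown geometry kind {geom.kind!r}")


# --------------------------------------------------------------------------
# TriSeg junction equilibrium
# --------------------------------------------------------------------------

@dataclass
class TriSegWall:
    name: str
    v_wall: float  # mL
    am_ref: float  # cm², zero-strain midwall area
    material: FiberMaterial
    contractility_scale: float = 1.0


@dataclass
class TriSegSolution:
    vm_sept: float
    y: float
    x: dict[str, float]
    am: dict[str, float]
    cm: dict[str, float]
    strain: dict[str, float]
    sigma_f: dict[str, float]
    sigma_pas: dict[str, float]
    tension: dict[str, float]
    residual: float
    # transmural pressures of the free walls (kPa, cavity minus pericardium)
    p_lv_trans: float
    p_rv_trans: float


class TriSegSolver:
    """Damped Newton solve of the three-wall junction equilibrium.

    Unknowns: septal midwall cap volume Vm_S (signed toward the RV) and the
    junction ring radius y.  Residuals: the axial and radial components of
    the three wall tensions at the junction ring must cancel.
    """

    def __init__(self, walls: dict[str, TriSegWall], tol: float = 1e-8,
                 max_iter: int = 50, y_ref: float | None = None,
                 ring_stiffness: float = 1.0, dt: float = 0.0):
        self.walls = walls  # keys "LV", "S", "RV"
        self.tol = tol
        self.max_iter = max_iter
        # the fibrous annulus resists radial deformation of the junction
        # ring: a weak elastic restoring term (kPa·cm per cm) that selects
        # the physiologic solution branch when wall tensions are small
        if y_ref is None:
            v_mid = 120.0 + 0.5 * (walls["LV"].v_wall + walls["S"].v_wall)
            y_ref = 0.95 * (3.0 * v_mid / (4.0 * math.pi)) ** (1.0 / 3.0)
        self.y_ref = y_ref
        self.ring_stiffness = ring_stiffness
        self.dt = dt
        self._warm: tuple[float, float] | None = None
        self._x_warm: dict[str, float] = {}
        self._eps_prev: dict[str, float] = {}
        self._jac: tuple[float, float, float, float] | None = None

    def _evaluate(self, v_lv: float, v_rv: float, vm_s: float, y: float,
                  activation: dict[str, float]):
        w = self.walls
        vm = {
            "LV": vm_s - v_lv - 0.5 * (w["LV"].v_wall + w["S"].v_wall),
            "S": vm_s,
            "RV": vm_s + v_rv + 0.5 * (w["S"].v_wall + w["RV"].v_wall),
        }
        out = {}
        tx = ty = 0.0
        for name, wall in w.items():
            x, am, cm = cap_geometry(vm[name], y, self._x_warm.get(name))
            eps = 0.5 * math.log(am / wall.am_ref)
            mat = wall.material
            # clamp for solver exploration; converged strains are checked by
            # the caller via TriSegSolution.strain
            eps = max(-mat.eps_limit, min(mat.eps_limit, eps))
            # scalar fast path of the constitutive law (see segment_stress)
            length_dep = min((eps - mat.eps_act0) * mat.length_slope, 1.0)
            eps_prev = self._eps_prev.get(name)
            if eps_prev is not None and self.dt > 0.0:
                shortening = -(eps - eps_prev) / self.dt
                fv = min(max(1.0 - shortening / mat.v_max, 0.0), 1.1)
            else:
                fv = 1.0
            sig_a = mat.sigma_act * activation[name] * length_dep * fv \
                if length_dep > 0.0 else 0.0
            sig_p = mat.sigma_pas * math.expm1(mat.k_pas * eps) if eps > 0.0 else 0.0
            sig = (sig_a + sig_p) * wall.contractility_scale
            # wall tension includes the compressive recoil (diastolic
            # suction) plus a tiny odd-symmetric term that keeps the junction
            # equilibrium well-posed when walls are slack
            sig_solver = sig + recoil_stress(eps) + 0.1 * math.sinh(2.0 * eps)
            tm = wall_tension(sig_solver, wall.v_wall, am, cm)
            r2 = x * x + y * y
            tx += tm * 2.0 * x * y / r2
            ty += tm * (y * y - x * x) / r2
            out[name] = (x, am, cm, eps, sig, sig_p, tm)
        ty += self.ring_stiffness * (y - self.y_ref)
        return tx, ty, out

    def solve(self, v_lv: float, v_rv: float, activation: dict[str, float]) -> TriSegSolution:
        if v_lv <= 0 or v_rv <= 0:
            raise ValueError("cavity volumes must be positive")
        w = self.walls
        if self._warm is None:
            # start from a flat septum and a ring sized to the LV midwall sphere
            v_mid = v_lv + 0.5 * (w["LV"].v_wall + w["S"].v_wall)
            r = (3.0 * v_mid / (4.0 * math.pi)) ** (1.0 / 3.0)
            guess = (0.35 * v_lv, 0.95 * r)
        else:
            guess = self._warm
        vm_s, y = guess

        scale_t = sum(
            wall.material.sigma_act * wall.v_wall for wall in w.values()
        ) / (3 * 100.0) + 1e-6  # rough tension scale, kPa·cm

        def norm(vm: float, yy: float):
            tx, ty, out = self._evaluate(v_lv, v_rv, vm, yy, activation)
            return math.hypot(tx, ty) / scale_t, tx, ty, out

        def fresh_jacobian(vm: float, yy: float):
            # central differences, steps large enough to beat round-off
            dv = 1e-5 * (v_lv + v_rv)
            dy = 1e-5 * (1.0 + abs(yy))
            txp, typ, _ = self._evaluate(v_lv, v_rv, vm + dv, yy, activation)
            txm, tym, _ = self._evaluate(v_lv, v_rv, vm - dv, yy, activation)
            txq, tyq, _ = self._evaluate(v_lv, v_rv, vm, yy + dy, activation)
            txr, tyr, _ = self._evaluate(v_lv, v_rv, vm, yy - dy, activation)
            return ((txp - txm) / (2 * dv), (typ - tym) / (2 * dv),
                    (txq - txr) / (2 * dy), (tyq - tyr) / (2 * dy))

        res, tx, ty, out = norm(vm_s, y)
        lam_lm = 1e-3  # Levenberg-Marquardt damping, adapted per iteration
        jac = self._jac  # cached across calls: warm-started states move little
        jac_fresh = False
        for it in range(min(self.max_iter, 8)):
            if res < self.tol:
                self._warm = (vm_s, y)
                self._x_warm = {k: v[0] for k, v in out.items()}
                self._eps_prev = {k: v[3] for k, v in out.items()}
                self._jac = jac
                p_lv = -2.0 * out["LV"][6] * out["LV"][2]
                p_rv = 2.0 * out["RV"][6] * out["RV"][2]
                return TriSegSolution(
                    vm_sept=vm_s, y=y,
                    x={k: v[0] for k, v in out.items()},
                    am={k: v[1] for k, v in out.items()},
                    cm={k: v[2] for k, v in out.items()},
                    strain={k: v[3] for k, v in out.items()},
                    sigma_f={k: v[4] for k, v in out.items()},
                    sigma_pas={k: v[5] for k, v in out.items()},
                    tension={k: v[6] for k, v in out.items()},
                    residual=res,
                    p_lv_trans=p_lv, p_rv_trans=p_rv,
                )
            if jac is None:
                jac = fresh_jacobian(vm_s, y)
                jac_fresh = True
                lam_lm = 1e-3
            j11, j21, j12, j22 = jac
            # scaled Levenberg-Marquardt step on the residual sum of squares
            v_scale = 0.25 * (v_lv + v_rv + w["LV"].v_wall + w["RV"].v_wall)
            y_scale = 0.2 * (1.0 + y)
            a11 = j11 * j11 + j21 * j21 + lam_lm * (1.0 / v_scale) ** 2 * scale_t**2
            a22 = j12 * j12 + j22 * j22 + lam_lm * (1.0 / y_scale) ** 2 * scale_t**2
            a12 = j11 * j12 + j21 * j22
            b1 = -(j11 * tx + j21 * ty)
            b2 = -(j12 * tx + j22 * ty)
            det = a11 * a22 - a12 * a12
            if det == 0.0:
                jac = None
                continue
            step_v = max(-v_scale, min(v_scale, (b1 * a22 - b2 * a12) / det))
            step_y = max(-y_scale, min(y_scale, (a11 * b2 - a12 * b1) / det))
            res_try, tx_t, ty_t, out_t = norm(vm_s + step_v, max(0.3, y + step_y))
            if res_try < res:
                vm_s = vm_s + step_v
                y = max(0.3, y + step_y)
                slow = res_try > 0.3 * res
                res, tx, ty, out = res_try, tx_t, ty_t, out_t
                lam_lm = max(lam_lm / 3.0, 1e-12)
                if jac_fresh:
                    jac_fresh = False  # position moved: Jacobian now stale
                elif slow:
                    jac = None  # cached Jacobian converging too slowly
            elif not jac_fresh:
                jac = None  # stale cached Jacobian: recompute and retry
            else:
                lam_lm *= 10.0
                if lam_lm > 1e8:
                    break
        # robust fallback: Powell hybrid root finder from the best iterate
        from scipy.optimize import fsolve

        def residual_vec(z):
            txx, tyy, _ = self._evaluate(v_lv, v_rv, z[0], max(z[1], 0.3),
                                         activation)
            return [txx, tyy]

        sol, info, ier, _msg = fsolve(residual_vec, [vm_s, y], full_output=True)
        res_f, tx, ty, out = norm(sol[0], max(sol[1], 0.3))
        if res_f < self.tol:
            vm_s, y = float(sol[0]), float(max(sol[1], 0.3))
            res = res_f
            self._warm = (vm_s, y)
            self._x_warm = {k: v[0] for k, v in out.items()}
            self._eps_prev = {k: v[3] for k, v in out.items()}
            self._jac = None
            p_lv = -2.0 * out["LV"][6] * out["LV"][2]
            p_rv = 2.0 * out["RV"][6] * out["RV"][2]
            return TriSegSolution(
                vm_sept=vm_s, y=y,
                x={k: v[0] for k, v in out.items()},
                am={k: v[1] for k, v in out.items()},
                cm={k: v[2] for k, v in out.items()},
                strain={k: v[3] for k, v in out.items()},
                sigma_f={k: v[4] for k, v in out.items()},
                sigma_pas={k: v[5] for k, v in out.items()},
                tension={k: v[6] for k, v in out.items()},
                residual=res,
                p_lv_trans=p_lv, p_rv_trans=p_rv,
            )
        raise TriSegConvergenceError(min(res, res_f), (vm_s, y))


# --------------------------------------------------------------------------
# pericardium
# --------------------------------------------------------------------------

@dataclass
class Pericardium:
    """Non-linearly compliant pericardial sac.

    p = k·((V/V_ref)^s − 1): ≈ 0 at the reference volume, monotone and
    convex, rising steeply above it.  The enclosed volume is the sum of
    cavity and wall volumes plus the epicardial coronary blood volume (the
    pericardium surrounds the heart and the coronary circulation).
    """

    v_ref: float  # mL
    stiffness: float = 0.8  # mmHg
    exponent: float = 12.0
    include_coronary: bool = True

    def pressure(self, total_volume: float) -> float:
        return self.stiffness * ((total_volume / self.v_ref) ** self.exponent - 1.0)
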