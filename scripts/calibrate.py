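"""Calibrate the closed-loop model to its resting hemodynamic targets.

Stage A adjusts global ventricular contractility (a common scale on the
active-stress constants) and the systemic peripheral resistance by a damped
two-point secant until the uncontrolled closed loop settles at the
configured mean arterial pressure and cardiac output.  Stage B runs coronary
autoregulation (layer-wise secant on the reference arteriolar resistances)
until branch flows and the endo-to-epi ratio match their targets.  The
resulting constants are printed as a YAML overlay; the shipped defaults in
``coroflow.config`` were produced this way.

Usage:  python scripts/calibrate.py [--config cfg.yaml] [--out overlay.yaml]
"""

from __future__ import annotations

import argparse
import sys
import warnings

import numpy as np
import yaml

from coroflow.config import load_config, reference_config
from coroflow.engine import Simulator


def evaluate(cfg, sigma_scale: float, r_sys: float, beats: int = 50):
    cfg = cfg.model_copy(deep=True)
    for wall in (cfg.mechanics.lv, cfg.mechanics.septum, cfg.mechanics.rv):
        wall.sigma_act_kpa *= sigma_scale
    sim = Simulator(cfg)
    sim.r_sys = r_sys
    m = None
    for _ in range(beats):
        m, _ = sim.run_beat()
    return np.array([m["p_art"], m["q_av"] * 60.0 / 1000.0])


def calibrate_systemic(cfg, tol: float = 0.005, max_iter: int = 4):
    target = np.array([cfg.general.map_mmhg, cfg.general.co_l_min])
    s, r = 1.0, cfg.circulation.r_sys_init or 1.0
    y0 = evaluate(cfg, s, r)
    ds, dr = 0.04, 0.08
    ys = evaluate(cfg, s - ds, r)
    yr = evaluate(cfg, s, r + dr)
    jac = np.column_stack([(y0 - ys) / ds, (yr - y0) / dr])
    for it in range(max_iter):
        err = target - y0
        if np.all(np.abs(err / target) < tol):
            break
        du = np.linalg.solve(jac, err)
        s += float(np.clip(du[0], -0.1, 0.1))
        r += float(np.clip(du[1], -0.2, 0.2))
        y0 = evaluate(cfg, s, r, beats=60)
        print(f"  systemic iter {it}: scale={s:.4f} r_sys={r:.4f} "
              f"MAP={y0[0]:.2f} CO={y0[1]:.3f}")
    return s, r, y0


def main() -> int:
    warnings.filterwarnings("ignore", category=RuntimeWarning)
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=None)
    ap.add_argument("--out", default="calibrated.yaml")
    ap.add_argument("--skip-systemic", action="store_true")
    args = ap.parse_args()
    cfg = load_config(args.config) if args.config else reference_config()

    overlay: dict = {}
    if not args.skip_systemic:
        print("stage A: systemic calibration (contractility scale, r_sys)")
        s, r, y = calibrate_systemic(cfg)
        overlay["mechanics"] = {
            "lv": {"sigma_act_kpa": round(cfg.mechanics.lv.sigma_act_kpa * s, 3)},
            "septum": {"sigma_act_kpa": round(cfg.mechanics.septum.sigma_act_kpa * s, 3)},
            "rv": {"sigma_act_kpa": round(cfg.mechanics.rv.sigma_act_kpa * s, 3)},
        }
        overlay["circulation"] = {"r_sys_init": round(r, 4)}
        for wall in (cfg.mechanics.lv, cfg.mechanics.septum, cfg.mechanics.rv):
            wall.sigma_act_kpa *= s
        cfg.circulation.r_sys_init = r
        print(f"  result: scale={s:.4f} r_sys={r:.4f} MAP={y[0]:.2f} CO={y[1]:.3f}")

    print("stage B: coronary autoregulation")
    sim = Simulator(cfg)
    info = sim.autoregulate_reference()
    print(f"  converged in {info['iterations']} iterations "
          f"(max layer error {info['residual']:.4f})")
    overlay["tuned_r0_arteriolar"] = {
        branch: [round(float(x), 4) for x in sim.bed_r0_1[i]]
        for i, branch in enumerate(("LCx", "LAD", "RCA"))
    }
    with open(args.out, "w") as fh:
        yaml.safe_dump(overlay, fh, sort_keys=True)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
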