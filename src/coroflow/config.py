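"""Configuration schema, defaults, loading and validation.

A single YAML (or JSON) file describes a simulation: hemodynamic targets,
wall volumes, the coronary territory table, branch target flows, conduit
vessel geometry, valve orifice areas, microcirculatory wall-law constants,
myofiber material constants and solver settings.  The bundled
``data/reference.yaml`` encodes the reference resting conditions (a 70 kg
adult: heart rate 71 bpm, cardiac output 5.1 L/min, mean arterial pressure
91 mmHg, systolic duration 41% of the cycle, branch target flows
112/83/60 mL/min with endo-to-epi ratio 1.11, wall volumes 108/45/39 mL,
aortic orifice 4.8 cm²).

I/O units are clinical (mmHg, mL, mL/min, cm², bpm); values are validated
and defaults resolved on load.  Constants that the printed reference tables
do not pin down (vessel geometry, wall-law p0/k/A_w, myofiber material) are
exposed here with calibrated defaults (see docs/methods.md).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .network import REFERENCE_TERRITORY


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeneralConfig(_Model):
    hr_bpm: float = Field(71.0, gt=0)
    co_l_min: float = Field(5.1, gt=0)
    map_mmhg: float = Field(91.0, gt=0)
    systolic_duration_frac: float = Field(0.41, gt=0, lt=1)
    blood_volume_ml: float = Field(5000.0, gt=0)

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_bpm


class WallsConfig(_Model):
    lv_wall_volume: float = Field(108.0, gt=0)
    septal_wall_volume: float = Field(45.0, gt=0)
    rv_wall_volume: float = Field(39.0, gt=0)
    la_wall_volume: float = Field(10.0, gt=0)
    ra_wall_volume: float = Field(7.0, gt=0)


class BranchTarget(_Model):
    q0_ml_min: float = Field(..., gt=0)
    endo_epi_ratio: float = Field(1.11, gt=0)


class VesselConfig(_Model):
    length_cm: float = Field(..., gt=0)
    a_ref_cm2: float = Field(..., gt=0)
    p_ref_mmhg: float = Field(..., gt=0)
    k: float = Field(..., gt=3)
    aw_ratio: float = Field(0.2, gt=0)


class ValveConfig(_Model):
    area_cm2: float = Field(..., gt=0)
    l_eff_cm: float = Field(1.5, gt=0)


class ValvesConfig(_Model):
    mitral: ValveConfig = ValveConfig(area_cm2=6.0, l_eff_cm=8.0)
    aortic: ValveConfig = ValveConfig(area_cm2=4.8, l_eff_cm=10.0)
    tricuspid: ValveConfig = ValveConfig(area_cm2=7.0, l_eff_cm=8.0)
    pulmonary: ValveConfig = ValveConfig(area_cm2=5.0, l_eff_cm=14.0)


class WallMaterialConfig(_Model):
    sigma_act_kpa: float = Field(..., gt=0)
    length_slope: float = Field(2.857, gt=0)
    eps_act0: float = -0.10
    sigma_pas_kpa: float = Field(..., gt=0)
    k_pas: float = Field(16.0, gt=0)
    am_ref_cm2: float = Field(..., gt=0)
    eps_limit: float = Field(1.0, gt=0)
    v_max_strain_rate: float = Field(2.6, gt=0)


class MechanicsConfig(_Model):
    """One-fiber material constants; calibrated defaults (not printed in the
    reference tables)."""

    lv: WallMaterialConfig = WallMaterialConfig(sigma_act_kpa=112.0, sigma_pas_kpa=0.10,
                                                am_ref_cm2=81.0)
    septum: WallMaterialConfig = WallMaterialConfig(sigma_act_kpa=112.0, sigma_pas_kpa=0.10,
                                                    am_ref_cm2=33.7)
    rv: WallMaterialConfig = WallMaterialConfig(sigma_act_kpa=84.0, sigma_pas_kpa=0.30,
                                                am_ref_cm2=88.0)
    la: WallMaterialConfig = WallMaterialConfig(sigma_act_kpa=9.0, sigma_pas_kpa=0.35,
                                                am_ref_cm2=50.0, k_pas=12.0)
    ra: WallMaterialConfig = WallMaterialConfig(sigma_act_kpa=7.0, sigma_pas_kpa=0.35,
                                                am_ref_cm2=50.0, k_pas=12.0)
    twitch_rise_frac: float = Field(0.30, gt=0, lt=1)
    twitch_decay_frac: float = Field(0.35, gt=0, lt=1)
    atrial_onset_frac: float = Field(0.0, ge=0, lt=1)
    av_delay_frac: float = Field(0.17, ge=0, lt=1)
    atrial_duration_frac: float = Field(0.22, gt=0, lt=1)


class PericardiumConfig(_Model):
    stiffness_mmhg: float = Field(0.5, gt=0)
    exponent: float = Field(10.0, gt=1)
    v_ref_ml: float = Field(700.0, gt=0)
    include_coronary_volume: bool = True


class MicroConfig(_Model):
    """Microcirculatory wall-law constants (calibrated defaults)."""

    p0_epi_art: float = Field(85.0, gt=0)
    p0_epi_ven: float = Field(4.0, gt=0)
    p0_arteriolar: float = Field(52.0, gt=0)
    p0_venular: float = Field(2.5, gt=0)
    k_art: float = Field(12.0, gt=3)
    k_ven: float = Field(10.0, gt=3)
    k_arteriole: float = Field(44.0, gt=3)
    k_venule: float = Field(8.0, gt=3)
    aw_epi_art: float = Field(0.5, gt=0)
    aw_epi_ven: float = Field(0.3, gt=0)
    aw_arteriole: float = Field(0.3, gt=0)
    aw_venule: float = Field(0.3, gt=0)
    # reference volumes (mL) at LAD-scale flow (83 mL/min); scaled per branch
    v0_epi_art: float = Field(0.8, gt=0)
    v0_epi_ven: float = Field(2.0, gt=0)
    v0_arteriolar: float = Field(3.6, gt=0)
    v0_venular: float = Field(3.6, gt=0)
    gamma: float = Field(0.06, ge=0)
    p_ra_mean_mmhg: float = Field(4.0, gt=0)


class CirculationConfig(_Model):
    # initial venous volume trim (mL), part of the resting calibration
    venous_volume_offset_ml: float = 20.0
    # calibrated initial systemic peripheral resistance (mmHg·s/mL); when
    # None it is derived from the MAP/CO targets minus the conduit
    # wave-impedance drop
    r_sys_init: float | None = 0.995
    p_pulm_art_mean: float = Field(15.0, gt=0)
    p_la_mean: float = Field(8.0, gt=0)
    venous_inlet_resistance: float = Field(0.06, gt=0)
    cs_inlet_resistance: float = Field(0.05, gt=0)


class SolverConfig(_Model):
    dt_s: float = Field(0.001, gt=0)
    max_beats: int = Field(200, gt=0)
    periodicity_tol: float = Field(1e-3, gt=0)
    homeostasis_gain: float = Field(0.5, gt=0, le=1)
    autoreg_tol: float = Field(0.01, gt=0)
    tube_coupling_z_frac: float = Field(0.4, ge=0)
    autoreg_max_iter: int = Field(26, gt=0)
    scheme: str = "euler"

    @field_validator("scheme")
    @classmethod
    def _scheme(cls, v):
        if v not in ("euler", "rk4"):
            raise ValueError("scheme must be 'euler' or 'rk4'")
        return v


_DEFAULT_VESSELS: dict[str, dict] = {
    "sys_art": dict(length_cm=55, a_ref_cm2=7.0, p_ref_mmhg=91, k=8, aw_ratio=0.2),
    "sys_ven": dict(length_cm=40, a_ref_cm2=9.0, p_ref_mmhg=4, k=10, aw_ratio=0.1),
    "pulm_art": dict(length_cm=15, a_ref_cm2=5.0, p_ref_mmhg=15, k=8, aw_ratio=0.2),
    "pulm_ven": dict(length_cm=15, a_ref_cm2=9.0, p_ref_mmhg=6, k=10, aw_ratio=0.1),
    "cor_lm": dict(length_cm=2.5, a_ref_cm2=0.28, p_ref_mmhg=91, k=18, aw_ratio=0.5),
    "cor_lad": dict(length_cm=9, a_ref_cm2=0.08, p_ref_mmhg=91, k=18, aw_ratio=0.5),
    "cor_lcx": dict(length_cm=8, a_ref_cm2=0.065, p_ref_mmhg=91, k=18, aw_ratio=0.5),
    "cor_rca": dict(length_cm=9, a_ref_cm2=0.11, p_ref_mmhg=91, k=18, aw_ratio=0.5),
    "cor_lad_vein": dict(length_cm=10, a_ref_cm2=0.25, p_ref_mmhg=5, k=10, aw_ratio=0.3),
    "cor_lcx_vein": dict(length_cm=9, a_ref_cm2=0.20, p_ref_mmhg=5, k=10, aw_ratio=0.3),
    "cor_rca_vein": dict(length_cm=10, a_ref_cm2=0.30, p_ref_mmhg=5, k=10, aw_ratio=0.3),
    "cor_cs_dist": dict(length_cm=3, a_ref_cm2=0.5, p_ref_mmhg=5, k=10, aw_ratio=0.3),
    "cor_cs_prox": dict(length_cm=2, a_ref_cm2=0.7, p_ref_mmhg=5, k=10, aw_ratio=0.3),
}


class Config(_Model):
    general: GeneralConfig = GeneralConfig()
    walls: WallsConfig = WallsConfig()
    territory_table: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {b: dict(w) for b, w in REFERENCE_TERRITORY.items()}
    )
    coronary_targets: dict[str, BranchTarget] = Field(
        default_factory=lambda: {
            "RCA": BranchTarget(q0_ml_min=112.0),
            "LAD": BranchTarget(q0_ml_min=83.0),
            "LCx": BranchTarget(q0_ml_min=60.0),
        }
    )
    vessels: dict[str, VesselConfig] = Field(
        default_factory=lambda: {n: VesselConfig(**d) for n, d in _DEFAULT_VESSELS.items()}
    )
    valves: ValvesConfig = ValvesConfig()
    mechanics: MechanicsConfig = MechanicsConfig()
    pericardium: PericardiumConfig = PericardiumConfig()
    micro: MicroConfig = MicroConfig()
    circulation: CirculationConfig = CirculationConfig()
    solver: SolverConfig = SolverConfig()


class ConfigError(ValueError):
    pass


def _deep_update(base: dict, overlay: dict) -> dict:
    for key, val in overlay.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Load and validate a configuration file (YAML or JSON).

    Missing sections fall back to the built-in defaults; ``overrides``
    (nested dict) is applied last.  Raises :class:`ConfigError` listing every
    offending key on schema violations.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
    if overrides:
        _deep_update(data, overrides)
    try:
        return Config(**data)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {issues}") from exc


def dump_config(config: Config, path: str | Path) -> None:
    """Serialize a resolved configuration back to YAML (round-trips exactly)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))


def reference_config() -> Config:
    """The bundled reference configuration (resting 70 kg adult)."""
    ref = resources.files("coroflow.data") / "reference.yaml"
    with resources.as_file(ref) as p:
        return load_config(p)
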