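"""Waveform metrics of a converged beat.

Phase segmentation follows the LV ejection interval: the systolic window is
bracketed by aortic valve opening and closure (the convention used when
comparing against Doppler tracings), and the diastolic window is the rest of
the cycle, isovolumic phases included.  End-diastole is taken at mitral
valve closure and end-systole at aortic valve closure.  Velocity–time
integrals use the antegrade (positive-clipped) velocity, mirroring Doppler
envelope tracing; retrograde flow is reported separately as a retrograde
fraction.

All metric functions are pure: the same beat record yields bit-identical
results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .micro import LAYERS
from .network import BRANCHES
from .record import BeatRecord


class MetricError(ValueError):
    pass


@dataclass
class PhaseSegmentation:
    """Systole/diastole windows of one beat (times in s from beat start)."""

    t_ed: float  # mitral closure
    t_es: float  # aortic closure
    t_eject_start: float  # aortic opening
    t_eject_end: float  # aortic closure
    period: float
    isovolumic_in_systole: bool = False

    @classmethod
    def from_record(cls, rec: BeatRecord,
                    isovolumic_in_systole: bool = False) -> "PhaseSegmentation":
        ev = rec.events
        for key in ("aortic_open", "aortic_close"):
            if key not in ev:
                raise MetricError(f"beat record lacks valve event {key!r}; "
                                  "not a converged ejecting beat")
        return cls(
            t_ed=ev.get("mitral_close", ev["aortic_open"]),
            t_es=ev["aortic_close"],
            t_eject_start=ev["aortic_open"],
            t_eject_end=ev["aortic_close"],
            period=rec.period,
            isovolumic_in_systole=isovolumic_in_systole,
        )

    def systolic_mask(self, rec: BeatRecord) -> np.ndarray:
        start = self.t_ed if self.isovolumic_in_systole else self.t_eject_start
        return rec.window_mask(start, self.t_eject_end)

    def diastolic_mask(self, rec: BeatRecord) -> np.ndarray:
        return ~self.systolic_mask(rec)


def _index_of(rec: BeatRecord, t: float) -> int:
    return int(round(t / rec.dt)) % rec.n


def pdsvr(velocity: np.ndarray, rec: BeatRecord, phases: PhaseSegmentation) -> float:
    """Peak diastolic-to-systolic velocity ratio.

    Returns NaN (flagged undefined) when the systolic peak is not positive.
    """
    v = np.asarray(velocity, float)
    sys_peak = float(v[phases.systolic_mask(rec)].max())
    dia_peak = float(v[phases.diastolic_mask(rec)].max())
    if sys_peak <= 0.0:
        return float("nan")
    return dia_peak / sys_peak


def dtvi(velocity: np.ndarray, rec: BeatRecord, phases: PhaseSegmentation) -> float:
    """Diastolic-to-total velocity–time integral (antegrade convention).

    Velocity is clipped at zero before integration; returns NaN when the
    total integral vanishes.  Lies in [0, 1] by construction.
    """
    v = np.clip(np.asarray(velocity, float), 0.0, None)
    total = float(v.sum())
    if total <= 0.0:
        return float("nan")
    return float(v[phases.diastolic_mask(rec)].sum()) / total


def retrograde_fraction(velocity: np.ndarray) -> float:
    """|retrograde| velocity–time integral over the antegrade integral."""
    v = np.asarray(velocity, float)
    ante = float(np.clip(v, 0.0, None).sum())
    retro = float(-np.clip(v, None, 0.0).sum())
    return retro / ante if ante > 0 else float("inf")


def diameter_change_ed_es(volume: np.ndarray, rec: BeatRecord,
                          phases: PhaseSegmentation) -> float:
    """Percent diameter change from end-diastole to end-systole.

    d ∝ sqrt(V) (circular cross-section, constant length); negative values
    mean systolic compression.
    """
    v = np.asarray(volume, float)
    d_ed = math_sqrt(v[_index_of(rec, phases.t_ed)])
    d_es = math_sqrt(v[_index_of(rec, phases.t_es)])
    return 100.0 * (d_es - d_ed) / d_ed


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


def endo_epi_ratio(rec: BeatRecord, branch: str) -> float:
    """Beat-averaged subendocardial over subepicardial arteriolar flow."""
    b = branch.lower()
    return rec.mean(f"q1_{b}_subendo") / rec.mean(f"q1_{b}_subepi")


def mean_transvalvular_gradient(rec: BeatRecord) -> float:
    """Time-average of the LV→aorta pressure difference during forward flow."""
    q = rec["q_aortic"]
    fwd = q > 0.0
    if not fwd.any():
        raise MetricError("no forward aortic flow in beat")
    return float(rec["dp_av"][fwd].mean())


def summary_table(rec: BeatRecord, scenario: str = "reference") -> pd.DataFrame:
    """Long-format metrics table (scenario, site, metric, value, units)."""
    required = ["q_aortic", "p_ao", "p_lv", "u_aortic", "q_cor_cs_dist"]
    missing = [c for c in required if c not in rec.channels]
    if missing:
        raise MetricError(f"beat record missing channels: {missing}")
    phases = PhaseSegmentation.from_record(rec)
    rows: list[tuple[str, str, float, str]] = []

    def add(site: str, metric: str, value: float, units: str) -> None:
        rows.append((site, metric, float(value), units))

    add("systemic", "cardiac_output", rec.mean("q_aortic") * 60.0 / 1000.0, "L/min")
    add("systemic", "mean_arterial_pressure", rec.mean("p_aorta"), "mmHg")
    add("LV", "peak_pressure", rec["p_lv"].max(), "mmHg")
    add("aortic_valve", "mean_gradient", mean_transvalvular_gradient(rec), "mmHg")
    add("aortic_valve", "peak_velocity", rec["u_aortic"].max(), "m/s")
    add("coronary_sinus", "mean_flow", rec.mean("q_cor_cs_dist") * 60.0, "mL/min")

    for branch in BRANCHES:
        b = branch.lower()
        add(branch, "mean_flow", rec.mean(f"q_{b}_in") * 60.0, "mL/min")
        add(branch, "endo_epi_ratio", endo_epi_ratio(rec, branch), "-")
        u = rec[f"u_cor_{b}"]
        add(branch, "pdsvr", pdsvr(u, rec, phases), "-")
        add(branch, "dtvi", dtvi(u, rec, phases), "-")
        add(branch, "peak_systolic_velocity",
            u[phases.systolic_mask(rec)].max(), "m/s")
        add(branch, "retrograde_fraction", retrograde_fraction(u), "-")
        for layer in LAYERS:
            add(branch, f"diameter_change_arteriolar_{layer}",
                diameter_change_ed_es(rec[f"v1_{b}_{layer}"], rec, phases), "%")
            add(branch, f"diameter_change_venular_{layer}",
                diameter_change_ed_es(rec[f"v2_{b}_{layer}"], rec, phases), "%")
    df = pd.DataFrame(rows, columns=["site", "metric", "value", "units"])
    df.insert(0, "scenario", scenario)
    return df


def write_outputs(rec: BeatRecord, out_dir: str | Path,
                  scenario: str = "reference") -> dict[str, Path]:
    """Write beat.csv, events.json, metrics.csv and metrics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beat_path = out / f"beat_{scenario}.csv"
    rec.to_dataframe().to_csv(beat_path, index=False)
    events_path = out / f"events_{scenario}.json"
    events_path.write_text(json.dumps(
        {"dt": rec.dt, "events": rec.events, "meta": {
            k: v for k, v in rec.meta.items() if isinstance(v, (int, float, str))
        }}, indent=2, sort_keys=True))
    table = summary_table(rec, scenario)
    metrics_path = out / f"metrics_{scenario}.csv"
    table.to_csv(metrics_path, index=False)
    json_path = out / f"metrics_{scenario}.json"
    payload = {
        f"{site}/{metric}": value
        for site, metric, value in zip(table["site"], table["metric"], table["value"])
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"beat": beat_path, "events": events_path,
            "metrics": metrics_path, "json": json_path}


def read_beat(beat_csv: str | Path, events_json: str | Path) -> BeatRecord:
    """Rebuild a :class:`BeatRecord` from the long-format CSV and events file."""
    df = pd.read_csv(beat_csv)
    wide = df.pivot(index="t", columns="channel", values="value").sort_index()
    info = json.loads(Path(events_json).read_text())
    return BeatRecord(dt=float(info["dt"]),
                      channels={c: wide[c].to_numpy() for c in wide.columns},
                      events=dict(info["events"]), meta=dict(info.get("meta", {})))
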