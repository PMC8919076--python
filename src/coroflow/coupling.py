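"""Cardiac-to-coronary coupling: transmurally varying intramyocardial pressure.

The intramyocardial pressure (IMP) compressing the intramural coronary
vessels of a layer at radial position r (0 = epicardium, 1 = endocardium) is
the sum of two mechanisms:

    IMP = CEP + VE
    CEP = r·P1 + (1 − r)·P2
    VE  = γ·σ_f

CEP (cavity-induced extracellular pressure) interpolates linearly from the
adjacent cavity pressure P1 at the endocardium to P2 at the epicardium: for
the LV free wall P1 = LV pressure and P2 = pericardial pressure, for the RV
free wall P1 = RV pressure and P2 = pericardial pressure, and for the septum
the gradient runs from LV pressure (LV-facing subendocardium, r = 5/6) to RV
pressure.  VE (varying elastance) models myocardial stiffening and is
proportional to the segment's total (active + passive) fiber stress through
the scaling γ (default 0.06, shared by all walls, chosen so that peak VE is
roughly 20% of peak LV pressure).  A branch's layer IMP is the volume-
weighted average over the myocardial segments of its territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .micro import LAYER_RADIAL_POSITION, LAYERS
from .network import BRANCHES, ConfigurationError, TerritoryTable, WallSpec
from .units import KPA_TO_MMHG

GAMMA_DEFAULT = 0.06


def cep(r, p1, p2):
    """Cavity-induced extracellular pressure at relative depth r.

    Linear interpolation: CEP → P1 (cavity) as r → 1, → P2 as r → 0.
    """
    r = np.asarray(r, dtype=float)
    return r * p1 + (1.0 - r) * p2


def ve(sigma_f_kpa, gamma: float = GAMMA_DEFAULT):
    """Varying-elastance pressure (mmHg) from fiber stress (kPa).

    VE = γ·σ_f, applied uniformly across the layers of a segment.  The unit
    conversion kPa → mmHg is enforced here, at the module boundary.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return gamma * np.asarray(sigma_f_kpa, dtype=float) * KPA_TO_MMHG


def branch_imp(per_segment_imp: np.ndarray, territory_weights: np.ndarray) -> np.ndarray:
    """Volume-weighted branch IMP per layer.

    ``per_segment_imp``: (n_segments, n_layers); ``territory_weights``:
    (n_segments,) wall volumes of the branch territory (normalized here).
    """
    w = np.asarray(territory_weights, dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("empty coronary territory")
    w = w / w.sum()
    return w @ np.asarray(per_segment_imp, dtype=float)


@dataclass
class IMPState:
    """Per-branch × per-layer IMP decomposition for one time point (mmHg)."""

    cep: np.ndarray  # (3 branches, 3 layers)
    ve: np.ndarray
    gamma: float = GAMMA_DEFAULT

    @property
    def imp(self) -> np.ndarray:
        return self.cep + self.ve


class IMPCalculator:
    """Precomputes territory weights; maps wall states to branch-layer IMP.

    Wall CEP endpoints: P1/P2 per wall as described in the module docstring.
    Septal r is measured from the RV side so that r = 5/6 faces the LV
    cavity.  With uniform material properties all segments of a wall share
    σ_f, so the weighted average reduces to wall-level weights (fractions of
    branch territory mass per wall).
    """

    def __init__(self, walls: list[WallSpec], territory: TerritoryTable,
                 gamma: float = GAMMA_DEFAULT):
        self.gamma = gamma
        wall_names = [w.name for w in walls]
        masses = {w.name: w.mass() for w in walls}
        self.wall_names = wall_names
        # (branches, walls) territory mass weights, normalized per branch
        wmat = np.array([
            [territory.fraction(b, w) * masses[w] for w in wall_names]
            for b in BRANCHES
        ])
        totals = wmat.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ConfigurationError("branch with empty territory")
        self.weights = wmat / totals

    def compute(self, p_lv: float, p_rv: float, p_peri: float,
                sigma_f_kpa: dict[str, float]) -> IMPState:
        """IMP per branch × layer from instantaneous cavity/pericardial
        pressures (mmHg) and per-wall fiber stress (kPa)."""
        r = LAYER_RADIAL_POSITION
        endpoints = {
            "LV": (p_lv, p_peri),
            "S": (p_lv, p_rv),
            "RV": (p_rv, p_peri),
        }
        cep_walls = np.array([cep(r, *endpoints[w]) for w in self.wall_names])
        ve_walls = np.array([
            np.full(len(LAYERS), float(ve(sigma_f_kpa[w], self.gamma)))
            for w in self.wall_names
        ])
        return IMPState(cep=self.weights @ cep_walls,
                        ve=self.weights @ ve_walls,
                        gamma=self.gamma)
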