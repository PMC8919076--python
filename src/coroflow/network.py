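"""Closed-loop network topology, wall segmentation and coronary territories.

The heart is represented by five walls (LV free wall, septum, RV free wall,
and the two atrial walls).  The LV free wall and septum are subdivided into
12 and 5 segments respectively so that individual myocardial segments can be
assigned to the perfusion territory of one of the three main coronary
branches (LCx, LAD, RCA).  Branch territories are quantified as the fraction
of each wall's mass supplied by each branch; the per-wall fractions for the
reference heart are

====== ======= ====== =======
branch RV wall S wall LV wall
====== ======= ====== =======
LCx     0       0      0.42
LAD     0       0.60   0.33
RCA     1.00    0.40   0.25
====== ======= ====== =======

The vascular side is a closed graph: ventricles eject through valves into
1D conduit vessels, coronary arteries stem from the ascending aorta, each
branch perfuses a lumped three-layer microcirculatory bed draining into its
own epicardial vein, and the veins reunite in the coronary sinus which
empties into the right atrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .units import MYOCARDIAL_DENSITY

BRANCHES = ("LCx", "LAD", "RCA")
VENTRICULAR_WALLS = ("LV", "S", "RV")

#: reference per-wall territory fractions (branch → wall → fraction)
REFERENCE_TERRITORY = {
    "LCx": {"RV": 0.0, "S": 0.0, "LV": 0.42},
    "LAD": {"RV": 0.0, "S": 0.60, "LV": 0.33},
    "RCA": {"RV": 1.0, "S": 0.40, "LV": 0.25},
}


class ConfigurationError(ValueError):
    """Raised when a network description is internally inconsistent."""


@dataclass
class WallSpec:
    """One myocardial wall: volume, segmentation and per-segment mass split."""

    name: str
    wall_volume: float  # mL
    n_segments: int
    segment_mass_fractions: list[float] | None = None

    def __post_init__(self) -> None:
        if self.wall_volume <= 0:
            raise ConfigurationError(f"wall {self.name}: volume must be > 0")
        if self.n_segments < 1:
            raise ConfigurationError(f"wall {self.name}: needs >= 1 segment")
        if self.segment_mass_fractions is None:
            # per-segment masses are not independently specified: default uniform
            self.segment_mass_fractions = [1.0 / self.n_segments] * self.n_segments
        if len(self.segment_mass_fractions) != self.n_segments:
            raise ConfigurationError(
                f"wall {self.name}: {len(self.segment_mass_fractions)} fractions "
                f"for {self.n_segments} segments"
            )
        if abs(sum(self.segment_mass_fractions) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"wall {self.name}: segment mass fractions must sum to 1"
            )

    def mass(self, density: float = MYOCARDIAL_DENSITY) -> float:
        """Wall mass in grams (volume × myocardial density)."""
        return self.wall_volume * density


@dataclass
class TerritoryTable:
    """Fraction of each wall's mass assigned to each coronary branch."""

    fractions: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        walls: set[str] = set()
        for branch, per_wall in self.fractions.items():
            if branch not in BRANCHES:
                raise ConfigurationError(f"unknown coronary branch {branch!r}")
            walls.update(per_wall)
            for wall, frac in per_wall.items():
                if not 0.0 <= frac <= 1.0:
                    raise ConfigurationError(
                        f"territory fraction {branch}/{wall} = {frac} outside [0, 1]"
                    )
        for wall in walls:
            total = sum(self.fractions[b].get(wall, 0.0) for b in self.fractions)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"territory fractions for wall {wall} sum to {total}, not 1"
                )

    def fraction(self, branch: str, wall: str) -> float:
        return self.fractions.get(branch, {}).get(wall, 0.0)

    @classmethod
    def reference(cls) -> "TerritoryTable":
        return cls({b: dict(w) for b, w in REFERENCE_TERRITORY.items()})


def territory_masses(
    walls: list[WallSpec],
    table: TerritoryTable,
    density: float = MYOCARDIAL_DENSITY,
) -> dict[str, float]:
    """Myocardial mass (g) perfused by each branch.

    branch mass = Σ_walls fraction(branch, wall) × wall mass.  The masses of
    all branches sum to the total ventricular mass.
    """
    if density <= 0:
        raise ConfigurationError("density must be > 0")
    out: dict[str, float] = {}
    for branch in BRANCHES:
        out[branch] = sum(
            table.fraction(branch, w.name) * w.mass(density) for w in walls
        )
        if branch in table.fractions and out[branch] == 0.0 and any(
            table.fraction(branch, w.name) > 0 for w in walls
        ):
            pass
    if all(m == 0.0 for m in out.values()):
        raise ConfigurationError("empty territory assignment")
    return out


# --------------------------------------------------------------------------
# vascular graph
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselEdge:
    """A 1D conduit vessel between two named junction nodes."""

    name: str
    prox_node: str
    dist_node: str
    kind: str  # "artery" | "vein"


@dataclass(frozen=True)
class ValveEdge:
    name: str
    upstream: str
    downstream: str


@dataclass(frozen=True)
class BedEdge:
    """A perfusion bed (systemic, pulmonary, or one coronary branch)."""

    name: str
    inlet_node: str
    outlet_node: str


@dataclass
class NetworkTopology:
    """Closed-loop graph of cavities, valves, conduit vessels and beds."""

    cavities: list[str]
    vessels: list[VesselEdge]
    valves: list[ValveEdge]
    beds: list[BedEdge]
    walls: list[WallSpec] = field(default_factory=list)
    territory: TerritoryTable | None = None

    def vessel(self, name: str) -> VesselEdge:
        for v in self.vessels:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def coronary_arteries(self) -> list[VesselEdge]:
        return [v for v in self.vessels if v.kind == "artery" and v.name.startswith("cor_")]

    @property
    def coronary_veins(self) -> list[VesselEdge]:
        return [v for v in self.vessels if v.kind == "vein" and v.name.startswith("cor_")]

    def validate(self) -> None:
        names = [v.name for v in self.vessels]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate vessel name(s): {sorted(dupes)}")

        # every node referenced by a vessel end must have a second attachment
        # (another vessel end, a valve, a bed, or a cavity): closed loop.
        attachments: dict[str, int] = {}
        def tally(node: str) -> None:
            attachments[node] = attachments.get(node, 0) + 1

        for v in self.vessels:
            tally(v.prox_node)
            tally(v.dist_node)
        for valve in self.valves:
            for node in (valve.upstream, valve.downstream):
                if node not in self.cavities:
                    tally(node)
        for bed in self.beds:
            tally(bed.inlet_node)
            tally(bed.outlet_node)

        unconnected = sorted(n for n, c in attachments.items() if c < 2 and n not in self.cavities)
        if unconnected:
            raise ConfigurationError(f"unconnected node(s): {unconnected}")

        # LM must bifurcate into LCx and LAD
        lm = [v for v in self.vessels if v.name == "cor_lm"]
        if lm:
            children = sorted(
                v.name for v in self.vessels if v.prox_node == lm[0].dist_node and v is not lm[0]
            )
            if children != ["cor_lad", "cor_lcx"]:
                raise ConfigurationError(
                    "LM must bifurcate into LAD and LCx, found children "
                    f"{children or 'none'}"
                )

        # connectivity of the undirected graph
        adj: dict[str, set[str]] = {}
        def link(a: str, b: str) -> None:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)

        for v in self.vessels:
            link(v.prox_node, v.dist_node)
        for valve in self.valves:
            link(valve.upstream, valve.downstream)
        for bed in self.beds:
            link(bed.inlet_node, bed.outlet_node)
        start = next(iter(adj))
        seen = {start}
        stack = [start]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        missing = sorted(set(adj) - seen)
        if missing:
            raise ConfigurationError(f"graph not closed; unreachable: {missing}")


def build_reference_network(config=None) -> NetworkTopology:
    """Reference closed-loop topology.

    Four coronary arteries (LM, LCx, LAD, RCA) stem from the aortic root;
    each branch bed drains into its own epicardial vein.  The left veins
    join the distal coronary sinus; the right coronary vein enters at the
    distal end of that segment, and the proximal coronary sinus carries the
    confluent flow into the right atrium.  Systemic and pulmonary loops
    close the circulation.

    ``config`` may carry wall volumes and a territory table (see
    :mod:`coroflow.config`); when omitted the reference values are used.
    """
    if config is not None:
        walls = [
            WallSpec("LV", config.walls.lv_wall_volume, 12),
            WallSpec("S", config.walls.septal_wall_volume, 5),
            WallSpec("RV", config.walls.rv_wall_volume, 1),
        ]
        territory = TerritoryTable(config.territory_table)
    else:
        walls = [WallSpec("LV", 108.0, 12), WallSpec("S", 45.0, 5), WallSpec("RV", 39.0, 1)]
        territory = TerritoryTable.reference()

    vessels = [
        VesselEdge("sys_art", "ao_root", "sys_cap", "artery"),
        VesselEdge("sys_ven", "sys_cap_v", "ra_inlet", "vein"),
        VesselEdge("pulm_art", "pa_root", "pulm_cap", "artery"),
        VesselEdge("pulm_ven", "pulm_cap_v", "la_inlet", "vein"),
        VesselEdge("cor_lm", "ao_root", "lm_bif", "artery"),
        VesselEdge("cor_lad", "lm_bif", "lad_bed_in", "artery"),
        VesselEdge("cor_lcx", "lm_bif", "lcx_bed_in", "artery"),
        VesselEdge("cor_rca", "ao_root", "rca_bed_in", "artery"),
        VesselEdge("cor_lad_vein", "lad_bed_out", "cs_left", "vein"),
        VesselEdge("cor_lcx_vein", "lcx_bed_out", "cs_left", "vein"),
        VesselEdge("cor_rca_vein", "rca_bed_out", "cs_right", "vein"),
        VesselEdge("cor_cs_dist", "cs_left", "cs_right", "vein"),
        VesselEdge("cor_cs_prox", "cs_right", "cs_ra", "vein"),
    ]
    valves = [
        ValveEdge("mitral", "LA", "LV"),
        ValveEdge("aortic", "LV", "ao_root"),
        ValveEdge("tricuspid", "RA", "RV"),
        ValveEdge("pulmonary", "RV", "pa_root"),
        ValveEdge("sys_ven_inlet", "ra_inlet", "RA"),
        ValveEdge("pulm_ven_inlet", "la_inlet", "LA"),
        ValveEdge("cs_inlet", "cs_ra", "RA"),
    ]
    beds = [
        BedEdge("systemic", "sys_cap", "sys_cap_v"),
        BedEdge("pulmonary", "pulm_cap", "pulm_cap_v"),
        BedEdge("LAD", "lad_bed_in", "lad_bed_out"),
        BedEdge("LCx", "lcx_bed_in", "lcx_bed_out"),
        BedEdge("RCA", "rca_bed_in", "rca_bed_out"),
    ]
    topo = NetworkTopology(
        cavities=["LA", "RA", "LV", "RV"],
        vessels=vessels,
        valves=valves,
        beds=beds,
        walls=walls,
        territory=territory,
    )
    topo.validate()
    return topo
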