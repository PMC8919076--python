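"""Topology, wall segmentation and coronary territory arithmetic."""

import pytest

from coroflow.network import (ConfigurationError, NetworkTopology, TerritoryTable,
                              VesselEdge, WallSpec, build_reference_network,
                              territory_masses)


def walls_with_masses(lv=114.0, s=47.0, rv=41.0, density=1.055):
    """Walls whose masses are exactly the stated gram values."""
    return [
        WallSpec("LV", lv / density, 12),
        WallSpec("S", s / density, 5),
        WallSpec("RV", rv / density, 1),
    ]


class TestTerritoryMasses:
    def test_reference_branch_masses(self):
        masses = territory_masses(walls_with_masses(), TerritoryTable.reference())
        # RCA = 41 + 0.40*47 + 0.25*114; LAD = 0.60*47 + 0.33*114; LCx = 0.42*114
        assert masses["RCA"] == pytest.approx(88.3, abs=1e-9)
        assert masses["LAD"] == pytest.approx(65.82, abs=1e-9)
        assert masses["LCx"] == pytest.approx(47.88, abs=1e-9)

    def test_masses_sum_to_total_heart_mass(self):
        masses = territory_masses(walls_with_masses(), TerritoryTable.reference())
        assert sum(masses.values()) == pytest.approx(202.0, abs=1e-9)

    def test_identity_fraction(self):
        table = TerritoryTable({
            "LCx": {"LV": 1.0, "S": 0.0, "RV": 0.0},
            "LAD": {"LV": 0.0, "S": 1.0, "RV": 0.0},
            "RCA": {"LV": 0.0, "S": 0.0, "RV": 1.0},
        })
        masses = territory_masses(walls_with_masses(), table)
        assert masses["LCx"] == pytest.approx(114.0)

    def test_wall_mass_density_rounding(self):
        # 108 mL of myocardium at 1.055 g/mL is the stated 114 g LV mass
        assert WallSpec("LV", 108.0, 12).mass() == pytest.approx(114.0, abs=0.2)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            TerritoryTable({"LCx": {"LV": 0.5}, "LAD": {"LV": 0.2},
                            "RCA": {"LV": 0.2}})


class TestWallSpec:
    def test_uniform_segment_fractions_default(self):
        w = WallSpec("LV", 108.0, 12)
        assert len(w.segment_mass_fractions) == 12
        assert sum(w.segment_mass_fractions) == pytest.approx(1.0, abs=1e-12)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ConfigurationError):
            WallSpec("S", 45.0, 2, segment_mass_fractions=[0.6, 0.6])


class TestTopology:
    def test_reference_network_counts(self):
        topo = build_reference_network()
        assert len(topo.coronary_arteries) == 4
        assert len(topo.coronary_veins) == 5
        assert topo.walls[0].n_segments == 12  # LV free wall
        assert topo.walls[1].n_segments == 5   # septum

    def test_lm_must_bifurcate(self):
        topo = build_reference_network()
        # remove the whole LCx branch so the only defect is the LM bifurcation
        topo.vessels = [v for v in topo.vessels
                        if v.name not in ("cor_lcx", "cor_lcx_vein")]
        topo.beds = [b for b in topo.beds if b.name != "LCx"]
        with pytest.raises(ConfigurationError, match="bifurcate"):
            topo.validate()

    def test_duplicate_vessel_name_rejected(self):
        topo = build_reference_network()
        topo.vessels.append(topo.vessels[0])
        with pytest.raises(ConfigurationError, match="duplicate"):
            topo.validate()

    def test_unconnected_node_rejected(self):
        topo = build_reference_network()
        topo.vessels.append(VesselEdge("stray", "nowhere_a", "nowhere_b", "artery"))
        with pytest.raises(ConfigurationError):
            topo.validate()
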