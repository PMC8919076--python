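"""Coronary territory masses and reference resistance ladder.

Builds the reference heart (wall masses 114/47/41 g), assigns each wall's
mass to the three coronary branches, and sizes one bed's reference
resistances from its target flow.  Everything here is closed-form
arithmetic — no simulation.
"""

from coroflow import TerritoryTable, WallSpec, territory_masses
from coroflow.micro import layer_target_flows, reference_resistances

walls = [WallSpec("LV", 114.0 / 1.055, 12), WallSpec("S", 47.0 / 1.055, 5),
         WallSpec("RV", 41.0 / 1.055, 1)]
masses = territory_masses(walls, TerritoryTable.reference())

print("perfusion territory masses (g):")
for branch, mass in masses.items():
    print(f"  {branch}: {mass:6.2f}")
print(f"  total: {sum(masses.values()):6.2f}  (= whole ventricular mass)")

# LAD bed: 83 mL/min target, endo/epi 1.11, perfusion pressure 94 → 4 mmHg
q_layer = layer_target_flows(83.0 / 60.0, 1.11)
res = reference_resistances(q_layer, 94.0, 4.0)
print("\nLAD bed reference resistances (mmHg·s/mL):")
print(f"  total            {res['R_total']:6.2f}   (= 90 mmHg / 1.383 mL/s)")
print(f"  epicardial art.  {res['R_a']:6.2f}   (28%)")
print(f"  epicardial ven.  {res['R_v']:6.2f}   (7%)")
for i, layer in enumerate(("subepi", "mid", "subendo")):
    print(f"  {layer:8s} R1/Rm/R2 {res['R1'][i]:6.1f} /{res['Rm'][i]:6.1f} /"
          f"{res['R2'][i]:6.1f}  (60:30:10 within the layer)")
print("\nLayer flows sum to the branch target; the subendocardial layer is "
      "sized for 1.11× the subepicardial flow.")
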