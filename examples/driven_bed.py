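"""A single coronary bed driven by an analytic intramyocardial pressure.

The rig replaces the whole heart with a half-sinusoid LV pressure pulse and
a matched fiber-stress waveform (peak VE = 20% of peak LV pressure), so the
microcirculation can be studied in isolation: systolic squeezing of the
subendocardial layer, early-systolic retrograde flow, and the suppression of
subendocardial inflow as the varying-elastance scaling γ grows.
"""

import numpy as np

from coroflow import make_driven_bed_fixture

print("driven LAD-scale bed, peak LV pressure 110 mmHg, HR 71:")
rig = make_driven_bed_fixture(peak_lv_pressure=110.0)
rec = rig.run_to_steady(max_beats=30, tol=1e-4)
n = rec["q1"].shape[0]
systole = slice(0, int(0.41 * n))
for li, layer in enumerate(("subepi", "mid", "subendo")):
    q = rec["q1"][:, li] * 60.0
    print(f"  {layer:8s} mean {q.mean():6.1f} mL/min   systolic min "
          f"{q[systole].min():6.1f}  (negative = retrograde)")
print("  -> the subendocardial layer is squeezed hardest: its inflow "
      "reverses in early systole while the subepicardium barely notices.\n")

print("gamma sweep (mean systolic subendocardial inflow, mL/min):")
for gamma in (0.0, 0.03, 0.06):
    rig = make_driven_bed_fixture(110.0, gamma=gamma)
    rec = rig.run_to_steady(max_beats=25, tol=1e-4)
    q_sys = rec["q1"][systole, 2].mean() * 60.0
    print(f"  gamma = {gamma:.2f}: {q_sys:7.2f}")
print("  -> myocardial stiffening (VE = gamma * sigma_f) monotonically "
      "suppresses systolic subendocardial perfusion.")
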