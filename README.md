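# coroflow

A closed-loop, multi-scale simulator of **cardiac-to-coronary coupling**:
beat-to-beat hemodynamics of the human circulation in which one-fiber /
TriSeg cardiac mechanics drive a coronary circulation made of 1D epicardial
conduit vessels and a three-layer lumped microcirculation, coupled through a
transmurally varying intramyocardial pressure.

It is aimed at computational physiologists who want to study how myocardial
contraction impedes its own blood supply — the systolic squeeze of the
subendocardium, diastole-dominant left-coronary inflow, systolic-dominant
venular outflow — and how valvular disease (severe aortic stenosis)
reshapes coronary flow without any change in the coronary vessels
themselves.

## The model

* **Heart.** Five walls (LV free wall, septum, RV free wall, two atria).
  Each ventricular wall is a thick myofiber shell: midwall area sets the
  natural fiber strain ε_f = ½·ln(A_m/A_ref); a constitutive law (active
  stress with force–length and force–velocity dependence, exponential
  passive stress) gives the fiber stress σ_f; Laplace's law converts wall
  tension and curvature into transmural pressure.  The three ventricular
  walls meet in a junction ring whose geometry is solved from force
  equilibrium (TriSeg), so the septum moves with the trans-septal load.  A
  non-linearly compliant pericardium surrounds heart and epicardial
  coronary vessels.  The LV free wall and septum carry 12 + 5 labelled
  segments mapped onto the three coronary territories
  (LCx : LAD : RCA = 42 : 33 : 25 % of the LV wall, 0 : 60 : 40 % of the
  septum, RCA takes the whole RV wall).
* **Coronary circulation.** Four epicardial arteries (LM → LAD + LCx, and
  RCA) and five veins (three branch veins, distal and proximal coronary
  sinus) as non-linear elastic tubes; each branch ends in a lumped bed:
  epicardial arterial compartment, three transmural layers (subepi, mid,
  subendo at r = 1/6, 3/6, 5/6) each with an arteriolar and a venular
  compartment, and an epicardial venous compartment.  Compartments follow a
  collapsible-tube pressure–area law

      p_trans = p₀·[((A + A_w/2)/(A₀ + A_w/2))^(k/3−1) − max(0, (A/A₀)^(−0.7)(A_w/A₀)^(0.4) − 1)²]

  and resistances follow Poiseuille's volume dependence R = R₀·V₀²/V².
  Reference resistances are split 28 : 65 : 7 (epicardial arterial :
  intramyocardial : venous) and 60 : 30 : 10 (R₁ : R_m : R₂) and tuned by
  an autoregulation loop until branch flows hit 112/83/60 mL/min with an
  endo-to-epi ratio of 1.11.
* **Coupling.** Each layer feels an intramyocardial pressure

      IMP = CEP + VE,   CEP = r·P₁ + (1−r)·P₂,   VE = γ·σ_f   (γ = 0.06)

  where P₁/P₂ are the adjacent cavity/pericardial pressures (LV→pericardium
  for the left free wall, LV→RV across the septum, RV→pericardium for the
  right wall) and branch IMP is the territory-mass-weighted average.
* **Closed loop.** Systemic and pulmonary circulations, Bernoulli valves
  with blood-column inertance, a homeostatic controller holding cardiac
  output (5.1 L/min) and mean arterial pressure (91 mmHg), explicit
  integration at a 1 ms step, beat-to-beat convergence to a periodic state.

## Worked example

```bash
python examples/run_reference.py
```

prints (abridged; a tuned resting run takes about two minutes):

```
autoregulation converged in 13 iterations (max layer-flow error 0.8%)

MAP 90.5 mmHg   CO 5.13 L/min   peak LV pressure 117 mmHg
branch flows (mL/min): LCX 60  LAD 83  RCA 112
distal coronary sinus mean flow: 144 mL/min (= LAD + LCx, the left venous confluence)

LAD velocity: peak systolic 0.13 m/s, peak diastolic 0.30 m/s
  pDSVR 2.29   DTVi 0.92 (diastole-dominant perfusion, the left-coronary signature)

subendocardial arteriolar diameter, ED→ES: LAD -14%  RCA -3%
```

The branch flows and endo-to-epi ratio sit on their targets because the
autoregulation loop put them there; the *waveform* — a small systolic
velocity, a large early-diastolic surge, the compression of subendocardial
arterioles — is emergent physics of the coupled model.  The peak
diastolic-to-systolic velocity ratio (pDSVR ≈ 2.3) is the classic Doppler
signature of left-coronary inflow.

`examples/aortic_stenosis.py` narrows the aortic orifice from 4.8 to
0.8 cm² (a single parameter) and shows the consequences: peak LV pressure
≈ 160 mmHg, a ≈ 43 mmHg mean transvalvular gradient, a 4.1 m/s jet, and a
period of *reverse* systolic LAD flow as the stenotic rise in
intramyocardial pressure squeezes blood back out of the wall.
`examples/driven_bed.py` isolates one microcirculatory bed under an
analytic pressure pulse, and `examples/territory_and_resistances.py` shows
the closed-form territory and resistance bookkeeping.

A thin CLI wraps the same library:

```bash
coroflow simulate --scenario pair --out results/   # tuned reference + stenosis
coroflow tune --out tuned.yaml                     # autoregulation only
coroflow metrics --beat results/beat_reference.csv --events results/events_reference.json
coroflow fixture --peak-lv 110                     # driven-bed rig
```

## Layout

| module | contents |
| --- | --- |
| `coroflow.network` | closed-loop topology, wall segmentation, territories |
| `coroflow.mechanics` | one-fiber law, TriSeg junction solve, pericardium |
| `coroflow.tubes` | non-linear tube law, wave impedance, pulse propagation |
| `coroflow.micro` | collapsible compartments, volume-dependent resistances, bed circuit |
| `coroflow.coupling` | intramyocardial pressure (CEP + VE), territory weighting |
| `coroflow.engine` | time integration, convergence, homeostasis, autoregulation, scenarios |
| `coroflow.metrics` | pDSVR, DTVi, diameter excursions, gradients, summary tables |
| `coroflow.config` / `coroflow.fixtures` / `coroflow.cli` | configuration, analytic test rigs, CLI |

See `docs/methods.md` for the model equations, parameter provenance and
known limitations.
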