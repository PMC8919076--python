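# Methods

This note documents the model equations, the provenance and calibration of
every tunable constant, the numerical choices, and the known limitations of
the package.  Units are clinical throughout: pressures in mmHg, volumes in
mL, flows in mL/s (mL/min at the I/O surface), areas in cm², fiber stress
in kPa (converted at the coupling boundary, 1 kPa = 7.5006 mmHg).

## 1. Cardiac mechanics

**One-fiber walls.** Each ventricular wall is a thick shell of
incompressible myocardium with homogeneously distributed fiber stress.
Midwall area A_m determines the natural fiber strain
ε_f = ½·ln(A_m/A_ref).  Total stress is

    σ_f = σ_act · act(t) · L(ε_f) · FV(dε_f/dt)  +  σ_pas·(e^{k_pas·ε_f} − 1)   (ε_f > 0)

* `act(t)` — a rise–plateau–decay twitch occupying the configured systolic
  duration (41 % of the cycle), sin² rise over 30 % of it, cos² decay over
  35 %.
* `L(ε)` — ascending force–length limb, zero at the slack strain
  ε₀ = −0.10, saturating at 1 for ε ≥ 0.25 (slope 2.857).  The plateau
  leaves a Starling reserve: acute dilation recruits force.
* `FV(v)` — linearized Hill force–velocity factor,
  clip(1 − shortening_rate/v_max, 0, 1.1) with v_max = 2.6 s⁻¹.  This is
  what caps the resting ejection velocity (peak aortic flow ≈ 450 mL/s) and
  lets slow, high-pressure ejection recruit more stress in aortic stenosis.
* Below the slack strain the wall develops a small compressive recoil
  stress (−0.3·(e^{−8ε}−1) kPa), giving diastolic suction and preventing
  cavity collapse.

Wall tension T_m = σ_f·V_wall/(2A_m)·(1 + z²/3 + z⁴/5) with
z = 3C_m·V_wall/(2A_m) corrects for wall thickness; transmural pressure is
2·T_m·C_m (Laplace).  For a closed sphere these assumptions reduce to the
closed form p = (σ_f/3)·ln(1 + V_wall/V_cav), which is used for the atria
and serves as the benchmark oracle in the tests.

**TriSeg.** The LV free wall, septum and RV free wall are spherical caps
sharing a junction ring; the septal cap volume and ring radius are solved
each time step from axial and radial tension balance (quasi-Newton with a
cached Jacobian, Levenberg damping, and a Powell-hybrid fallback; residual
tolerance 10⁻⁸ of the wall-tension scale).  Two regularizations keep the
equilibrium well-posed when walls go slack: a tiny odd-symmetric tension
term (0.1·sinh(2ε) kPa) and a weak elastic restoring force on the ring
radius (1 kPa·cm per cm toward the reference ring), representing the
fibrous annulus.  Both are negligible against working tensions.

**Pericardium.** p = 0.5·((V/700 mL)^10 − 1) mmHg over the summed cavity,
wall and epicardial coronary volumes.

**MultiPatch segmentation.** The LV free wall carries 12 labelled segments
and the septum 5; with uniform material parameters all segments of a wall
share stress and strain, so the labels only matter for territory
book-keeping (the only quantitative territory datum is the per-wall
fraction table).

## 2. Conduit vessels

Large vessels are single-element non-linear elastic tubes (fixed length,
variable cross-section) obeying the same pressure–area law as the
microcirculation (below) without entering the collapse regime.  A tube's
ends couple to junction nodes through the Poiseuille resistance of half the
vessel plus 0.4× its characteristic impedance Z = ρc/A (the Z fraction
damps junction transients; a pure-Z coupling would wrongly impose the
characteristic impedance as a DC resistance).  Junction nodes are massless:
their pressure is the conductance-weighted average of member tube pressures
plus source flows, so Kirchhoff's law holds exactly every step.  Coronary
bed inlet flows carry the blood-column inertance of the feeding artery
(ρl/A), which low-pass filters the inlet velocity on the ~50 ms scale.  For
pulse-propagation studies `TubeChain` discretizes a tube into N segments
with inter-segment inertance and reproduces the linearized wave speed
c = √((A/ρ)·dp/dA) within 2 %.

## 3. Coronary microcirculation

Each branch bed: epicardial arterial compartment → arterial split node →
three parallel transmural layers (arteriolar compartment, shared middle
resistance, venular compartment) → venous merge node → epicardial venous
compartment.  Compartment pressure–area law:

    p_trans(A) = p₀·[((A + A_w/2)/(A₀ + A_w/2))^(k/3−1) − max(0, (A/A₀)^(−0.7)·(A_w/A₀)^(0.4) − 1)²]

The first factor anchors p_trans(A₀) = p₀ (exponent k/3 − 1; the
alternative reading breaks the anchor).  The collapse term's exponent signs
are chosen so it is inactive at the reference state and diverges negatively
as A → 0.  Compliances are the local slope of this law, not independent
parameters.  Resistances follow R = R₀·V₀²/V² with a smooth volume floor
at 1 % of V₀ (identity above 1.25 % of V₀).  Layer intramyocardial pressure
adds to the transmural pressure of both compartments of the layer;
epicardial compartments feel pericardial pressure instead.

Reference resistances: R_total = mean perfusion pressure / branch target
flow, split 28:65:7 and 60:30:10, with per-layer paths scaled inversely to
the layer's flow share (subepi : mid : subendo = 1 : 1.055 : 1.11).

**Autoregulation** rescales each layer's R₀,₁ (secant iteration on mean
layer flow) until all nine layer flows sit within 1 % of their targets.
During the first iterations the intramyocardial (V₀, p₀) pairs are
re-anchored at the diastolic mean of the evolving resting beat.  This
anchoring is the package's definition of the compartments' reference state:
it makes R(V) fluctuate around R₀ over the cycle, so the printed resistance
splits hold at the operating point; without it the systolic collapse
penalty makes the subendocardial flow target unreachable.

## 4. Intramyocardial pressure

IMP = CEP + VE per branch and layer.  CEP = r·P₁ + (1−r)·P₂ at
r ∈ {1/6, 3/6, 5/6}; endpoints: LV free wall (LV cavity → pericardium),
septum (LV → RV, r measured from the RV side so r = 5/6 faces the LV),
RV free wall (RV → pericardium).  VE = γ·σ_f with γ = 0.06 for all walls
and σ_f the segment's total (active + passive) stress, applied uniformly
across the three layers.  Branch values are territory-mass-weighted
averages.  In the tuned resting beat peak VE is ≈ 19–20 % of peak LV
pressure, the calibration the γ value encodes.

## 5. Closed loop, control and scenarios

Valves: orifice Bernoulli law Δp = ρ/(2A²)·q|q| plus inertance of an
effective blood column (aortic 16 cm·ρ/A — LVOT plus proximal aorta;
mitral/tricuspid 8 cm; pulmonary 14 cm), diode closure, no regurgitation,
and a guard that an (almost) empty chamber cannot keep ejecting.
Integration: explicit Euler at 1 ms (the model's natural step; all
compartment time constants are ≥ a few ms); an RK4 option exists for
step-size studies.  Blood volume is conserved to round-off by
construction.  A beat is converged when the beat-to-beat relative state
change falls below 10⁻³ and the hemodynamic targets are met.

**Homeostasis.** Between beats a controller adjusts systemic peripheral
resistance and circulating volume (added/removed in the venous reservoir)
toward MAP = 91 mmHg and CO = 5.1 L/min.  It identifies the 2×2 plant
sensitivity once by explicit perturbation (all probe windows start from the
same settled state so drift cancels) and then applies damped Newton updates
every ten beats, with guards against venous congestion (p_RA > 10 mmHg)
and collapse (p_RA < 0.5 mmHg).  Venous return resistance (0.06 mmHg·s/mL
at each atrial inlet) makes cardiac output preload-controllable, which is
what the volume knob exploits.

**Aortic stenosis.** Only the aortic orifice area changes (4.8 →
0.8 cm²); the tuned coronary parameters are frozen (no re-autoregulation).
The stenosed loop cannot hold both targets exactly: the controller runs to
its best-effort point (≈ MAP 83 mmHg, CO 4.8 L/min) and the run converges
when the controller stalls; the achieved means are stored in the beat
record's metadata.

## 6. Parameter provenance

Printed reference inputs (heart rate 71 bpm, CO 5.1 L/min, MAP 91 mmHg,
systolic duration 41 %, branch flows 112/83/60 mL/min, endo/epi 1.11, wall
volumes 108/45/39 mL, orifice areas, territory fractions, γ = 0.06,
r = 1/6–5/6, splits 28:65:7 and 60:30:10, myocardial density 1.055 g/mL,
1 ms step) are taken as given.  Everything else — one-fiber constants,
vessel geometry, wall-law p₀/k/A_w, compartment reference volumes, valve
effective lengths, pericardial constants — is not printed anywhere and is
therefore a package calibration: `scripts/calibrate.py` fits the global
contractility scale and systemic resistance to the resting MAP/CO by a
two-point secant on the uncontrolled loop, and coronary vessel areas were
sized so that mean LAD velocity matches the clinical Doppler scale
(≈ 0.17 m/s mean, peak systolic ≈ 0.13 m/s).  These constants are config
fields with the calibrated defaults, not physiologic measurements.

## 7. What the driven-bed fixture does and does not show

`make_driven_bed_fixture` replaces the heart with a half-sinusoid LV
pressure and a proportionally matched fiber-stress pulse, with constant
arterial/venous boundary pressures.  It reproduces the layerwise systolic
squeeze, early-systolic retrograde subendocardial flow and the γ
sensitivity with the same circuit and stepper as the full model, so tests
on it exercise the microcirculation faithfully.  It omits aortic pulsation,
pericardial pressure and venous pressure waves, so absolute flows differ a
few percent from the closed loop and waveform-shape metrics (pDSVR, DTVi)
should only be read from the full simulation.

## 8. Known limitations

* The stenosis case suppresses coronary flow more strongly than the
  reference publication (LAD −57 % vs −35 %; endo/epi 0.24 vs 0.38).  Root
  cause: with the linearized Hill force–velocity law, slow stenotic
  ejection loses the velocity damping that limits fiber stress at rest, so
  peak σ_f (hence VE) roughly doubles while peak LV pressure rises only
  ~37 %, loading every transmural layer; and the controller's best-effort
  MAP (83 vs 91 mmHg) costs another ~8 % of perfusion pressure.  A
  sarcomere-level contraction model would keep σ_f closer to proportional
  to pressure.
* The stenosis LAD velocity recovers in the last ~40 ms of ejection (the
  LV relaxes while aortic flow coasts on its inertia), so the *peak
  systolic* velocity (≈0.11 m/s) overstates the near-zero mid-systolic
  plateau; mid-systole is retrograde, as observed clinically.
* The systolic antegrade velocity–time integral is small (DTVi ≈ 0.92 vs
  ≈0.8 reported), the flip side of the strong systolic impediment.
* Single-element conduit vessels do not resolve intra-vessel wave shapes;
  wave transit exists only in the N-segment `TubeChain`.
* No chronic adaptation, no hyperemia/flow reserve, no shortening-induced
  intracellular pressure (deliberately excluded), no atrial coronary
  supply.
* The quasi-static IMP sweep of the isolated bed shows a <3 % arteriolar
  volume rise at low IMP (flow-mediated pressure redistribution) before
  compression dominates.
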