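# Methods

## Model structure

The simulator couples a lumped (0D) left ventricle and aortic valve to a
distributed (1D) systemic arterial tree.

**Ventricle.** The time-varying elastance formulation generates LV
pressure from volume, `P_LV = E(t)(V − V_d)`. The normalized elastance
`E_N(τ)`, τ = t/t_max, is a double-Hill product
`k · [τ^n1/(1+τ^n1)] · [1/(1+(τ/τ2)^n2)]` with n1 = 1.32 and n2 = 21.9.
τ2 is fixed in closed form so the maximum sits exactly at τ = 1
(stationarity of log E_N gives `τ2 = r^(−1/n2)` with
`r = 1/(2·n2/n1 − 1)`), and k normalizes that maximum to 1; E_N(0) = 0
exactly, so the diastolic elastance floor is E_ed regardless of E_es.
Diastole is closed by a constant-pressure atrium behind a linear diode
resistance (0.01 mmHg·s/mL). The atrial pressure is a controller
variable: after each cycle it moves by 0.9× the end-diastolic pressure
error until the simulated LVEDP matches the prescribed value within
0.2 mmHg. This makes LVEDP (and hence preload, EDV = LVEDP/E_ed + V_d)
an honest input even as E_ed or systole-diastole timing change.

**Peak-elastance time.** With the sharp double-Hill relaxation, ejection
terminates shortly after the elastance peak, so t_max effectively sets
the ejection time. The default is t_max = 0.44·t_HP (0.35 s at the
0.8 s default period), which yields ejection times of ~0.33–0.36 s —
the prolonged LVET characteristic of the severe-aortic-stenosis
population this model targets (normal LVET at 75 bpm is ~0.31 s, and
severe stenosis lengthens it). This is an assumption (the timing inputs
of comparable studies are rarely printed) and is config-exposed.

**Valve.** Orifice area is A_eff = A_mes·max(ζ, 1e-4); the floor keeps
the inertance and Bernoulli coefficient finite when closed. The
gradient is ΔP = L·dQ/dt + β·Q|Q| with L = ρ·l_eff/A_eff
(l_eff default 1.5 cm) and β = K_t·(ρ/2)(1/A_eff − 1/A_o)², K_t = 1.5.
A_o defaults to the ascending-aorta (root-segment) cross-section, so a
larger aorta produces larger divergent losses. The opening law
(dζ/dt = (1−ζ)K_vo·ΔP) applies for ΔP ≥ 0 and the closing law
(dζ/dt = ζ·K_vc·ΔP) for ΔP < 0, with the instantaneous signed gradient
driving both. Flow is advanced semi-implicitly (quadratic drag
linearized about the current flow), unconditionally stable at the PDE
time step. The valve is a pure stenosis: it does not conduct backward
(Q clamped at 0), because with the calibrated minimal opening
coefficient and equal closing coefficient the closure is slow, and an
unclamped valve would pass a regurgitant volume of 10–20% of the
forward stroke — an aortic-insufficiency physiology outside this
model's scope. `ValveParams(allow_backflow=True)` restores the
unclamped behaviour for study.

**Rate-coefficient calibration.** K_vo is the smallest value on a
geometric grid (factor 1.25 from 0.01 /(mmHg·s)) whose converged cycle
reaches ζ ≥ 0.999; K_vc is set equal. This reproduces the slow,
stenosis-like opening (acceleration-time fraction ~0.4–0.5 of
ejection). Calibration is per valve area at the sweep baseline and held
fixed across a sweep, mirroring a per-patient ejection-time
calibration.

**Arterial tree.** 1D continuity and momentum
(∂A/∂t + ∂Q/∂x = 0; ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ)∂P/∂x = f) with
friction f = −2(γ_v+2)πμQ/(ρA); γ_v = 9 approximates the flat
Womersley-like velocity profile of large arteries (γ_v = 2 recovers
Poiseuille). The wall law is the Langewouters arctangent
A(P) = A_max(1/2 + arctan((P−P0)/P1)/π); geometry files store the area
at the 95 mmHg reference, from which A_max is recovered. An optional
Kelvin–Voigt term (pressure ∝ (dA/dt)/A, `visc_coeff` column) is
accepted but defaults to zero (elastic walls): the study's outcomes are
cycle-averaged gradients, which wall creep barely moves. Terminals are
three-element Windkessels advanced implicitly.

## Numerics

* Two-step MacCormack (Lax–Wendroff class, second order) on a fixed
  grid, dx ≈ 1.5 cm, at least 3 nodes per segment. The time step is
  fixed per run from a conservative wave-speed bound (pressure headroom
  220 mmHg, advective headroom 250 cm/s, CFL safety 0.5); the actual
  CFL number is monitored every step and violation aborts with a
  diagnostic.
* **Junctions** combine characteristic physics with exact conservation:
  the coupling system (mass + total-pressure continuity
  P + ρu²/2, Newton to 1e-10 relative, ≤50 iterations with damped
  steps) is closed by *exact* Riemann invariants of the arctangent law,
  W = u ± s·Φ(A/A_max) with s = √(πP1/ρ) and Φ a tabulated universal
  shape integral, sampled at the characteristic foot (semi-Lagrangian
  interpolation — sampling the neighbour node alone biases the mean
  junction flux by O(dx)). The resulting fluxes then advance the
  boundary areas by half-cell finite-volume mass balances, so volume is
  conserved to machine precision; over a converged cycle root inflow
  equals summed terminal outflow to ~1e-12. In extreme soft-wall,
  low-pressure corners the discrete one-step system can lack an exact
  root; the solver then accepts the best iterate if its total-pressure
  mismatch is below 0.1 mmHg (hemodynamically negligible; conservation
  is unaffected).
* Terminal and root boundaries use the same conservative half-cell
  update, with the terminal flux from a scalar Newton solve against the
  implicit Windkessel and the root flux prescribed (valve flow or a
  given inflow waveform).
* Halving the time step moves stroke volume and mean TPG by <0.5%.

## Calibration loops and definitions

* **Periodicity:** cycles are repeated until the relative change of
  stroke volume and mean aortic pressure is below 1e-3 (plus the LVEDP
  criterion); typically 6–15 cycles from a uniform 80 mmHg start.
* **Afterload:** achieved TVR is the operational MAP/CO (CO = net
  systemic output); achieved TAC is structural (volume-integrated
  vessel compliance at the realized mean pressure plus terminal
  compliances). The calibration loop runs, compares achieved to target,
  and rescales (≤10 outer iterations, 1% tolerance). Terminal
  resistances share one exact factor; because the large-artery viscous
  resistance (~3% of TVR) sits in series with the terminals, the
  aggregate resistance target is steered multiplicatively until MAP/CO
  hits the request. Compliance is scaled through the reference areas
  (A_max): this multiplies dA/dP by the same factor at *every* pressure
  and leaves wave speeds invariant. Scaling the width pressure P1
  instead would hit the aggregate target at the reference pressure
  while sharpening the arctangent so severely that a nominally
  compliant tree has almost no compliance left at systolic pressures —
  which is where the gradient–compliance interaction lives.
  Already-calibrated cases are detected and left untouched
  (fixed-point stability).
* **Stroke volume** is the forward transvalvular volume (the
  echocardiographic quantity); with the default regurgitation-free
  valve it equals the net volume. The PV-loop width equals it by mass
  balance.
* **Ejection window** (for mean/max TPG and timing indices): the
  longest contiguous run with ζ above its floor and forward flow;
  acceleration time runs from ejection onset to peak flow.

## Sensitivity analysis

Each determinant (E_es 0.5–6 mmHg/mL, E_ed 0.03–0.31 mmHg/mL, TVR
0.6–1.8 mmHg·s/mL, TAC 0.5–2 mL/mmHg) is swept over 10 evenly spaced
values at each valve-area level (0.6/1.0/1.5/2.0 cm²), everything else
held at baseline (E_es 2.0, E_ed 0.1, TVR 1.0, TAC 1.2, t_HP 0.8 s,
LVEDP 11 mmHg, V_d 39.3 mL) and re-calibrated per case to within 1%.
A fifth sweep co-varies TAC with TVR along the hyperbola
TAC·TVR = const, the constant defaulting to the baseline product
(config-exposed). Effects on the mean TPG are reported two ways:

* per natural unit — the ordinary OLS slope (statsmodels), with SE and
  two-sided t-test p-value (n−2 df);
* per 10% increase from the lowest (baseline) sweep value — the OLS
  slope against the number of *compounding* 10% increments,
  k = ln(x/x_min)/ln(1.1). A simple rescaling of the per-unit slope by
  0.1·x_min cannot represent a "per-10%" effect consistently across
  determinants whose ranges span a 12-fold versus a 3-fold increase;
  the compounding-increment regression does, and it is the definition
  under which the two reporting conventions are mutually consistent.

## Synthetic geometry

The generator emulates the gross architecture of the systemic tree: an
eight-segment aortic trunk tapering from 5.3 to ~1.1 cm², carotid,
subclavian/vertebral/brachial, celiac, mesenteric, renal and
iliac/femoral branches, wave speeds rising from ~4 m/s at the root to
~9 m/s in the limbs, terminal resistances distributed by regional flow
fractions (head ~16%, arms ~18%, splanchnic ~30%, renal ~20%, legs
~17%) and terminal compliances in proportion. Aggregate afterload lands
near the baseline values before any rescaling. A seeded ±2% jitter on
lengths and areas individualizes trees; all physics is deterministic.
It does **not** reproduce any published anatomical segment table, wave
reflection sites are far coarser than reality, and there is no coronary,
cerebral or pulmonary circulation — so passing tests demonstrate the
mechanisms and their ordering, not patient-level waveform fidelity. The
103-segment variant subdivides the same topology (identical afterload)
for workloads expecting a dense tree.

## Known limitations

* No physiological reflexes: each swept case is an open-loop
  experiment, deliberately so (isolated effects are the point).
* The equal opening/closing coefficient with minimal-opening
  calibration makes closure slow; the regurgitation-free clamp is the
  corresponding modelling choice.
* Absolute gradient levels on the synthetic tree run ~20–40% above the
  values a patient-specific geometry would give at the same stroke
  volume (shorter ejection, peakier flow, early partial opening each
  contribute ~10%); orderings, signs and the interaction with stenosis
  severity are robust to this.
* Problem sizes used throughout (24-segment tree, dx ≈ 1.5 cm,
  ~450 steps per cycle, 10-point sweeps) were chosen so a full
  sensitivity study runs in minutes on one core; refining them changes
  summary metrics by well under 1%.
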