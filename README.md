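# stenoflow

Coupled heart–valve–arterial simulation of aortic valve stenosis, built
for quantifying how the transvalvular pressure gradient (TPG) — the
standard severity marker of aortic stenosis — depends on the
hemodynamic environment in which it is measured.

The mean TPG is flow-dependent: left-ventricular contractility,
diastolic stiffness, vascular resistance and arterial compliance all
move it, yet none of these can be varied in isolation in a patient.
`stenoflow` provides the in-silico laboratory for exactly that
experiment, for cardiovascular modellers and for clinician-scientists
studying low-flow/low-gradient stenosis: each determinant is swept on
its own while everything else is held fixed, and the independent effect
on the mean TPG is quantified by regression.

## Model

Three coupled components, solved together through cardiac cycles until
the beat-to-beat stroke volume and mean pressure are periodic:

* **Left ventricle** — time-varying elastance:
  `P_LV(t) = E(t) · (V(t) − V_d)` with
  `E(t) = (E_es − E_ed) · E_N(t/t_max) + E_ed`, where `E_N` is a
  normalized double-Hill activation/relaxation curve (0 at
  end-diastole, 1 at the time of peak elastance). Filling comes from a
  constant-pressure atrium behind a diode resistance, auto-tuned so the
  end-diastolic pressure equals the prescribed LVEDP.
* **Stenotic aortic valve** — pressure gradient
  `ΔP = L·dQ/dt + β·Q·|Q|`, with inertance `L = ρ·l_eff/A_eff` and
  turbulent divergent-loss coefficient
  `β = K_t·(ρ/2)·(1/A_eff − 1/A_o)²` (`K_t = 1.5`, `A_o` the
  ascending-aorta area). The orifice `A_eff = A_mes·ζ(t)` opens and
  closes dynamically: `dζ/dt = (1−ζ)·K_vo·ΔP` for a favourable gradient
  and `dζ/dt = ζ·K_vc·ΔP` for an adverse one; the rate coefficient is
  calibrated as the smallest value that still opens the valve fully
  within the ejection.
* **Systemic arterial tree** — 1D continuity/momentum pulse-wave
  propagation (two-step MacCormack) on a branching network with the
  Langewouters arctangent pressure–area law, junctions coupled through
  exact Riemann invariants with exact mass conservation, and
  three-element Windkessel outlets. Aggregate afterload is summarized
  as TVR (MAP/CO) and TAC (total vessel + terminal compliance), both of
  which can be rescaled to targets and are re-calibrated per case.

Since published whole-body geometries are not redistributable, the
package generates its own synthetic arterial trees (24-segment default,
103-segment refinement) with physiological taper, branch topology, wave
speeds and afterload — explicitly labelled non-anatomical.

## Worked example

```python
from stenoflow import calibrate_case, patient_fixture, summarize

cfg = patient_fixture("dekker_av_stenosis")   # Ees 3.3, Eed 0.1, LVEDP 11, AVA 0.6
cfg, waveforms = calibrate_case(cfg, tvr_target=1.0, tac_target=1.2)
s = summarize(waveforms)
print(f"SV {s.sv:.1f} mL, mean TPG {s.mean_tpg:.1f} mmHg, "
      f"BP {s.sbp:.0f}/{s.dbp:.0f} mmHg, ET {s.ejection_time*1e3:.0f} ms")
```

prints

```
SV 69.4 mL, mean TPG 75.4 mmHg, BP 109/67 mmHg, ET 356 ms
```

a critical stenosis under preserved contractility: a gradient far above
the 40 mmHg severity threshold with prolonged ejection, at normal
arterial pressures. The scripts in `examples/` walk through the other
capabilities — the contractility sweep, the stroke-volume/gradient
curve with the dobutamine rest/stress pair, the compliance–resistance
map showing that peripheral pressure alone does not determine the
gradient, and geometry generation. A thin CLI (`stenoflow simulate`,
`stenoflow sweep`, `stenoflow fixtures`) wraps the same functions for
shell use.

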