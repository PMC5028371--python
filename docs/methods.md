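# Methods

## The physical system being simulated

The package reproduces, in software, a bench model of the ventilated
respiratory system built from hardware-store physiology:

* **Lung** — one to three elastic test lungs in parallel (19 ml/cmH₂O
  each, so 19/38/57 ml/cmH₂O total), enclosed in an airtight box.
* **Pleural space** — the gas above the water surface of a semi-stiff
  plastic container, plus the lung box and tubing. It is evacuated to
  −5 cmH₂O at baseline.
* **Chest wall / abdomen** — the container (diaphragmatic surface
  1500 cm²) is three-quarters filled with water and coupled through a
  valve of adjustable resistance to a 10-litre plastic sack (upper surface
  1800 cm²). The higher water level in the container produced by the
  pleural vacuum imitates the rib-cage spring-out force; strapping the
  container ("stiff chest wall") reduces its wall compliance.

Evacuation pre-loads the system: at zero airway pressure the lung is held
at functional residual capacity by a transpulmonary pressure of
0 − (−5) = 5 cmH₂O. The point of the apparatus — and of the simulation —
is that the two chest-wall elastances are different physical mechanisms:

* **tidal** chest-wall elastance (ΔPPL/VT ≈ 18–24 cmH₂O/L) reflects
  compressing the pleural gas and bulging the container wall during one
  breath, when the resistive valve gives the water no time to move;
* **end-expiratory** chest-wall elastance (ΔPPL_EE/ΔEELV ≈ 1.5 cmH₂O/L)
  reflects only the hydrostatic head change once the water has
  redistributed, i.e. the spring-out force.

Because the end-expiratory elastance is near zero, a PEEP step raises the
end-expiratory transpulmonary pressure by almost the full ΔPEEP, and lung
elastance can be measured as ΔPEEP/ΔEELV from spirometry alone.

## Governing equations

State variables: lung volume above residual `V` (ml) and displaced water
`w` (ml, container → sack). All pressures gauge cmH₂O.

* Quasi-static linear lung: `P_TP = V / C_L` behind a small airway
  resistance `R_aw`. Inspiratory flow is prescribed (square wave);
  expiration is passive through a one-way PEEP valve with resistance
  `R_exp`: `q = max(0, P_alv − PEEP) / (R_aw + R_exp)`.
* Hydraulic valve: `dw/dt = (P_PL + head(w)) / R_valve` with
  `head(w) = −P_evac − w·E_stat/1000`. The static chest-wall elastance
  `E_stat` is the geometric term `(1/A_container + 1/A_sack)·1000 =
  1.22 cmH₂O/L` plus a small residual term (below).
* Pleural pressure: the pleural gas amount `(P_atm + P_PL)·V_gas` is
  conserved, with
  `V_gas = V_gas0 − ΔV + w + C_wall·(P_PL − P_evac)`
  (lung expansion steals gas volume, water displacement adds it, the wall
  bulges linearly). `P_PL` is obtained by solving this quadratic exactly
  at every evaluation, so gas conservation holds to machine precision by
  construction. The abdominal sack is perfectly plastic (its surface sees
  atmospheric pressure).

Assumptions deliberately excluded: temperature/humidity effects, gas
exchange, nonlinear lung recruitment, 3-D geometry, and any active valve
or ventilator control beyond the ideal behaviours above.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| compliance per test lung | 19 | ml/cmH₂O | nominal hardware value |
| lungs in parallel | 1–3 | — | arm definition |
| capacity per test lung | 600 | ml | chosen so the single-lung arm's end-inspiratory volume exceeds capacity at PEEP 12 but not at PEEP 8, reproducing the bench omission rule |
| residual volume | 0 | ml | linear lung anchor |
| evacuation pressure | −5 | cmH₂O | bench procedure |
| pleural gas volume | 15 000 | ml | unreported on the bench; sets the gas compressibility C_gas ≈ 14.6 ml/cmH₂O |
| wall compliance (normal / strapped) | 36.63 / 22.55 | ml/cmH₂O | calibrated so tidal ΔPPL/VT at ZEEP is 18 / 24 cmH₂O/L |
| container / sack surface | 1500 / 1800 | cm² | bench geometry |
| residual static elastance | 0.40 | cmH₂O/L | calibrated so the measured end-expiratory chest-wall elastance is 1.5 cmH₂O/L (geometry alone gives 1.22) |
| valve resistance | 0.12 | cmH₂O·s/ml | sets the post-step pleural relaxation time constant to ≈9 s, completing within 10–15 breaths |
| airway / expiratory resistance | 0.003 / 0.005 | cmH₂O·s/ml | small enough that expiration completes and end-expiratory airway pressure sits within 0.05 cmH₂O of PEEP on every arm |
| VT, rate, I:E, pause | 300 ml, 15/min, 1:2, 10 % | — | ventilator settings of the procedure |

The two calibrations (wall compliance, residual static elastance) were run
once with `calibrate_chest_wall` / the exact static solver and frozen into
the defaults; `make_default_config` returns the frozen values and the
calibration can be re-run from them at any time (`tests` and the
acceptance pipeline both do).

## Numerics

* Fixed-step classical Runge–Kutta 4 at dt = 1 ms. Breath-phase
  boundaries are quantised to the 10-ms record grid (flow portion 0.93 s,
  inspiratory flow 322.58 ml/s), so phase switches never fall inside an
  integrator step and the delivered tidal volume is exact.
* Channels are recorded at 100 Hz. Pressure and volume channels are point
  samples; the **flow channel is the mean flow over each 10-ms interval**
  (i.e. the exact volume increment times the rate), so the 100-Hz
  rectangle summation used by the spirometric tidal volumes integrates
  exactly. A point-sampled square flow wave would alias several ml per
  breath into VTi.
* The static equilibrium solver inverts the full coupled statics (lung
  line, gas law, hydrostatic spring) with a bracketed scalar root-find;
  the familiar closed form ΔEELV = ΔPEEP/(E_L + E_cw,stat) is exposed
  separately as its small-signal linearisation. The linearisation
  overstates the end-expiratory pleural rise by the factor
  1 + E_stat(C_wall + C_gas)/1000 ≈ 1.08, which is why the residual
  static elastance is calibrated against the exact solver.
* Degenerate inputs: zero tidal volume is the CPAP path (used by the
  absolute oracle test); a zero ΔEELV or zero VT raises rather than
  returning infinite elastances; exceeding lung capacity raises a
  `CapacityError`, which the protocol layer converts into the bench's
  step-omission bookkeeping.

### Periodic steady state vs static equilibrium

Under cyclic ventilation the valve sees the cycle-*mean* pleural
pressure, which exceeds the end-expiratory value, so the periodic steady
state settles with end-expiratory pleural pressure ≈1.3 cmH₂O below the
no-flow static equilibrium (and EELV correspondingly above static FRC).
This is genuine physics of the apparatus, not integrator error. All
reported quantities are PEEP-step *differences*, which the linearity of
the model makes offset-free; the absolute convergence of the ODE to the
static solver is verified on CPAP (non-cycling) runs.

### PEEP-change bookkeeping

Measured PEEP is the mean airway pressure over the final 100 ms of each
expiration; a change is flagged when consecutive breaths differ by more
than 1 cmH₂O. A large step onto a compliant arm (e.g. 0→12.2 on three
lungs) exceeds the previous plateau pressure, so the first expiration
never opens the valve and the flag fires on two consecutive breaths; the
analysis layer merges flags closer than four breaths into one transition
anchored at its first breath. The ΔEELV estimator sums VTi − VTe over the
first 15 breaths from that anchor and subtracts 15 times the per-breath
offset measured over breaths 16–20, which removes both a constant
flow-sensor bias (±2 ml/s recovers the true volume within 5 ml) and the
systematic residue of the 100-Hz summation.

## What the synthetic data does and does not emulate

The simulator *is* the study's data source: it reproduces the hardware
geometry, the ventilator settings, the evacuated baseline, sensor noise
(per-sample Gaussian on pressures and flow) and a constant
pneumotachograph offset. It does **not** emulate: nonlinear or
volume-history-dependent test-lung mechanics (the printed isolated-lung
FRC values 92/167/242 ml sit below the nominal-compliance prediction
95/190/285 ml, and the bench tidal lung elastance ran ~12 % above
nominal — the default keeps ideal linear lungs), cardiogenic
oscillations, leaks, valve imperfections, or drifting sensor gain.
Passing tests therefore demonstrate the *mechanism* — spring-out
off-loading makes end-expiratory pleural pressure PEEP-invariant and the
PEEP-step method self-consistent — not the idiosyncrasies of any
particular bench or patient.

One consequence is worth stating plainly: in a linear model the
zero-intercept slope of measured ΔEELV on ΔPEEP/E_L(tidal) is bounded by
E_L/(E_L + E_cw,EE) < 1 (≈0.93 pooled over the arms), because the
PEEP-step elastance necessarily contains the small end-expiratory
chest-wall term. A slope slightly above 1, as a physical bench can
report, requires measurement scatter or lungs whose tidal elastance runs
above the elastance governing the PEEP-step range; the simulation
reports the ideal-model value and the r² ≈ 1 that goes with it. The same
term makes the PEEP-step driving-pressure estimate exceed the
conventional ΔPAW − ΔPPL by exactly E_cw,EE × VT ≈ 0.45 cmH₂O.

## Design choices that were genuinely open

* **Pause placement**: the end-inspiratory pause is the terminal part of
  the inspiratory third of the cycle (flow 0.93 s + pause 0.4 s +
  expiration 2.67 s); the settings state the fractions but not the
  nesting, and equilibrium results are insensitive to it.
* **Square inspiratory flow**: the volume-control default; the flow
  shape is otherwise unspecified.
* **ΔEELV summation start**: the 15-breath window starts at the first
  breath whose expiration occurs at the new level.
* **Offset rule reading**: the per-breath offset is the mean VTi − VTe
  of the five breaths following the summation window, subtracted
  15-fold — the only reading that makes the trailing breaths useful.
* **Breaths per level**: 25 (the estimator needs 20 after a change; the
  pleural relaxation completes in 10–15).
* **Isolated-lung alignment test**: the figure-level claim that the
  isolated-lung P/V curve lies along the attached model's end-expiratory
  airway points is tested after fitting the parallel offset (the curves
  are drawn transposed from their ≈5 cmH₂O start); the residual bowing
  equals ΔPPL_EE and stays below 0.5 cmH₂O.

## Problem sizes

The shipped pipelines use 25 breaths per PEEP level (100 s simulated per
level), three paired step sizes on six arms plus the incremental
staircase — about 2.5 simulated hours integrated at 1 kHz per full
reproduction, which runs in well under a minute on one core.

## Known limitations

* Linear lung only by default (a tabulated P/V lung is a config option
  left unimplemented; the parameter slots exist).
* No pressure-control or spontaneous-breathing modes; no trigger logic.
* The abdomen is a single hydraulic compartment; there is no separate
  rib-cage vs diaphragm partition, mirroring the bench.
* Sensor noise is white; real pneumotachographs drift.
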