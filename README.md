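# peepsim

A simulated bench model of the ventilated respiratory system — an elastic
recoiling lung, an evacuated "pleural" gas space, and an expanding
chest-wall analogue built from a water-filled container coupled to an
abdominal sack — together with the complete PEEP-step measurement
pipeline that runs on its ventilator waveforms.

## Who this is for, and why

Partitioning the driving pressure of mechanical ventilation between lung
and chest wall normally requires esophageal manometry, which is rarely
done at the bedside. The PEEP-step method sidesteps it: because the rib
cage springs *outward* below its resting volume, the end-expiratory
pleural pressure P̄PL stays essentially constant when PEEP is raised, so

* ΔEELV = ΔPEEP / E_L  — the end-expiratory lung-volume change after a
  PEEP step is set by lung elastance alone,
* E_L = ΔPEEP / ΔEELV — lung elastance from a PEEP step plus spirometry,
* ΔP_TP = (ΔPEEP/ΔEELV) × VT — transpulmonary driving pressure with no
  pleural or esophageal pressure signal.

`peepsim` is for respiratory-mechanics researchers and educators who
want a fully inspectable, deterministic model in which these claims can
be simulated, measured with the same estimators used on real ventilator
data (15-breath cumulative ΔEELV with 5-breath offset compensation,
100-Hz channels), and stress-tested against sensor noise and flow-sensor
bias.

The physics is two coupled ODE states (lung volume, displaced water)
closed by an exact ideal-gas pleural pressure: tidal breaths compress
pleural gas (tidal chest-wall elastance ≈ 18–24 cmH₂O/L), while slow
water redistribution through a resistive valve leaves only the
hydrostatic spring at end-expiration (end-expiratory chest-wall
elastance ≈ 1.5 cmH₂O/L ≙ compliance ≈ 650 ml/cmH₂O). That dichotomy is
the whole story.

## Worked example

Two test lungs (C_L = 38 ml/cmH₂O), normal chest wall, a 0 → 8.4 → 0
cmH₂O PEEP step, 25 breaths per level:

```python
import peepsim as ps

cfg = ps.make_default_config(2, "normal")
wf = ps.simulate(cfg, [(0.0, 25), (8.4, 25), (0.0, 25)])
print(ps.PeepStepModel(wf, arm="2L/normal").fit().summary())
```

prints

```
PEEP-step mechanics — arm 2L/normal
breath   dPEEP    dEELV  EL(step) EL(tidal)  dPPL_EE  dPTP_EE  ECW_EE
    25    8.40    301.0     27.91     26.34     0.45     7.95    1.50
    50   -8.40   -301.0     27.91     26.34    -0.45    -7.95    1.50
```

Reading the first row: the 8.4-cmH₂O PEEP increase inflated the lung by
301 ml (ΔEELV from flow summation alone), so the PEEP-step lung
elastance is 8.4/0.301 = 27.9 cmH₂O/L — within 6 % of the tidal estimate
(ΔPAW−ΔPPL)/VT = 26.3 cmH₂O/L that needs the pleural signal. The
end-expiratory pleural pressure rose only 0.45 cmH₂O (ECW_EE =
1.5 cmH₂O/L, against a *tidal* chest-wall elastance of 18), so the
end-expiratory transpulmonary pressure gained 7.95 of the 8.4 cmH₂O
applied. The down-step mirrors the up-step exactly.

The closed-form static oracle agrees: `ps.equilibrium_solver(cfg, 8.4)`
gives ΔEELV = 302.0 ml and P̄PL = −4.55 cmH₂O.

## Command line

```bash
peepsim list-presets
peepsim simulate --preset two_lungs_normal_0_8_0 --out run/ --repetitions 3
peepsim analyze run/waveforms_rep0.csv --out tables/
peepsim reproduce results_summary --out tables/
peepsim reproduce regression --out tables/
peepsim reproduce fig8_example --out tables/
```

`simulate` writes 100-Hz waveform CSVs (`time_s, paw_cmH2O, ppl_cmH2O,
flow_ml_s, vlung_ml, phase`), per-breath tables and a run manifest;
noise-free reruns are checksum-identical. Protocol steps whose
end-inspiratory volume would exceed the test-lung capacity are omitted
and logged (with one lung, the 0-12-0 step).

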