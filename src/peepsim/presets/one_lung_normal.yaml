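lung:
  n_units: 1
  compliance_per_unit: 19.0
  residual_volume: 0.0
  capacity_per_unit: 600.0
  airway_resistance: 0.003
chest_wall:
  pleural_gas_volume: 15000.0
  wall_compliance: 36.63
  strapped: false
  atmospheric_pressure: 1033.0
  evacuation_pressure: -5.0
abdomen:
  container_area: 1500.0
  sack_area: 1800.0
  sack_volume: 10000.0
  valve_resistance: 0.12
  fluid_column_factor: 1.0
  residual_static_elastance: 0.4
ventilator:
  tidal_volume: 300.0
  respiratory_rate: 15.0
  ie_ratio: 0.5
  pause_fraction: 0.1
  peep: 0.0
  expiratory_resistance: 0.005
integrator_dt: 0.001
record_rate: 100.0
isolated_lung: false
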