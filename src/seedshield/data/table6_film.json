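{
  "thickness_mm": {"value": 0.12, "sd": 0.02},
  "moisture_absorption_pct": {"value": 3.9, "sd": 0.2},
  "water_solubility_pct": {"value": 26.5, "sd": 2.4},
  "opacity_A_per_mm": {"value": 1.1, "sd": 0.1},
  "water_vapor_permeability_g_per_m_Pa_s": {"value": 1.8, "sd": 0.3},
  "tensile_strength_MPa": {"value": 17.4, "sd": 1.5},
  "elongation_at_break_pct": {"value": 122.7, "sd": 5.1}
}
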