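design_name: D1
channel_length_um: 3000.0
control_points:
- s_um: 0.0
  width_um: 98.0
  height_um: 102.0
- s_um: 3000.0
  width_um: 24.0
  height_um: 40.0
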