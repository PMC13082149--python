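objective:
  magnification: 10.0
  na: 0.4
fov_size_um:
- 1300.0
- 2200.0
fovs_per_well: 5
z_slices: 18
z_step_um: 6.0
volumes_per_fov: 6
fiduciary_frames_per_well: 1
wells: 24
pixel_size_um: 0.425
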