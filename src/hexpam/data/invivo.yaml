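# Full-scale in vivo operating point of the dual-channel hexagon-scanner PAM.
# Use for timing arithmetic and reports; a raster at this scale is far larger
# than the shipped desk-scale simulation default (see desk.yaml).
scanner:
  radius_mm: 7.0          # circumscribed radius; 14-mm polygon diameter
  beam_offset_mm: 5.0
  n_facets: 6
  facet_width_mm: 7.0
  facet_height_mm: 10.0
acquisition:
  pulse_delay_ns: 450.0
  sound_speed_m_s: 1500.0
  digitizer_rate_MHz: 250.0
  prf_kHz: 500.0
  bscan_rate_Hz: 300.0
  slow_step_um: 5.0
  channel_range_mm: 14.0
  overlap_mm: 4.0
  fov_fast_mm: 24.0
  fov_slow_mm: 22.5
  rpm: 3000.0             # 300 Hz B-scan rate with six facets
  depth_of_focus_mm: 0.221
  lateral_res_um: 7.5
  axial_res_um: 33.0
  transducer_center_MHz: 30.0
  depth_range_mm: 2.0
  working_distance_mm: 30.0
  pixel_um: 5.0
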