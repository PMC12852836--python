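# Desk-scale simulation default: same timing physics (pulse delay, sampling,
# sound speed, resolutions) as the in vivo operating point, but a reduced
# raster so a full simulate -> reconstruct -> unmix chain runs in seconds.
scanner:
  radius_mm: 7.0
  beam_offset_mm: 5.0
  n_facets: 6
  facet_width_mm: 7.0
  facet_height_mm: 10.0
acquisition:
  pulse_delay_ns: 450.0
  sound_speed_m_s: 1500.0
  digitizer_rate_MHz: 250.0
  prf_kHz: 24.0           # 80 A-lines per B-scan at 300 Hz
  bscan_rate_Hz: 300.0
  slow_step_um: 25.0
  channel_range_mm: 2.0
  overlap_mm: 0.5
  fov_fast_mm: 3.5
  fov_slow_mm: 2.4        # 96 B-scans = 16 per facet
  rpm: 3000.0
  depth_of_focus_mm: 0.221
  lateral_res_um: 7.5
  axial_res_um: 33.0
  transducer_center_MHz: 30.0
  depth_range_mm: 1.2
  working_distance_mm: 30.0
  pixel_um: 25.0
simulation:
  phantom:
    kind: vessels
    extent_mm: [3.8, 2.6, 0.9]
    voxel_um: 15.0
    n_vessels: 6
    radius_um: [40.0, 90.0]
    so2_values: [0.97, 0.70]
    total_hb_mol_l: 2.3e-3
    depth_band_mm: [0.25, 0.45]
    seed: 0
  perturbation:
    offsets_um: [30.0, -20.0, 10.0, 0.0, -10.0, 20.0]
    gains: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
    wobble_amplitude_um: 5.0
    wobble_cycles: 1.5
  noise_snr_db: null      # null = noise-free
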