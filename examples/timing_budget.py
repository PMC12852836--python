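"""Acquisition-timing arithmetic at the in vivo operating point.

Prints the identities that define the system's throughput: a 22.5 x 24 mm2
field of view in about 15 s, an 8.4-um average fast-axis step, and the
0.675-mm acoustic separation that keeps the two wavelength echoes apart.
"""

import dataclasses

from hexpam import effective_range_mm, pulse_separation_mm
from hexpam.config import builtin_config_path, load_config
from hexpam.geometry import timing_summary

setup = load_config(builtin_config_path("invivo"))
cfg = setup.config

t = timing_summary(cfg, n_facets=setup.geom.n_facets)
print(f"volumetric scan time      : {t['scan_time_s']:.1f} s "
      f"({cfg.fov_slow_mm} mm slow axis at {cfg.slow_step_um} um, "
      f"{cfg.bscan_rate_Hz:.0f} Hz B-scans)")
print(f"average fast-axis step    : {t['avg_fast_step_um']:.1f} um "
      f"({cfg.channel_range_mm} mm per pass, {cfg.prf_kHz:.0f} kHz PRF)")
print(f"A-lines per B-scan        : {t['alines_per_bscan']:.0f}")
print(f"overlap fraction          : {t['overlap_fraction_pct']:.1f} % "
      f"of a single channel range")

fast = dataclasses.replace(cfg, rpm=10000.0)
print(f"B-scan rate at 10,000 rpm : "
      f"{timing_summary(fast)['bscan_rate_from_rpm_Hz']:.0f} Hz")

sep = pulse_separation_mm(cfg.pulse_delay_ns, cfg.sound_speed_m_s)
print(f"\nwavelength echo separation: {sep:.3f} mm "
      f"({cfg.pulse_delay_ns:.0f} ns at {cfg.sound_speed_m_s:.0f} m/s) "
      f"> depth of focus {cfg.depth_of_focus_mm} mm")
print(f"effective fast axis       : "
      f"{effective_range_mm(cfg.channel_range_mm, cfg.channel_range_mm, cfg.overlap_mm):.0f} mm "
      f"(two {cfg.channel_range_mm:.0f}-mm channels, "
      f"{cfg.overlap_mm:.0f}-mm overlap)")
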