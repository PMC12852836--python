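"""Dual-wavelength sO2 round trip on a synthetic vessel.

Oxy- and deoxy-haemoglobin absorb differently at 532 and 558 nm, so the
ratio of the two photoacoustic amplitudes encodes oxygen saturation.  This
script simulates an artery-like (sO2 = 0.97) and a vein-like (sO2 = 0.70)
vessel, runs the full acquisition + demultiplexing + unmixing chain, and
reports the recovered per-vessel saturation, noise-free and at 20-dB SNR.
"""

import numpy as np

from hexpam import ExtinctionTable, PhantomSpec, ScanConfig, ScannerGeometry, generate_vessel_phantom, simulate_scan
from hexpam.pipeline import so2_from_raw

geom = ScannerGeometry()
table = ExtinctionTable.default()
cfg = ScanConfig(channel_range_mm=2.0, overlap_mm=0.5, fov_fast_mm=3.5,
                 prf_kHz=24.0, bscan_rate_Hz=300.0, slow_step_um=25.0,
                 fov_slow_mm=0.9, depth_range_mm=1.2, pixel_um=25.0)

for label, so2, seed in (("artery-like", 0.97, 3), ("vein-like", 0.70, 13)):
    spec = PhantomSpec(extent_mm=(3.8, 1.1, 0.9), voxel_um=15.0, n_vessels=1,
                       radius_um=(60.0, 60.0), so2_values=(so2,),
                       depth_band_mm=(0.25, 0.45), seed=seed)
    phantom = generate_vessel_phantom(spec)
    clean = so2_from_raw(simulate_scan(phantom, table, cfg, geom, seed=1))
    noisy = so2_from_raw(simulate_scan(phantom, table, cfg, geom,
                                       noise_snr_db=20.0, seed=7))
    m = clean["so2"]
    err = np.abs(m.so2[m.mask] - so2).max()
    core = m.mask & (clean["a532"] > 0.3 * clean["a532"].max()) \
        & noisy["so2"].mask
    noisy_mean = np.nanmean(noisy["so2"].so2[core])
    print(f"{label} vessel, assigned sO2 = {so2:.2f}")
    print(f"  noise-free: {m.mask.sum()} valid pixels, "
          f"worst pixel error {err:.2e}")
    print(f"  20-dB SNR : vessel-core mean {noisy_mean:.4f} "
          f"(error {abs(noisy_mean - so2):.4f})")
print("\nthe noise-free recovery is exact to numerical precision because "
      "the window-energy amplitude is invariant to the half-sample timing "
      "offset between the two wavelength gates")
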