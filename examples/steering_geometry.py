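"""Steering geometry of the dual-beam hexagon scanner.

Two fixed laser beams, one from each side of a spinning hexagon mirror,
are steered by two different facets at once.  This script evaluates the
beam/facet incidence angles across one facet period and shows the two
scanning regimes: in the central regime the angles sum to 60 degrees, in
the outer regime to 120 degrees.
"""

import numpy as np

from hexpam import ScanConfig, ScannerGeometry, channel_angles, focus_trajectory, initial_angle

geom = ScannerGeometry(radius_mm=7.0, beam_offset_mm=5.0)  # 14-mm polygon
theta0 = initial_angle(geom)
print(f"initial angle theta0 = arccos(d/R) = {theta0:.3f} deg")
print(f"central regime: {60 - theta0:.2f} deg < omega < {theta0:.2f} deg\n")

print(f"{'omega':>8} {'theta1':>8} {'theta2':>8} {'sum':>8}  regime")
for omega in np.arange(2.5, 60.0, 5.0):
    s = channel_angles(omega, geom)
    print(f"{omega:8.1f} {s.theta1_deg:8.2f} {s.theta2_deg:8.2f} "
          f"{s.angle_sum_deg:8.2f}  {s.regime}")

# one facet pass sweeps each channel across its full 14-mm range
cfg = ScanConfig()
grid = np.linspace(60 - theta0 + 1e-6, 120 - theta0 - 1e-6, 1001)
pos1, _ = focus_trajectory(grid, geom, cfg)
print(f"\nchannel-1 focal sweep over one facet pass: "
      f"{pos1.max() - pos1.min():.6f} mm (configured {cfg.channel_range_mm} mm)")
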