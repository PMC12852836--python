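import dataclasses
import math

import numpy as np
import pytest
from hypothesis import settings

import hexpam as h

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent brute-force ray-trace oracle (kept deliberately naive: it
# intersects each incident ray with all six facet lines and reflects about
# the facet normal; the package implementation selects facets analytically)
# ---------------------------------------------------------------------------
def raytrace_oracle(omega_deg, radius_mm, offset_mm, channel, n_facets=6):
    """Returns (incidence_from_normal_deg, facet_normal_deg) or None."""
    a = radius_mm * math.cos(math.pi / n_facets)
    half = radius_mm * math.sin(math.pi / n_facets)
    ux = -1.0 if channel == 1 else 1.0
    x0 = -100.0 * radius_mm * ux
    d = offset_mm
    best = None
    for k in range(n_facets):
        phi = math.radians(omega_deg + 360.0 / n_facets * k)
        nx, ny = math.cos(phi), math.sin(phi)
        un = ux * nx
        if un >= 0:
            continue
        t = (a - (x0 * nx + d * ny)) / un
        if t <= 0:
            continue
        px = x0 + t * ux
        s = -px * math.sin(phi) + d * math.cos(phi)
        if abs(s) <= half + 1e-12:
            if best is None or t < best[0]:
                best = (t, phi, abs(un))
    if best is None:
        return None
    return math.degrees(math.acos(min(1.0, best[2]))), math.degrees(best[1])


@pytest.fixture(scope="session")
def geom():
    return h.ScannerGeometry()


@pytest.fixture(scope="session")
def table():
    return h.ExtinctionTable.default()


@pytest.fixture(scope="session")
def desk_cfg():
    """Scaled-down acquisition used by the simulation tests."""
    return h.ScanConfig(channel_range_mm=2.0, overlap_mm=0.5, fov_fast_mm=3.5,
                        prf_kHz=24.0, bscan_rate_Hz=300.0, slow_step_um=25.0,
                        fov_slow_mm=0.9, depth_range_mm=1.2, pixel_um=25.0)


@pytest.fixture(scope="session")
def single_vessel_scan(geom, table, desk_cfg):
    """Noise-free scan of one vessel with sO2 = 0.75, shared across tests."""
    spec = h.PhantomSpec(extent_mm=(3.8, 1.1, 0.9), voxel_um=15.0,
                         n_vessels=1, radius_um=(60.0, 60.0),
                         so2_values=(0.75,), depth_band_mm=(0.25, 0.45),
                         seed=3)
    phantom = h.generate_vessel_phantom(spec)
    raw = h.simulate_scan(phantom, table, desk_cfg, geom, None, seed=1)
    return {"phantom": phantom, "spec": spec, "raw": raw}


@pytest.fixture(scope="session")
def flat_target_scan(geom, table):
    """Flat slab spanning a full 14-mm facet pass (depth-correction target)."""
    cfg = h.ScanConfig(prf_kHz=84.0, bscan_rate_Hz=300.0, slow_step_um=50.0,
                       fov_slow_mm=0.3, depth_range_mm=1.2, pixel_um=50.0)
    phantom = h.flat_target_phantom(0.35, 60.0, (24.2, 0.4, 1.4),
                                    voxel_um=25.0)
    raw = h.simulate_scan(phantom, table, cfg, geom, None, seed=0)
    return {"raw": raw, "config": cfg, "depth_mm": 0.35}


def surface_depths_mm(volume, row=0):
    """Envelope-peak surface depth per filled column (parabolic refinement)."""
    data = volume.data[row]
    filled = volume.provenance["filled"][row]
    start = volume.provenance["gate_start_samples"][row]
    corrected = volume.provenance.get("depth_corrected", False)
    out = []
    for i in np.flatnonzero(filled):
        col = data[i]
        p = int(np.argmax(col))
        sub = 0.0
        if 0 < p < col.size - 1:
            denom = col[p - 1] - 2 * col[p] + col[p + 1]
            if denom < 0:
                sub = 0.5 * (col[p - 1] - col[p + 1]) / denom
        z = (p + sub) * volume.z_pitch_mm
        if not corrected:
            z += start[i] * volume.z_pitch_mm
        out.append(z)
    return np.asarray(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
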