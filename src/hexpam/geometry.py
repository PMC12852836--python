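"""Steering geometry and acquisition timing of a dual-channel polygon-scanner PAM.

A single water-immersible hexagon mirror steers two fixed excitation beams at
once.  Both beams travel horizontally at an orthogonal distance ``d`` from the
polygon centre, one arriving from each side of the scanner (the two
optical-acoustic combiners face each other), so each beam strikes a different
facet of the same rotating mirror.  With the scan angle ``omega`` measured
from a facet-centred orientation, the beam/facet incidence angles (taken from
the facet normal, as usual in optics) obey

    theta1 + theta2 = 60 deg    for 60 deg - theta0 < omega < theta0
    theta1 + theta2 = 120 deg   for omega >= theta0        (one facet period)

where ``theta0 = arccos(d / R)`` and ``R`` is the circumscribed radius of the
polygon.  Everything in this module is pure geometry/arithmetic: angles are
degrees at the API boundary and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ScannerGeometry",
    "SteeringState",
    "ScanConfig",
    "initial_angle",
    "channel_angles",
    "focus_trajectory",
    "arc_sag_mm",
    "pulse_separation_mm",
    "effective_range_mm",
    "timing_summary",
]


@dataclass(frozen=True)
class ScannerGeometry:
    """Polygon mirror and beam-delivery geometry.

    ``radius_mm`` is the circumscribed (vertex) radius; the shipped default of
    7 mm corresponds to a 14-mm polygon diameter.  ``beam_offset_mm`` is the
    orthogonal distance from the polygon centre to each incident beam.
    """

    radius_mm: float = 7.0
    beam_offset_mm: float = 5.0
    n_facets: int = 6
    facet_width_mm: float = 7.0
    facet_height_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.beam_offset_mm < 0:
            raise ValueError(
                f"beam_offset_mm must be >= 0, got {self.beam_offset_mm}")
        if self.beam_offset_mm > self.radius_mm:
            raise ValueError(
                "beam_offset_mm must not exceed radius_mm "
                f"(got d={self.beam_offset_mm}, R={self.radius_mm})")
        if self.n_facets < 3:
            raise ValueError(f"n_facets must be >= 3, got {self.n_facets}")
        if self.facet_width_mm <= 0 or self.facet_height_mm <= 0:
            raise ValueError("facet dimensions must be positive")
        if self.radius_mm <= 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")

    @property
    def apothem_mm(self) -> float:
        """Distance from the polygon centre to each facet plane."""
        return self.radius_mm * math.cos(math.pi / self.n_facets)

    @property
    def facet_half_chord_mm(self) -> float:
        return self.radius_mm * math.sin(math.pi / self.n_facets)

    @property
    def facet_period_deg(self) -> float:
        """Rotation angle spanned by one facet pass."""
        return 360.0 / self.n_facets

    @property
    def theta0_deg(self) -> float:
        return initial_angle(self)


@dataclass(frozen=True)
class SteeringState:
    """Instantaneous beam-steering state of the two channels."""

    omega_deg: float
    theta1_deg: float
    theta2_deg: float
    theta0_deg: float
    regime: str  # "central" | "outer" | "facet-transition"

    @property
    def angle_sum_deg(self) -> float:
        return self.theta1_deg + self.theta2_deg


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ScanConfig:
    """Timing, sampling, and field-of-view parameters of one acquisition.

    Defaults reproduce the in vivo operating point: 450-ns inter-wavelength
    delay, 250-MHz digitisation, a 500-kHz per-wavelength pulse repetition
    rate, a 300-Hz B-scan rate, a 5-um slow-axis step, and two 14-mm channel
    ranges merged with a 4-mm overlap into a 24-mm effective fast axis.
    """

    pulse_delay_ns: float = 450.0
    sound_speed_m_s: float = 1500.0
    digitizer_rate_MHz: float = 250.0
    prf_kHz: float = 500.0
    bscan_rate_Hz: float = 300.0
    slow_step_um: float = 5.0
    channel_range_mm: float = 14.0
    overlap_mm: float = 4.0
    fov_fast_mm: float = 24.0
    fov_slow_mm: float = 22.5
    rpm: float = 3000.0
    depth_of_focus_mm: float = 0.221
    lateral_res_um: float = 7.5
    axial_res_um: float = 33.0
    # acquisition/simulation plumbing
    transducer_center_MHz: float = 30.0
    depth_range_mm: float = 2.0
    working_distance_mm: float = 30.0
    pixel_um: float = 5.0
    # surface gate threshold in scaled MADs of the envelope; at 10 the
    # Rayleigh-tail false-trigger rate stays negligible over a full raster
    surface_threshold_mads: float = 10.0
    energy_calibration_558: float = 1.0
    blend: str = "linear"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("blend",):
                continue
            if f.name == "pulse_delay_ns":
                if self.pulse_delay_ns < 0:
                    raise ValueError("pulse_delay_ns must be >= 0")
                continue
            _positive(f.name, getattr(self, f.name))
        if self.overlap_mm >= self.channel_range_mm:
            raise ValueError(
                "overlap_mm must be smaller than channel_range_mm "
                f"(got overlap={self.overlap_mm}, range={self.channel_range_mm})")
        sep = pulse_separation_mm(self.pulse_delay_ns, self.sound_speed_m_s)
        if sep <= self.depth_of_focus_mm:
            raise ValueError(
                "pulse_delay_ns * sound_speed_m_s must exceed the optical depth "
                f"of focus so the two wavelength echoes cannot overlap "
                f"(separation {sep:.4f} mm <= DOF {self.depth_of_focus_mm} mm)")
        eff = effective_range_mm(self.channel_range_mm, self.channel_range_mm,
                                 self.overlap_mm)
        if abs(eff - self.fov_fast_mm) > 1e-6:
            raise ValueError(
                "fov_fast_mm must equal 2*channel_range_mm - overlap_mm "
                f"(got {self.fov_fast_mm}, expected {eff})")
        if self.blend not in ("linear", "cosine"):
            raise ValueError(f"blend must be 'linear' or 'cosine', got {self.blend!r}")

    # -- derived quantities used throughout the pipeline ------------------
    @property
    def pulse_separation_mm(self) -> float:
        return pulse_separation_mm(self.pulse_delay_ns, self.sound_speed_m_s)

    @property
    def delay_samples(self) -> float:
        """Inter-wavelength delay in digitiser samples (may be fractional)."""
        return self.pulse_delay_ns * 1e-9 * self.digitizer_rate_MHz * 1e6

    @property
    def mm_per_sample(self) -> float:
        return self.sound_speed_m_s * 1e3 / (self.digitizer_rate_MHz * 1e6)

    @property
    def n_alines(self) -> int:
        return int(self.prf_kHz * 1e3 / self.bscan_rate_Hz)

    @property
    def n_bscans(self) -> int:
        return int(round(self.fov_slow_mm * 1e3 / self.slow_step_um))


def initial_angle(geom: ScannerGeometry) -> float:
    """Initial polygon angle ``theta0 = arccos(d / R)`` in degrees.

    This is the angular distance between a vertex and the foot of the
    perpendicular from the polygon centre to a beam at the moment the vertex
    crosses that beam, i.e. the half-width of the regime boundaries.
    """
    d, R = geom.beam_offset_mm, geom.radius_mm
    if d < 0:
        raise ValueError(f"beam_offset_mm must be >= 0, got {d}")
    if d > R:
        raise ValueError(f"beam_offset_mm must not exceed radius_mm (d={d}, R={R})")
    return math.degrees(math.acos(d / R))


def _trace_channel(omega_deg: float, geom: ScannerGeometry, channel: int):
    """Mirror-reflection ray trace of one fixed incident beam.

    Returns ``(facet_index, incidence_deg, facet_normal_deg, hit_xy)`` for the
    facet the beam actually strikes, or ``None`` if the beam misses every
    facet (cannot happen for 0 <= d < R).  Channel 1 travels in the -x
    direction, channel 2 in +x; both run along the line y = +d.  Facet ``k``
    has outward normal at ``omega + k * facet_period`` degrees (facet-centred
    convention: at omega = 0 facet 0 faces channel 1 squarely).
    """
    d = geom.beam_offset_mm
    a = geom.apothem_mm
    half = geom.facet_half_chord_mm
    step = geom.facet_period_deg
    ux = -1.0 if channel == 1 else 1.0
    # start well outside the polygon on the beam's own side
    x0 = 10.0 * geom.radius_mm * (-ux)
    best = None
    for k in range(geom.n_facets):
        phi = math.radians(omega_deg + k * step)
        nx, ny = math.cos(phi), math.sin(phi)
        un = ux * nx
        if un >= -1e-15:  # facet faces away from the beam
            continue
        travel = (a - (x0 * nx + d * ny)) / un
        if travel <= 0:
            continue
        hx = x0 + travel * ux
        s = -hx * math.sin(phi) + d * math.cos(phi)  # in-facet chord coordinate
        if abs(s) <= half + 1e-12:
            if best is None or travel < best[0]:
                best = (travel, k, phi, (hx, d))
    if best is None:
        return None
    travel, k, phi, hit = best
    incidence = math.degrees(math.acos(min(1.0, abs(ux * math.cos(phi)))))
    return k, incidence, math.degrees(phi), hit


def channel_angles(omega_deg: float, geom: ScannerGeometry) -> SteeringState:
    """Beam/facet incidence angles of both channels at scan angle ``omega``.

    ``omega`` is reduced modulo one facet period before evaluation.  The
    regime label follows the steering-angle equations: ``central`` when
    ``period - theta0 < omega < theta0`` (angle sum = one facet period),
    ``outer`` when ``omega >= theta0`` (angle sum doubled), and
    ``facet-transition`` for the residual band ``[0, period - theta0]`` in
    which one beam straddles a vertex at the band edges; transition states
    are flagged rather than raised, and are dropped from the usable line.
    """
    period = geom.facet_period_deg
    omega = float(omega_deg) % period
    theta0 = initial_angle(geom)
    hit1 = _trace_channel(omega, geom, channel=1)
    hit2 = _trace_channel(omega, geom, channel=2)
    if hit1 is None or hit2 is None:
        raise ValueError(
            f"beam misses the polygon at omega={omega_deg} deg; check geometry")
    if period - theta0 < omega < theta0:
        regime = "central"
    elif omega >= theta0:
        regime = "outer"
    else:
        regime = "facet-transition"
    return SteeringState(omega_deg=omega, theta1_deg=hit1[1], theta2_deg=hit2[1],
                         theta0_deg=theta0, regime=regime)


def _pass_start_deg(geom: ScannerGeometry, channel: int) -> float:
    """Facet-normal angle at which a channel's facet pass begins.

    A channel stays on one facet between two consecutive vertex crossings of
    its own beam; the struck facet's normal angle then sweeps one facet
    period starting at this value.
    """
    period = geom.facet_period_deg
    theta0 = initial_angle(geom)
    if channel == 1:
        return period - theta0
    return period + theta0


def focus_trajectory(omega_grid, geom: ScannerGeometry, config: ScanConfig):
    """Fast-axis focal-spot position of each channel, in channel-local mm.

    The reflected-ray angle equals twice the struck facet's normal angle, so
    within one facet pass it sweeps linearly over two facet periods; because
    the focusing optics are not prescribed, that sweep is normalised so one
    facet pass spans exactly ``channel_range_mm``.  Returns ``(pos1, pos2)``
    arrays in [0, channel_range_mm); positions are strictly monotone within a
    single facet pass.
    """
    omegas = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    if omegas.size == 0:
        raise ValueError("omega_grid must be non-empty")
    period = geom.facet_period_deg
    out = []
    for channel in (1, 2):
        start = _pass_start_deg(geom, channel)
        pos = np.empty_like(omegas)
        for i, w in enumerate(omegas):
            traced = _trace_channel(w % period, geom, channel)
            if traced is None:
                raise ValueError(f"beam misses the polygon at omega={w} deg")
            # reflected angle = 2 * facet normal angle; normalise the sweep
            phi = traced[2]
            frac = ((phi - start) % period) / period
            pos[i] = frac * config.channel_range_mm
        out.append(pos)
    return out[0], out[1]


def arc_sag_mm(x_mm, config: ScanConfig) -> np.ndarray:
    """Extra acoustic path at fast-axis position ``x`` (channel-local mm).

    The focal spot of a rotating-mirror scan rides on an arc of radius equal
    to the working distance, tangent to the flat focal plane at the centre of
    the facet pass; the sagitta of that arc is the depth distortion the
    rotatory scanning imprints on the raw data and that depth correction must
    remove.  Zero at the pass centre by construction.
    """
    wd = config.working_distance_mm
    dx = np.asarray(x_mm, dtype=float) - config.channel_range_mm / 2.0
    if np.any(np.abs(dx) >= wd):
        raise ValueError(
            "fast-axis excursion exceeds the working distance; increase "
            "working_distance_mm")
    return wd - np.sqrt(wd * wd - dx * dx)


def pulse_separation_mm(delay_ns: float, sound_speed_m_s: float) -> float:
    """Spatial separation of the two wavelength echoes, ``delay * c`` in mm."""
    if delay_ns < 0:
        raise ValueError(f"delay_ns must be >= 0, got {delay_ns}")
    if sound_speed_m_s <= 0:
        raise ValueError(f"sound_speed_m_s must be > 0, got {sound_speed_m_s}")
    return delay_ns * 1e-9 * sound_speed_m_s * 1e3


def effective_range_mm(range1_mm: float, range2_mm: float,
                       overlap_mm: float) -> float:
    """Total fast-axis extent of two overlapping channel ranges."""
    if overlap_mm < 0 or overlap_mm > min(range1_mm, range2_mm):
        raise ValueError(
            f"overlap_mm must lie in [0, min(range1, range2)], got {overlap_mm}")
    return range1_mm + range2_mm - overlap_mm


def timing_summary(config: ScanConfig, n_facets: int = 6) -> dict:
    """Acquisition-timing identities derived from a scan configuration.

    Returns a dict with the total volumetric scan time, the average fast-axis
    step between A-lines, the B-scan rate implied by the rotation speed, the
    A-line count per B-scan, and the inter-channel overlap fraction.
    """
    if config.bscan_rate_Hz <= 0 or config.prf_kHz <= 0 or config.rpm <= 0:
        raise ValueError("rates must be strictly positive")
    n_lines = config.fov_slow_mm * 1e3 / config.slow_step_um
    return {
        "scan_time_s": n_lines / config.bscan_rate_Hz,
        "avg_fast_step_um":
            config.channel_range_mm * 1e3 * config.bscan_rate_Hz
            / (config.prf_kHz * 1e3),
        "bscan_rate_from_rpm_Hz": config.rpm / 60.0 * n_facets,
        "alines_per_bscan": config.prf_kHz * 1e3 / config.bscan_rate_Hz,
        "overlap_fraction_pct": 100.0 * config.overlap_mm / config.channel_range_mm,
    }
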